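"""Graph statistics, seed neighborhoods, and cross-tissue bridging.

Works on undirected protein-association graphs whose edges carry a
``confidence`` in [0, 1] (STRING-style).  Three layers:

* descriptive statistics of an induced subgraph against the global edge
  density of the background (observed/expected edges, average degree,
  average local clustering, binomial interaction-enrichment p), with an
  equal-size random-node-set null for empirical significance;
* per-tissue minimal bridging between two seed proteins: on the
  confidence-thresholded graph, the connectors are the intermediate
  nodes of the shortest seed-to-seed path plus those of successive
  next-shortest alternatives while a total node budget allows;
* the cross-tissue connector frequency census with mean + 2 SD outlier
  selection of tissue-independent bridges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError
from .genesets import normalize_id

logger = logging.getLogger(__name__)


@dataclass
class NetworkStats:
    """Induced-subgraph statistics against the background density."""

    n_nodes: int
    observed_edges: int
    expected_edges: float
    oe_ratio: float
    avg_degree: float
    avg_clustering: float
    ppi_p: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "observed_edges": self.observed_edges,
            "expected_edges": self.expected_edges,
            "oe_ratio": self.oe_ratio,
            "avg_degree": self.avg_degree,
            "avg_clustering": self.avg_clustering,
            "ppi_p": self.ppi_p,
        }


@dataclass
class BridgeResult:
    """Minimal connector set between the two seeds in one tissue graph."""

    tissue_id: str
    connector_ids: set[str]
    n_connectors: int
    bridged: bool


@dataclass
class FrequencyTable:
    """Cross-tissue census of connector proteins.

    ``counts`` maps each protein that bridged at least once to the
    number of tissues it appeared in.  ``selected`` holds the proteins
    whose count exceeds mean + 2 SD (population SD over observed
    connectors); SEM is reported alongside for comparability.
    """

    counts: dict[str, int]
    n_tissues: int
    mean: float
    sd: float
    sem: float
    selected: set[str] = field(default_factory=set)

    def selected_at(self, k: float) -> set[str]:
        """Proteins with count > mean + k*SD (k=2 reproduces ``selected``)."""
        thr = self.mean + k * self.sd
        return {p for p, c in self.counts.items() if c > thr}

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(sorted(self.counts.items()),
                           columns=["protein_id", "n_tissues_included"])
        out["selected"] = out["protein_id"].isin(self.selected)
        return out.sort_values(["n_tissues_included", "protein_id"],
                               ascending=[False, True], ignore_index=True)


def _check_graph(g: nx.Graph) -> None:
    for u, v, d in g.edges(data=True):
        c = d.get("confidence", 1.0)
        if not 0.0 <= c <= 1.0:
            raise InputError(f"edge ({u}, {v}) confidence {c} outside [0, 1]")


def neighborhood_network(seed_id: str, background: nx.Graph, k: int = 100) -> nx.Graph:
    """Subgraph induced by a seed plus its k strongest neighbors.

    Neighbors rank by descending edge confidence with ascending-ID
    tie-break; the induced subgraph keeps all edges among the chosen
    nodes.
    """
    seed_id = normalize_id(seed_id)
    if seed_id not in background:
        raise InputError(f"seed {seed_id!r} absent from background graph")
    neighbors = sorted(
        background[seed_id],
        key=lambda n: (-background[seed_id][n].get("confidence", 1.0), n),
    )[:k]
    return background.subgraph([seed_id, *neighbors]).copy()


def network_stats(node_set, background: nx.Graph) -> NetworkStats:
    """Descriptive statistics of the subgraph induced by ``node_set``.

    ``expected_edges`` is C(n,2) times the global edge density of the
    background; ``ppi_p`` is the upper-tail binomial probability of at
    least the observed number of edges in C(n,2) trials at that density.
    Degree-<2 nodes contribute clustering 0.
    """
    nodes = {normalize_id(n) for n in node_set}
    missing = nodes - set(background.nodes)
    if missing:
        raise InputError(f"nodes absent from background: {sorted(missing)[:5]}")
    n = len(nodes)
    if n < 2:
        raise DegenerateInputError("need >= 2 nodes for network statistics")
    n_bg = background.number_of_nodes()
    density = background.number_of_edges() / math.comb(n_bg, 2)
    if density == 0:
        raise DegenerateInputError("background graph has no edges")
    sub = background.subgraph(nodes)
    observed = sub.number_of_edges()
    pairs = math.comb(n, 2)
    expected = pairs * density
    return NetworkStats(
        n_nodes=n,
        observed_edges=observed,
        expected_edges=expected,
        oe_ratio=observed / expected,
        avg_degree=2.0 * observed / n,
        avg_clustering=nx.average_clustering(sub, count_zeros=True),
        ppi_p=float(stats.binom.sf(observed - 1, pairs, density)),
    )


#: statistics where a *small* value is the extreme (significant) direction
_LOWER_TAIL_STATS = frozenset({"ppi_p"})


def compare_to_random_networks(node_set, background: nx.Graph,
                               n_rand: int = 1000, seed: int | None = None
                               ) -> pd.DataFrame:
    """Empirical significance of subgraph statistics vs random node sets.

    Each statistic of ``node_set`` is compared against ``n_rand``
    equal-size uniform random node sets from the background; empirical p
    uses the +1 correction, upper-tailed except for ``ppi_p`` where
    smaller is more extreme.  Returns a DataFrame indexed by statistic
    with observed value, null mean/SD, and empirical p.
    """
    if n_rand < 1:
        raise InputError("n_rand must be >= 1")
    obs = network_stats(node_set, background).as_dict()
    # n_nodes and expected_edges are fixed by the set size; nothing to test
    del obs["n_nodes"], obs["expected_edges"]
    size = len({normalize_id(n) for n in node_set})
    all_nodes = sorted(background.nodes)
    rng = np.random.default_rng(seed)
    null: dict[str, list[float]] = {k: [] for k in obs}
    for _ in range(n_rand):
        idx = rng.choice(len(all_nodes), size=size, replace=False)
        s = network_stats([all_nodes[i] for i in idx], background).as_dict()
        for k in null:
            null[k].append(s[k])
    rows = []
    for stat, observed in obs.items():
        draws = np.asarray(null[stat])
        if stat in _LOWER_TAIL_STATS:
            b = int(np.sum(draws <= observed))
        else:
            b = int(np.sum(draws >= observed))
        rows.append((stat, observed, float(draws.mean()),
                     float(draws.std(ddof=1)) if n_rand > 1 else 0.0,
                     (b + 1) / (n_rand + 1)))
    return pd.DataFrame(rows, columns=["statistic", "observed", "null_mean",
                                       "null_sd", "empirical_p"]
                        ).set_index("statistic")


def _path_conf(g: nx.Graph, path: list[str]) -> float:
    return sum(g[u][v].get("confidence", 1.0) for u, v in zip(path, path[1:]))


def bridge_seeds(seed_a: str, seed_b: str, tissue: nx.Graph,
                 max_nodes: int = 20, min_confidence: float = 0.9,
                 max_paths: int = 1000) -> BridgeResult:
    """Minimal connectors between two seeds in one tissue graph.

    Edges below ``min_confidence`` are discarded.  Simple seed-to-seed
    paths are enumerated in a deterministic order — ascending length,
    then descending total edge confidence, then lexicographic node
    sequence — and the intermediate nodes of successive paths are pooled
    while the total node count (connectors plus both seeds) stays within
    ``max_nodes``; the first path that would overflow the budget stops
    the enumeration.  ``max_paths`` caps the number of paths examined so
    dense graphs stay tractable.  A missing seed or no feasible path
    yields ``bridged=False`` rather than an exception.
    """
    if max_nodes < 2:
        raise InputError("max_nodes must be >= 2")
    if not 0.0 <= min_confidence <= 1.0:
        raise InputError("min_confidence must be in [0, 1]")
    seed_a, seed_b = normalize_id(seed_a), normalize_id(seed_b)
    if seed_a == seed_b:
        raise InputError("seed proteins must differ")
    tissue_id = tissue.graph.get("tissue_id", "")
    if seed_a not in tissue or seed_b not in tissue:
        logger.info("tissue %s: seed absent, not bridged", tissue_id)
        return BridgeResult(tissue_id, set(), 0, False)

    h = nx.Graph()
    h.add_nodes_from(tissue.nodes)
    for u, v, d in tissue.edges(data=True):
        if d.get("confidence", 1.0) >= min_confidence:
            h.add_edge(u, v, confidence=d.get("confidence", 1.0))
    if not nx.has_path(h, seed_a, seed_b):
        return BridgeResult(tissue_id, set(), 0, False)

    budget = max_nodes - 2
    connectors: set[str] = set()
    bridged = False
    gen = nx.shortest_simple_paths(h, seed_a, seed_b)
    examined = 0
    buffer: list[list[str]] = []
    buffer_len: int | None = None
    stop = False

    def flush(paths: list[list[str]]) -> None:
        nonlocal connectors, bridged, stop
        for path in sorted(paths, key=lambda p: (-_path_conf(h, p), tuple(p))):
            inter = set(path[1:-1])
            if len(connectors | inter) <= budget:
                connectors |= inter
                bridged = True
            else:
                stop = True
                return

    for path in gen:
        if examined >= max_paths:
            break
        examined += 1
        if buffer_len is None or len(path) == buffer_len:
            buffer_len = len(path)
            buffer.append(path)
            continue
        flush(buffer)
        if stop:
            buffer = []
            break
        buffer, buffer_len = [path], len(path)
    if buffer and not stop:
        flush(buffer)

    return BridgeResult(tissue_id, connectors, len(connectors), bridged)


def bridge_tissues(seed_a: str, seed_b: str, tissues,
                   max_nodes: int = 20, min_confidence: float = 0.9,
                   max_paths: int = 1000) -> list[BridgeResult]:
    """Apply :func:`bridge_seeds` across a list of tissue graphs."""
    return [bridge_seeds(seed_a, seed_b, t, max_nodes=max_nodes,
                         min_confidence=min_confidence, max_paths=max_paths)
            for t in tissues]


def bridge_frequency(results: list[BridgeResult]) -> FrequencyTable:
    """Cross-tissue connector census with mean + 2 SD selection.

    Counts how many tissues each connector protein appears in; only
    proteins observed in at least one bridge enter the census.  The mean
    and population SD are taken over the observed connector proteins,
    SEM = SD / sqrt(#proteins), and ``selected`` holds the proteins more
    than two SD above the mean.
    """
    if not any(r.bridged for r in results):
        raise InputError("no tissue was successfully bridged")
    counts: dict[str, int] = {}
    for r in results:
        for p in r.connector_ids:
            counts[p] = counts.get(p, 0) + 1
    n_tissues = len(results)
    if counts:
        values = np.array(list(counts.values()), dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=0))
        sem = sd / math.sqrt(len(values))
    else:
        mean = sd = sem = 0.0
    table = FrequencyTable(counts, n_tissues, mean, sd, sem)
    table.selected = table.selected_at(2.0)
    return table
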