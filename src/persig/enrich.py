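"""Gene-set statistics on ranked profiles and ID lists.

Two complementary tests:

* **KS running-sum enrichment** on a ranked profile — walking down the
  ranking, the running sum gains 1/Nh at each set member ("hit") and
  loses 1/(N-Nh) at each non-member.  The enrichment score ``es`` is the
  signed maximum deviation from zero; the *leading edge* is the set
  members at or before the extremum (after it for negative scores).
  Significance comes from gene-label permutation with the +1-corrected
  empirical p.  This is the classic unweighted statistic; a weighted
  variant (running sum increments proportional to |score|) is available
  behind a flag.
* **Over-representation analysis (ORA)** — upper-tail hypergeometric
  probability of the observed query/set overlap within a finite
  universe, Benjamini-Hochberg corrected across a collection.

Collections of significant sets can additionally be ranked (best-match
table) and clustered by Jaccard distance with average linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InputError
from .genesets import GeneSet, GeneSetCollection, normalize_id

logger = logging.getLogger(__name__)


@dataclass
class KsResult:
    """One KS enrichment call: signed score, permutation p, leading edge."""

    set_name: str
    es: float
    p: float
    leading_edge: list[str]
    n_hits: int
    n_perm: int
    fdr_q: float = float("nan")


def _running_sum_extrema(hit_pos: np.ndarray, n: int, n_hits: int):
    """Signed extrema of the unweighted running sum from sorted hit ranks.

    The maximum can only occur immediately after a hit and the minimum
    immediately before one, so both are computed from the Nh hit
    positions alone (O(Nh) instead of O(N)).
    """
    j = np.arange(1, n_hits + 1)
    miss_step = 1.0 / (n - n_hits)
    # value just after the j-th hit / just before it
    after = j / n_hits - (hit_pos + 1 - j) * miss_step
    before = (j - 1) / n_hits - (hit_pos + 1 - j) * miss_step
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    return float(after[i_max]), int(hit_pos[i_max]), float(before[i_min]), int(hit_pos[i_min])


def _es_from_positions(hit_pos: np.ndarray, n: int) -> tuple[float, int, int]:
    """(es, peak_rank, sign) for sorted 0-based hit positions."""
    n_hits = hit_pos.size
    vmax, argmax, vmin, argmin = _running_sum_extrema(hit_pos, n, n_hits)
    # exact ties (|max| == |min| up to rounding) resolve to the positive
    # extremum; true gaps are >= 1/(Nh*(N-Nh)), far above the tolerance
    if vmax >= -vmin - 1e-9:
        return vmax, argmax, +1
    return vmin, argmin, -1


def _perm_es(rng: np.random.Generator, n: int, n_hits: int, n_perm: int) -> np.ndarray:
    """|es| under gene-label permutation (random hit positions)."""
    out = np.empty(n_perm)
    j = np.arange(1, n_hits + 1)
    miss_step = 1.0 / (n - n_hits)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=n_hits, replace=False))
        after = j / n_hits - (pos + 1 - j) * miss_step
        before = (j - 1) / n_hits - (pos + 1 - j) * miss_step
        out[i] = max(after.max(), -before.min())
    return out


def ks_enrichment(ranked, gene_set: GeneSet, n_perm: int = 1000,
                  seed: int | None = None, weights=None) -> KsResult:
    """KS running-sum enrichment of one gene set on a ranked ID list.

    ``ranked`` is an ordered ID sequence (best rank first) or a mean
    profile DataFrame with a ``rank`` column.  ``n_perm`` gene-label
    permutations give the two-sided empirical p on |es| with the +1
    correction; ``n_perm=0`` computes the score only (p = NaN).  With
    ``weights`` (a score per ranked ID, e.g. the profile itself) the
    weighted variant is used for the observed score.
    """
    ids = _as_ranked_ids(ranked)
    n = len(ids)
    members = gene_set.members
    hits = np.array([i for i, g in enumerate(ids) if normalize_id(g) in members])
    n_hits = hits.size
    if n_hits == 0:
        raise DegenerateInputError(f"set {gene_set.name!r} has no member in the "
                                   "ranked universe")
    if n_hits == n:
        raise DegenerateInputError(f"set {gene_set.name!r} covers the whole universe")

    if weights is not None:
        es, peak, sign = _weighted_es(ids, hits, np.asarray(weights, dtype=float))
    else:
        es, peak, sign = _es_from_positions(hits, n)

    if sign > 0:
        leading = [ids[i] for i in hits if i <= peak]
    else:
        leading = [ids[i] for i in hits if i >= peak]

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null_abs = _perm_es(rng, n, n_hits, n_perm)
        b = int(np.sum(null_abs >= abs(es)))
        p = (b + 1) / (n_perm + 1)
    else:
        p = float("nan")
    return KsResult(gene_set.name, es, p, leading, n_hits, n_perm)


def _weighted_es(ids, hits, scores) -> tuple[float, int, int]:
    """Weighted running sum: hit increments proportional to |score|."""
    n = len(ids)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[hits] = True
    w = np.abs(scores)
    denom = w[is_hit].sum()
    if denom == 0:
        raise DegenerateInputError("all hit weights are zero")
    steps = np.where(is_hit, w / denom, -1.0 / (n - is_hit.sum()))
    rs = np.cumsum(steps)
    i_max, i_min = int(np.argmax(rs)), int(np.argmin(rs))
    if rs[i_max] >= -rs[i_min] - 1e-9:
        return float(rs[i_max]), i_max, +1
    return float(rs[i_min]), i_min, -1


def _as_ranked_ids(ranked) -> list[str]:
    if isinstance(ranked, pd.DataFrame):
        if "rank" in ranked.columns:
            return [normalize_id(i) for i in ranked.sort_values("rank").index]
        return [normalize_id(i) for i in ranked.index]
    ids = [normalize_id(i) for i in ranked]
    if len(set(ids)) != len(ids):
        raise InputError("ranked universe contains duplicate IDs")
    return ids


def ora_enrichment(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in a collection.

    Query members outside the universe are dropped (and logged); each
    set is likewise restricted to the universe.  p is the upper-tail
    probability of an overlap at least as large as observed; BH FDR is
    applied across the collection.  The table is sorted by ascending p
    with set-name tie-break.
    """
    uni = {normalize_id(u) for u in universe}
    if not uni:
        raise InputError("empty universe")
    q = {normalize_id(g) for g in query}
    outside = q - uni
    if outside:
        logger.info("dropping %d query IDs outside the universe", len(outside))
        q &= uni
    n_query, n_uni = len(q), len(uni)

    rows = []
    for gs in collection:
        m = gs.members & uni
        k = len(q & m)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(m), n_query))
        rows.append((gs.name, k, n_query, len(m), n_uni, p))
    out = pd.DataFrame(rows, columns=["set_name", "k_overlap", "n_query",
                                      "m_set", "N_universe", "p"])
    if len(out):
        out["fdr_q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["p", "set_name"], kind="mergesort",
                              ignore_index=True)
    else:
        out["fdr_q"] = pd.Series(dtype=float)
    return out


def rank_collections(query_or_ranked, collection: GeneSetCollection,
                     n_perm: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Best-match table of a signature against every set in a collection.

    An ordered profile (DataFrame or sequence) is scored per set with
    :func:`ks_enrichment` (sets with no member in the universe are
    skipped with a warning); an unordered ID set is scored with
    :func:`ora_enrichment`.  Rows are ordered by significance, then by
    |es| (or overlap), then set name; ``rank`` starts at 1.
    """
    if len(collection) == 0:
        raise InputError("empty collection")
    if isinstance(query_or_ranked, (set, frozenset)):
        if not query_or_ranked:
            raise InputError("empty query set")
        universe = _collection_universe(collection) | {normalize_id(g)
                                                       for g in query_or_ranked}
        out = ora_enrichment(query_or_ranked, collection, universe)
        out = out.sort_values(["p", "k_overlap", "set_name"],
                              ascending=[True, False, True], kind="mergesort",
                              ignore_index=True)
        out["rank"] = np.arange(1, len(out) + 1)
        return out

    ids = _as_ranked_ids(query_or_ranked)
    if not ids:
        raise InputError("empty ranked profile")
    rows = []
    rng = np.random.default_rng(seed)
    for gs in collection:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            r = ks_enrichment(ids, gs, n_perm=n_perm, seed=sub_seed)
        except DegenerateInputError as exc:
            logger.warning("skipping set %s: %s", gs.name, exc)
            continue
        rows.append((gs.name, r.es, r.p, r.n_hits, len(r.leading_edge)))
    out = pd.DataFrame(rows, columns=["set_name", "es", "p", "n_hits",
                                      "n_leading_edge"])
    if len(out):
        out["fdr_q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["abs_es"] = out["es"].abs()
        out = out.sort_values(["p", "abs_es", "set_name"],
                              ascending=[True, False, True], kind="mergesort",
                              ignore_index=True).drop(columns="abs_es")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _collection_universe(collection: GeneSetCollection) -> set[str]:
    uni: set[str] = set()
    for gs in collection:
        uni |= gs.members
    return uni


@dataclass
class ClusterResult:
    """Average-linkage clustering of gene sets by Jaccard distance."""

    set_names: list[str]
    distance: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    excluded: list[str] = field(default_factory=list)

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters,
                                    criterion="maxclust")
        return dict(zip(self.set_names, (int(l) for l in labels)))


def jaccard_distance(a: GeneSet, b: GeneSet, universe=None) -> float:
    """1 - |A∩B| / |A∪B| on set members (optionally within a universe)."""
    ma, mb = a.members, b.members
    if universe is not None:
        uni = {normalize_id(u) for u in universe}
        ma, mb = ma & uni, mb & uni
    union = ma | mb
    if not union:
        raise DegenerateInputError("both sets empty in the universe")
    return 1.0 - len(ma & mb) / len(union)


def cluster_gene_sets(sets: list[GeneSet], universe=None) -> ClusterResult:
    """Hierarchically cluster gene sets by member overlap.

    Pairwise Jaccard distances feed scipy average linkage; sets with no
    members in the universe are excluded (and logged).  The leaf order
    is deterministic given the inputs.
    """
    uni = {normalize_id(u) for u in universe} if universe is not None else None
    kept, excluded = [], []
    for s in sets:
        members = s.members if uni is None else s.members & uni
        if members:
            kept.append(GeneSet(s.name, s.description, members))
        else:
            excluded.append(s.name)
            logger.warning("excluding set %s: no members in universe", s.name)
    if len(kept) < 2:
        raise InputError("need >= 2 sets with members to cluster")
    names = [s.name for s in kept]
    n = len(kept)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = jaccard_distance(kept[i], kept[j])
    linkage = hierarchy.average(squareform(dist, checks=False))
    leaves = hierarchy.leaves_list(linkage)
    return ClusterResult(
        set_names=names,
        distance=pd.DataFrame(dist, index=names, columns=names),
        linkage=linkage,
        leaf_order=[names[i] for i in leaves],
        excluded=excluded,
    )
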