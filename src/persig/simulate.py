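"""Synthetic data generators for the whole pipeline.

The generators emulate a dose-series perturbagen proteomics experiment:
a receptor is over-expressed at graded cDNA doses, three detergent-based
compartment extracts (cytoplasm, plasma membrane, nucleus/organelle) are
quantified label-free against paired mock transfections, and downstream
analyses consume the resulting intensity matrix together with gene-set
collections and tissue-specific interaction graphs.  Every generator is a
pure function of its config and seed, and returns the planted ground truth
alongside the data so recovery can be scored exactly.

Defaults mirror the study design being emulated: ~2,500 quantified
proteins, five doses (0.5, 1, 2, 5, 10 arbitrary cDNA units), three
compartment extracts, a down-dominant effect polarity (60% of planted
effects negative), and a 142-tissue graph census for the bridging
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .genesets import GeneSet, GeneSetCollection, normalize_id

DEFAULT_DOSES = (0.5, 1.0, 2.0, 5.0, 10.0)
DEFAULT_COMPARTMENTS = ("cytoplasm", "membrane", "nucleus")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated dose-series perturbagen experiment.

    Parameters
    ----------
    n_proteins:
        Number of quantified proteins (rows). Must be >= 10.
    doses:
        Dose labels in arbitrary units; one case/mock pair per dose and
        compartment.
    compartments:
        Compartment-extract labels.
    n_replicates:
        Replicates per (condition, dose, compartment) cell.
    dep_fraction:
        Fraction of proteins planted with a true expression effect.
    effect_size_log2:
        Absolute planted effect on the log2 scale (before dose scaling).
    down_fraction:
        Probability a planted effect is negative (down-regulated).
    noise_sd_log2:
        Replicate noise SD on the log2 scale.
    missing_rate:
        Probability a measured intensity is missing completely at random.
    dose_scaling:
        ``"log"`` scales planted effect magnitude linearly in log-dose
        (normalised so the highest dose has scale 1); ``"none"`` applies
        the full effect at every dose.
    seed:
        RNG seed; identical seeds give bit-identical outputs.
    """

    n_proteins: int = 2500
    doses: tuple[float, ...] = DEFAULT_DOSES
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    n_replicates: int = 3
    dep_fraction: float = 0.15
    effect_size_log2: float = 1.5
    down_fraction: float = 0.6
    noise_sd_log2: float = 0.4
    missing_rate: float = 0.05
    baseline_mean_log2: float = 20.0
    baseline_sd_log2: float = 2.0
    dose_scaling: str = "log"
    seed: int = 0

    def __post_init__(self):
        for name in ("dep_fraction", "down_fraction", "missing_rate",
                     "effect_size_log2", "noise_sd_log2",
                     "baseline_mean_log2", "baseline_sd_log2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigError(f"{name} must be finite, got {v!r}")
        for name in ("dep_fraction", "down_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd_log2 <= 0:
            raise ConfigError("noise_sd_log2 must be > 0")
        if self.effect_size_log2 < 0:
            raise ConfigError("effect_size_log2 must be >= 0")
        if self.n_proteins < 10:
            raise ConfigError("n_proteins must be >= 10")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if len(self.doses) < 1 or len(self.compartments) < 1:
            raise ConfigError("need at least one dose and one compartment")
        if self.dose_scaling not in ("log", "none"):
            raise ConfigError("dose_scaling must be 'log' or 'none'")
        # tuples keep the config hashable and frozen
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        object.__setattr__(self, "compartments", tuple(self.compartments))


@dataclass
class IntensityMatrix:
    """Protein x sample quantification table with sample annotations.

    ``values`` is a DataFrame indexed by protein ID with one column per
    sample (missing values as NaN, observed values nonnegative).
    ``samples`` is indexed by sample ID with columns
    ``condition`` ("case"/"mock"), ``dose``, ``compartment``,
    ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise InputError("duplicate protein IDs in intensity matrix")
        missing_cols = {"condition", "dose", "compartment", "replicate"}
        missing_cols -= set(self.samples.columns)
        if missing_cols:
            raise InputError(f"sample annotation lacks columns {sorted(missing_cols)}")
        if not self.values.columns.equals(self.samples.index):
            raise InputError("sample annotation does not match matrix columns")
        if self.samples[["condition", "dose", "compartment", "replicate"]].isna().any().any():
            raise InputError("incomplete sample annotation")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise InputError("negative intensities")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    def select(self, condition=None, dose=None, compartment=None) -> list[str]:
        """Sample IDs matching the given annotation values."""
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if dose is not None:
            mask &= self.samples["dose"] == dose
        if compartment is not None:
            mask &= self.samples["compartment"] == compartment
        return list(self.samples.index[mask])


@dataclass
class GroundTruth:
    """Planted signal labels for recovery scoring.

    ``dep_effects`` maps (dose, compartment) to {protein ID -> signed log2
    effect actually applied in that cell}.  ``planted_sets`` and
    ``planted_bridges`` record the names/IDs planted by the gene-set and
    tissue-graph generators.
    """

    dep_effects: dict[tuple[float, str], dict[str, float]] = field(default_factory=dict)
    planted_sets: list[str] = field(default_factory=list)
    planted_bridges: list[str] = field(default_factory=list)

    def dep_ids(self, dose: float, compartment: str) -> set[str]:
        return set(self.dep_effects.get((dose, compartment), {}))


def _protein_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _dose_scale(dose: float, doses: tuple[float, ...], mode: str) -> float:
    if mode == "none":
        return 1.0
    lo, hi = min(doses), max(doses)
    if hi == lo:
        return 1.0
    # linear in log-dose, anchored so the lowest dose keeps a nonzero effect
    return (1.0 + math.log2(dose / lo)) / (1.0 + math.log2(hi / lo))


def simulate_perturbagen_experiment(config: SimConfig) -> tuple[IntensityMatrix, GroundTruth]:
    """Simulate the case/mock intensity matrix of a dose-series screen.

    Baseline log2 intensities are drawn per protein from
    Normal(baseline_mean_log2, baseline_sd_log2) and shared between case
    and mock.  A ``dep_fraction`` subset of proteins carries a planted
    effect of ``effect_size_log2`` (negative with probability
    ``down_fraction``), applied to case samples only and scaled per dose.
    Gaussian replicate noise is added on the log2 scale, intensities are
    exponentiated back, and values are removed completely at random at
    ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    ids = _protein_ids(config.n_proteins)
    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2,
                          config.n_proteins)

    n_dep = int(round(config.dep_fraction * config.n_proteins))
    dep_idx = np.sort(rng.choice(config.n_proteins, size=n_dep, replace=False))
    signs = np.where(rng.random(n_dep) < config.down_fraction, -1.0, 1.0)
    effect = np.zeros(config.n_proteins)
    effect[dep_idx] = signs * config.effect_size_log2

    columns, col_data, annotations = [], [], []
    truth = GroundTruth()
    for dose in config.doses:
        scale = _dose_scale(dose, config.doses, config.dose_scaling)
        for comp in config.compartments:
            cell_effect = effect * scale
            truth.dep_effects[(dose, comp)] = {
                ids[i]: cell_effect[i] for i in dep_idx
            }
            for condition in ("case", "mock"):
                shift = cell_effect if condition == "case" else 0.0
                for rep in range(1, config.n_replicates + 1):
                    log2_vals = (baseline + shift
                                 + rng.normal(0.0, config.noise_sd_log2,
                                              config.n_proteins))
                    vals = np.exp2(log2_vals)
                    if config.missing_rate > 0:
                        mask = rng.random(config.n_proteins) < config.missing_rate
                        vals = np.where(mask, np.nan, vals)
                    sid = f"{condition}_d{dose:g}_{comp}_r{rep}"
                    columns.append(sid)
                    col_data.append(vals)
                    annotations.append((sid, condition, dose, comp, rep))

    values = pd.DataFrame(np.column_stack(col_data), index=ids, columns=columns)
    samples = pd.DataFrame(annotations,
                           columns=["sample_id", "condition", "dose",
                                    "compartment", "replicate"]).set_index("sample_id")
    return IntensityMatrix(values, samples), truth


def simulate_gene_set_collection(universe, n_sets: int,
                                 set_size_range: tuple[int, int] = (15, 200),
                                 planted=None, seed: int = 0,
                                 name: str = "simulated") -> GeneSetCollection:
    """Random background gene sets plus optional planted enriched sets.

    ``planted`` is a list of ``(set_name, dep_ids, purity)`` triples: the
    planted set has the size of ``dep_ids``; each slot is filled from
    ``dep_ids`` with probability ``purity`` (binomially) and from the rest
    of the universe otherwise, so purity=1 reproduces ``dep_ids`` exactly.
    Background sets are drawn uniformly from the universe with sizes
    uniform over ``set_size_range``.
    """
    universe = [normalize_id(u) for u in universe]
    if len(set(universe)) != len(universe):
        raise InputError("universe contains duplicate IDs")
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ConfigError(f"set_size_range {set_size_range} incompatible with "
                          f"universe of {len(universe)}")

    collection = GeneSetCollection(name)
    for set_name, dep_ids, purity in (planted or []):
        if not 0.0 <= purity <= 1.0:
            raise ConfigError(f"purity must be in [0, 1], got {purity}")
        dep_ids = [normalize_id(d) for d in dep_ids]
        missing = set(dep_ids) - set(universe)
        if missing:
            raise InputError(f"planted IDs outside universe: {sorted(missing)[:5]}")
        size = len(dep_ids)
        n_from_dep = int(rng.binomial(size, purity))
        members = list(rng.choice(dep_ids, size=n_from_dep, replace=False))
        background_pool = sorted(set(universe) - set(dep_ids))
        members += list(rng.choice(background_pool, size=size - n_from_dep,
                                   replace=False))
        collection.add(GeneSet(set_name, "planted", frozenset(members)))

    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        collection.add(GeneSet(f"BACKGROUND_SET_{i + 1:04d}", "background",
                               frozenset(members)))
    return collection


def simulate_tissue_networks(universe, n_tissues: int = 142,
                             seed_a: str = "MDC1", seed_b: str = "PHB",
                             planted_bridges=(), bridge_tissue_fraction: float = 0.5,
                             edge_density: float = 0.03,
                             seed: int = 0) -> list[nx.Graph]:
    """Independent random tissue graphs with planted bridge hubs.

    Each tissue is an Erdos-Renyi graph over the universe at
    ``edge_density`` with edge confidences uniform on [0.5, 1].  In a
    ``bridge_tissue_fraction`` subset of tissues each planted bridge node
    is wired to both seeds at confidence 1.0 while any direct seed-seed
    edge is suppressed, making the planted nodes recurrent minimal
    connectors.  Graphs carry ``tissue_id`` in ``G.graph``.
    """
    universe = [normalize_id(u) for u in universe]
    seed_a, seed_b = normalize_id(seed_a), normalize_id(seed_b)
    if seed_a == seed_b:
        raise InputError("seed proteins must differ")
    if seed_a not in universe or seed_b not in universe:
        raise InputError("both seed proteins must be in the universe")
    if not 0.0 <= bridge_tissue_fraction <= 1.0:
        raise ConfigError("bridge_tissue_fraction must be in [0, 1]")
    planted_bridges = [normalize_id(b) for b in planted_bridges]
    if set(planted_bridges) - set(universe):
        raise InputError("planted bridges must be in the universe")

    rng = np.random.default_rng(seed)
    n_bridged = int(round(bridge_tissue_fraction * n_tissues))
    bridged_tissues = set(rng.choice(n_tissues, size=n_bridged, replace=False))

    graphs = []
    n = len(universe)
    iu, ju = np.triu_indices(n, k=1)
    for t in range(n_tissues):
        present = rng.random(iu.size) < edge_density
        confs = rng.uniform(0.5, 1.0, iu.size)
        g = nx.Graph(tissue_id=f"tissue_{t + 1:03d}")
        g.add_nodes_from(universe)
        for a, b, c in zip(iu[present], ju[present], confs[present]):
            g.add_edge(universe[a], universe[b], confidence=float(c))
        if t in bridged_tissues and planted_bridges:
            if g.has_edge(seed_a, seed_b):
                g.remove_edge(seed_a, seed_b)
            for bridge in planted_bridges:
                g.add_edge(bridge, seed_a, confidence=1.0)
                g.add_edge(bridge, seed_b, confidence=1.0)
        graphs.append(g)
    return graphs
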