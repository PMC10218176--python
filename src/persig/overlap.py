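"""Monte-Carlo significance of ID-set intersections.

The observed overlap |A∩B| is compared with a null in which one of the
two sets is replaced by a uniform random subset of the universe of the
same size — the randomisation used throughout the source study for
DEP-list vs. signature and interactome vs. interactome comparisons.  The
empirical p uses the +1 correction, (b+1)/(n_rand+1), so it never
returns zero; under uniform sampling the null overlap is hypergeometric,
which the reported null mean/SD can be checked against.

A second null construction for interactome comparisons replaces the
random subsets with *donor* interactomes — pre-supplied interactor lists
of randomly chosen proteins — and scores the observed overlap against
that small empirical distribution (count and percentage).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError
from .genesets import normalize_id

logger = logging.getLogger(__name__)


@dataclass
class OverlapTest:
    """Observed intersection size with its Monte-Carlo null summary."""

    observed_k: int
    null_mean: float
    null_sd: float
    empirical_p: float
    z: float
    n_rand: int
    universe_size: int
    seed: int | None
    size_a: int = 0
    size_b: int = 0
    randomized: str = "A"

    def hypergeom_mean(self) -> float:
        """Closed-form expectation |A|*|B|/N of the uniform null."""
        return self.size_a * self.size_b / self.universe_size

    def hypergeom_sd(self) -> float:
        n, a, b = self.universe_size, self.size_a, self.size_b
        var = (a * b * (n - a) * (n - b)) / (n * n * (n - 1))
        return math.sqrt(var)


@dataclass
class DonorOverlapTest(OverlapTest):
    """Overlap scored against donor interactomes instead of random draws."""

    donor_overlaps: list[int] = field(default_factory=list)
    donor_percents: list[float] = field(default_factory=list)
    observed_percent: float = float("nan")


def _normalize(ids, universe: set[str], label: str) -> set[str]:
    s = {normalize_id(i) for i in ids}
    outside = s - universe
    if outside:
        logger.info("dropping %d %s IDs outside the universe", len(outside), label)
        s &= universe
    return s


def overlap_test(set_a, set_b, universe, randomize: str = "A",
                 n_rand: int = 1000, seed: int | None = None) -> OverlapTest:
    """Monte-Carlo test of |A∩B| against equal-size random subsets.

    ``randomize`` selects which set the null replaces with a uniform
    random subset of the universe of the same size.  Members outside the
    universe are dropped (and logged) before testing.  The empirical p
    is one-sided for over-representation, (b+1)/(n_rand+1) with b the
    number of null overlaps >= the observed one.
    """
    if randomize not in ("A", "B"):
        raise ConfigError("randomize must be 'A' or 'B'")
    if n_rand < 1:
        raise ConfigError("n_rand must be >= 1")
    uni = sorted({normalize_id(u) for u in universe})
    uni_set = set(uni)
    if not uni:
        raise InputError("empty universe")
    a = _normalize(set_a, uni_set, "set A")
    b = _normalize(set_b, uni_set, "set B")
    if len(a) > len(uni) or len(b) > len(uni):
        raise InputError("set larger than universe")

    observed = len(a & b)
    rand_size = len(a) if randomize == "A" else len(b)
    fixed = b if randomize == "A" else a

    rng = np.random.default_rng(seed)
    fixed_mask = np.fromiter((u in fixed for u in uni), dtype=bool, count=len(uni))
    null_k = np.empty(n_rand, dtype=int)
    for i in range(n_rand):
        idx = rng.choice(len(uni), size=rand_size, replace=False)
        null_k[i] = int(fixed_mask[idx].sum())

    null_mean = float(null_k.mean())
    null_sd = float(null_k.std(ddof=1)) if n_rand > 1 else 0.0
    b_count = int(np.sum(null_k >= observed))
    p = (b_count + 1) / (n_rand + 1)
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    return OverlapTest(observed, null_mean, null_sd, p, z, n_rand,
                       len(uni), seed, len(a), len(b), randomize)


def interactome_overlap_test(interactome_a, interactome_b, universe,
                             mode: str = "random_lists", donors=None,
                             n_rand: int = 1000, randomize: str = "A",
                             seed: int | None = None) -> OverlapTest:
    """Interactome-vs-interactome overlap under one of two nulls.

    ``mode="random_lists"`` replaces one interactome with same-size
    uniform random ID lists (delegates to :func:`overlap_test`).
    ``mode="random_seed_proteins"`` scores the observed overlap against
    the overlaps of pre-supplied *donor* interactomes (the interactor
    lists of randomly chosen proteins) with interactome B, reporting the
    donor counts and percentage overlaps alongside the +1-corrected
    empirical p.
    """
    if mode == "random_lists":
        return overlap_test(interactome_a, interactome_b, universe,
                            randomize=randomize, n_rand=n_rand, seed=seed)
    if mode != "random_seed_proteins":
        raise ConfigError(f"unknown mode {mode!r}")
    if not donors:
        raise InputError("mode 'random_seed_proteins' requires donor interactomes")

    uni_set = {normalize_id(u) for u in universe}
    a = _normalize(interactome_a, uni_set, "interactome A")
    b = _normalize(interactome_b, uni_set, "interactome B")
    observed = len(a & b)
    donor_sets = [_normalize(d, uni_set, "donor") for d in donors]
    donor_k = [len(d & b) for d in donor_sets]
    donor_pct = [100.0 * k / len(d) if d else 0.0
                 for k, d in zip(donor_k, donor_sets)]
    exceed = sum(1 for k in donor_k if k >= observed)
    p = (exceed + 1) / (len(donor_k) + 1)
    mean = float(np.mean(donor_k))
    sd = float(np.std(donor_k, ddof=1)) if len(donor_k) > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else float("nan")
    return DonorOverlapTest(
        observed_k=observed, null_mean=mean, null_sd=sd, empirical_p=p, z=z,
        n_rand=len(donor_k), universe_size=len(uni_set), seed=seed,
        size_a=len(a), size_b=len(b), randomized="A",
        donor_overlaps=donor_k, donor_percents=donor_pct,
        observed_percent=100.0 * observed / len(a) if a else float("nan"),
    )


def simulate_interactome(universe, size_a: int, size_b: int,
                         shared_fraction: float, seed: int | None = None
                         ) -> tuple[set[str], set[str]]:
    """Two ID sets with a controlled forced overlap.

    Exactly ``round(shared_fraction * min(size_a, size_b))`` members are
    common; the remainders are sampled disjointly from the rest of the
    universe.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ConfigError("shared_fraction must be in [0, 1]")
    uni = sorted({normalize_id(u) for u in universe})
    n_shared = int(round(shared_fraction * min(size_a, size_b)))
    if size_a + size_b - n_shared > len(uni):
        raise InputError("sizes infeasible for this universe")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(uni), size=size_a + size_b - n_shared, replace=False)
    shared = {uni[i] for i in picks[:n_shared]}
    only_a = {uni[i] for i in picks[n_shared:n_shared + size_a - n_shared]}
    only_b = {uni[i] for i in picks[n_shared + size_a - n_shared:]}
    return shared | only_a, shared | only_b
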