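"""Differential-expression calling on case/mock intensity matrices.

A protein is a differentially expressed protein (DEP) for one
(dose, compartment) contrast when its case/mock log2 intensity ratio
deviates significantly from the global mean of all ratios in that
contrast: z = (ratio - global mean) / global SD, with a two-sided normal
p-value and call at p <= alpha (default 0.05, uncorrected; BH FDR
available as an option).  Polarity is the sign of the deviation from the
global mean.  Downstream summaries are the cross-compartment mean profile
(a ranked signature) and the dose-independent "consistency core" of
proteins called at every dose.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InputError
from .simulate import IntensityMatrix

logger = logging.getLogger(__name__)

DEP_COLUMNS = ["log2_ratio", "z", "p", "is_dep", "polarity"]


def compute_log_ratios(matrix: IntensityMatrix, dose, compartment) -> pd.DataFrame:
    """Per-protein log2(case mean / mock mean) for one (dose, compartment).

    Only observed (non-missing) replicate intensities enter the means; a
    protein is reported only when it has at least one observed case and
    one observed mock value.  Returns a DataFrame indexed by protein ID
    with columns ``log2_ratio``, ``n_case``, ``n_mock``, ``n_used``;
    the number of dropped proteins is recorded in ``.attrs["n_dropped"]``.
    """
    case_cols = matrix.select("case", dose, compartment)
    mock_cols = matrix.select("mock", dose, compartment)
    if not case_cols or not mock_cols:
        raise InputError(f"no case/mock samples for dose={dose!r}, "
                         f"compartment={compartment!r}")
    case = matrix.values[case_cols]
    mock = matrix.values[mock_cols]
    n_case = case.notna().sum(axis=1)
    n_mock = mock.notna().sum(axis=1)
    ok = (n_case >= 1) & (n_mock >= 1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d proteins without observations on both sides "
                    "(dose=%s, compartment=%s)", n_dropped, dose, compartment)
    ratios = np.log2(case[ok].mean(axis=1) / mock[ok].mean(axis=1))
    out = pd.DataFrame({
        "log2_ratio": ratios,
        "n_case": n_case[ok].astype(int),
        "n_mock": n_mock[ok].astype(int),
    })
    out["n_used"] = out["n_case"] + out["n_mock"]
    out.index.name = "protein_id"
    out.attrs["n_dropped"] = n_dropped
    out.attrs["dose"] = dose
    out.attrs["compartment"] = compartment
    return out


def call_deps(ratios: pd.DataFrame, alpha: float = 0.05,
              fdr: bool = False) -> pd.DataFrame:
    """Call DEPs against the global log2-ratio distribution.

    z standardises each ratio against the mean and SD of all ratios in
    the contrast; p is the two-sided standard-normal tail.  ``is_dep``
    holds where p <= alpha (on BH q-values instead when ``fdr=True``);
    ``polarity`` is "up" where the ratio exceeds the global mean, "down"
    otherwise.
    """
    if not 0 < alpha <= 1:
        raise InputError(f"alpha must be in (0, 1], got {alpha}")
    if len(ratios) < 3:
        raise InputError("need >= 3 proteins to define the global distribution")
    r = ratios["log2_ratio"].astype(float)
    mean, sd = r.mean(), r.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("global SD of log2 ratios is zero")
    z = (r - mean) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = ratios.copy()
    out["z"] = z
    out["p"] = p
    if fdr:
        out["fdr_q"] = multipletests(p, method="fdr_bh")[1]
        out["is_dep"] = out["fdr_q"] <= alpha
    else:
        out["is_dep"] = out["p"] <= alpha
    out["polarity"] = np.where(r > mean, "up", "down")
    out.attrs.update(ratios.attrs)
    out.attrs["alpha"] = alpha
    out.attrs["global_mean"] = float(mean)
    out.attrs["global_sd"] = float(sd)
    return out


def dep_ids(dep_table: pd.DataFrame) -> set[str]:
    """IDs of the proteins called DEP in a table."""
    return set(dep_table.index[dep_table["is_dep"]])


def mean_profile(dep_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean log2 ratio across compartment extracts, ranked descending.

    Covers the union of proteins quantified in at least one table; the
    mean is taken over available tables only.  Rank 1 is the largest mean
    ratio; ties break by ascending protein ID so the ranking is total.
    """
    if not dep_tables:
        raise InputError("need at least one DEP table")
    ratios = pd.concat([t["log2_ratio"] for t in dep_tables], axis=1)
    out = pd.DataFrame({
        "mean_log2_ratio": ratios.mean(axis=1),
        "n_compartments": ratios.notna().sum(axis=1).astype(int),
    })
    # stable sort on an ID-sorted frame = descending ratio, ascending ID ties
    out = out.reindex(sorted(out.index)).sort_values(
        "mean_log2_ratio", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "protein_id"
    return out


def ranked_ids(profile: pd.DataFrame) -> list[str]:
    """Protein IDs of a mean profile in rank order (best first)."""
    return list(profile.sort_values("rank").index)


def consistency_core(dep_tables: dict[object, pd.DataFrame]) -> tuple[set[str], pd.DataFrame]:
    """Dose-independent DEP core: proteins called at every dose.

    ``dep_tables`` maps dose label -> DEP table for one compartment (or
    pooled).  Returns the intersection of DEP ID sets across all doses
    and a polarity matrix (protein x dose) for the core, retained
    regardless of sign agreement across doses.
    """
    if not dep_tables:
        raise InputError("empty table set")
    if len(dep_tables) < 2:
        raise InputError("need >= 2 dose levels for a consistency core")
    sets = [dep_ids(t) for t in dep_tables.values()]
    core = set.intersection(*sets)
    doses = list(dep_tables)
    polarity = pd.DataFrame(index=sorted(core), columns=doses, dtype=object)
    for dose, table in dep_tables.items():
        polarity[dose] = table.loc[polarity.index, "polarity"]
    polarity.index.name = "protein_id"
    return core, polarity
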