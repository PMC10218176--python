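# Methods

## The experiment being modelled

`persig` analyses a dose-series perturbagen screen: a receptor is ectopically
expressed at five cDNA doses (0.5, 1, 2, 5, 10 arbitrary units), cells are
fractionated into three compartment extracts (cytoplasm, plasma membrane,
nucleus/organelle), and each (dose, compartment) cell is quantified
label-free against a paired mock transfection. The package consumes a
quantified protein × sample intensity matrix; spectra, peptide inference and
between-run normalisation are upstream and out of scope.

## DEP calling

The only distributional statement available for the original calls is a
significance threshold against a "global mean", so the caller takes the
minimal reading: within one (dose, compartment) contrast, the per-protein
log2(case mean / mock mean) ratios form the global distribution, each ratio
is standardised by that distribution's mean and sample SD, and the two-sided
standard-normal tail gives p. Calls are `p ≤ α` with α = 0.05 and **no**
multiple-testing correction by default, matching the emulated analysis;
Benjamini–Hochberg FDR is available behind `call_deps(..., fdr=True)`.
Polarity is the sign of the deviation from the global mean, so "down" at the
boundary (ratio exactly at the mean counts as not-up).

Consequences worth knowing:

* The global mean/SD are computed per contrast, not pooled across
  compartments — each extract has its own chemistry.
* Planted (true) effects inflate the global SD, so power *decreases* as the
  contaminated fraction grows. At a planted effect of 3× the replicate noise
  SD with 3 replicates, the closed-form per-protein power exceeds 90% only
  in a sparse-signal regime; the power checks therefore run at
  `dep_fraction = 0.02`. This is a property of the global-mean method, not
  of the implementation.
* A protein needs ≥ 1 observed value on each side to be reported; missing
  values are never imputed.
* Ties in every ranking break by ascending protein ID after descending
  score, making all orderings total and deterministic.

The per-dose DEP totals reported by the pipeline pool the three compartment
extracts by union; this is flagged in the output metadata. The
dose-independent "consistency core" is the plain n-way intersection of DEP
ID sets across doses, with the polarity matrix retained regardless of sign
agreement, and the core cardinality is always reported as computed, never
assumed.

## KS enrichment

The running sum is the classic unweighted Kolmogorov–Smirnov form: walking
down the ranked profile, +1/Nh at each set member, −1/(N−Nh) otherwise; the
enrichment score is the signed extremum, and the leading edge is the set
members at or before the positive peak (at or after the trough for negative
scores — the negative case is defined symmetrically since only the positive
case is ever illustrated in the emulated analysis). A weighted variant
(increments ∝ |score|) exists behind the `weights` argument but is not the
default. Exact |max| = |min| ties resolve to the positive extremum, compared
with a 1e-9 tolerance; genuine gaps are at least 1/(Nh·(N−Nh)), orders of
magnitude above it.

Significance is by gene-label permutation (random hit positions), the only
permutation unit available post hoc on a ranked profile. The empirical p is
two-sided on |es| with the +1 correction, (b+1)/(n_perm+1): a sign-matched
one-sided p is not uniform under the null, the two-sided form is, and the
uniformity is property-tested. Default n_perm = 1000 (tests use fewer; the
floor 1/(n_perm+1) is then coarser, and best-match ranking falls back to
|es| among p ties).

## ORA, FDR, clustering

Over-representation uses the exact upper-tail hypergeometric probability of
the query/set overlap within the declared universe (scipy), BH-corrected
across the collection (statsmodels). Query or set members outside the
universe are dropped and logged, never silently added. Significance
defaults (q ≤ 0.05) are package conventions, since the emulated analysis
states none. Similarity clustering of sets is average-linkage on pairwise
Jaccard distance (1 − |A∩B|/|A∪B|), with deterministic leaf order.

## Set-overlap significance

The Monte-Carlo null replaces one designated set with a uniform random
subset of the universe of equal size; under this null the overlap is
hypergeometric, and the reported null mean/SD are test-checked against the
closed forms |A||B|/N and its variance. The test is one-sided for
over-representation only. Defaults: n_rand = 1000; a paper-mode n_rand = 10
mirrors the tiny nulls of the emulated comparisons, where the +1 correction
bottoms the p at 1/11. The universe is all quantified proteins unless
overridden; IDs are uppercased, and no alias expansion is attempted. The
donor-interactome mode scores the observed overlap against pre-supplied
interactor lists of randomly chosen proteins (count and percentage), the
second null construction used in the emulated interactome analysis.

## Network statistics and bridging

Expected edges use the background's global edge density, C(n,2)·d — not a
degree-preserving null, which the emulated tool does not document either;
the binomial tail at that density gives the interaction-enrichment p.
Average local clustering counts degree-<2 nodes as zero. The random-network
comparison draws equal-size uniform node sets; empirical p is upper-tailed
for edges/O-E/degree/clustering and lower-tailed for the binomial p, where
small is extreme.

Tissue bridging re-specifies a proprietary network-growing step as a
declared, reproducible rule: on the subgraph of edges with confidence ≥
`min_confidence` (default 0.9, "highest confidence"; the simulations use
0.5 to match their confidence distribution), simple paths between the two
seeds are enumerated in a deterministic order — ascending length, then
descending total edge confidence, then lexicographic node sequence — and
intermediate nodes are pooled while the total node count stays within
`max_nodes` (default 20, counting both seeds); the first overflowing path
stops the enumeration. Because exhaustive simple-path enumeration is
unbounded in dense graphs, a `max_paths` cap (default 1000, in enumeration
order, hence deterministic) bounds the work; the brute-force oracle test
runs uncapped on 12-node graphs where the enumeration is complete.

The frequency census counts, for every protein that ever bridged, the
number of tissues it connected; mean and population SD are taken over those
observed connectors only (proteins never seen are not zero-counted), SEM is
reported alongside because the emulated analysis quotes mean + SEM while
*selecting* by two SDs, and `selected` is counts > mean + 2·SD. With a
single connector the SD is 0 and nothing is selected.

## Synthetic data

The generators define the study conditions for every test:

* **Intensity matrices** — baseline log2 intensities per protein from
  Normal(20, 2), a typical LFQ dynamic range (no distribution is stated for
  the original data); planted effects of ±`effect_size_log2` (default 1.5)
  on a `dep_fraction` (default 0.15) of proteins, negative with probability
  `down_fraction` = 0.6 (the emulated screen reports 57.8–68.9% down across
  doses); replicate noise SD 0.4 on the log2 scale; 3 replicates per cell
  (the original replicate count is unstated; configurable); missingness is
  MCAR at 5% — left-censoring is deliberately not modelled. Dose scales the
  planted effect linearly in log-dose by default (the original reports
  qualitatively different phenotypes per dose but no effect-size model);
  `dose_scaling="none"` applies full effects everywhere and is used by the
  calibration/power checks so the effect size is exactly what it says.
* **Gene-set collections** — background sets uniform over the universe;
  planted sets of the size of the supplied DEP list with a binomial
  `purity` fraction of true members.
* **Tissue graphs** — independent Erdős–Rényi graphs (default 142 tissues,
  the census size of the emulated analysis) with edge confidences uniform
  on [0.5, 1]; planted bridges wired to both seeds at confidence 1.0 in a
  `bridge_tissue_fraction` of tissues, with direct seed–seed edges
  suppressed there.

What passing tests on these simulations do **not** show: robustness to
intensity-dependent missingness, batch effects between runs, correlated
protein co-regulation, scale-free topology of real interactomes, or ID
mapping noise — none of which the generators emulate.

## Problem sizes used by the checks

Oracle sweeps: KS vs exhaustive running sums on universes of 8–30 with
1–8-member sets; ORA vs exact combinatorial tail sums for every
(N ≤ 15, n, m) and literal draw enumeration for N ≤ 7. Calibration: 500
repetitions for overlap and network nulls; 4–6 × 1000–2000-protein null
screens for the false-positive rate. Recovery: 10 × 2000-protein screens at
the 3σ sparse regime; 100 seeds of 300-protein profiles for best-match
ranking; 50 censuses of 142 tissue graphs over a 120-node universe at
density 0.03 with 3 planted bridges at tissue fraction 0.5. The acceptance
script runs the screen at 2500 proteins (the emulated signature scale) and
10 bridging censuses.

## Known limitations

* The global-mean z test treats the ratio distribution as normal; heavy
  tails inflate the false-positive rate slightly above α.
* Budgeted path pooling is not a Steiner-tree optimum and is sensitive to
  `max_paths` only in graphs dense enough to exhaust the budget across many
  equal-length alternatives.
* The donor-interactome null inherits the granularity of its donor count
  (p ≥ 1/(n_donors+1)).
* Reported percentages from tiny DEP tables are unstable; the pipeline
  reports counts alongside.
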