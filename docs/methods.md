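# Methods

This note documents the models, the numerical choices and the open
design decisions behind `orchidedge`. It is written for a maintainer or
reviewer who wants to know exactly what each number means and what the
synthetic tests do and do not demonstrate.

## The prioritization model

### PD and ED

On a rooted, time-calibrated tree with branch lengths in Myr,
phylogenetic diversity (PD) is the sum of all non-root branch lengths.
A root edge length, if present in the Newick source, is parsed and
round-tripped but excluded from every metric: the metrics are defined on
the ingroup tree, and dated trees commonly arrive with outgroups pruned
and a residual stem edge.

Evolutionary distinctiveness (ED) uses the fair-proportion definition:
each branch is divided equally among the tips descending from it, and a
tip's ED is the sum of its shares. This is the primary definition here
because it carries an exact conservation law — ED summed over tips
equals PD — which every computation is tested against (relative
tolerance 1e-9). An equal-splits variant (`equal_splits_ed`), in which
the value splits at each divergence rather than by tip count, is
available for sensitivity analyses but feeds nothing downstream.

### ED2: expected unique PD

ED2 replaces the fair-proportion share with an expectation under
extinction. Writing `TBL_i` for tip `i`'s terminal branch, `L_j` for the
length of ancestral branch `j` on `i`'s root path and `p_k` for the
extinction probability of tip `k`,

```
ED2_i = TBL_i + Σ_j  L_j · Π_{k ∈ desc(j) \ {i}} p_k .
```

Under independent extinctions with probabilities `p_k`, this is exactly
the expected amount of PD that survives only through tip `i`. The test
suite verifies this identity against an exhaustive enumeration over all
joint survival states of the non-focal tips (trees up to 6 tips, 1000
random probability maps, absolute tolerance 1e-12). The focal tip's own
probability never enters its own ED2; consequently `TBL_i ≤ ED2_i ≤
depth_i` for every probability map, which is asserted as a property.

Leave-one-out products inside each branch's descendant set are computed
by prefix/suffix cumulative products in the single-map code path, so
the result is exact even for vanishing probabilities. The vectorised
resampling path divides the full product by the focal tip's value
instead; this is safe there because every drawn probability is bounded
below by 0.00174 (the floor of the LC interval).

### GE2: category risk distributions

Each Red List category carries a pool of 50-year extinction
probabilities with a pinned median and a bounded support:

| category | median    | support              |
|----------|-----------|----------------------|
| CR       | 0.97      | (0.69436, 0.99999)   |
| EN       | 0.485     | (0.33861, 0.69435)   |
| VU       | 0.2425    | (0.17085, 0.33861)   |
| NT       | 0.12125   | (0.09337, 0.17085)   |
| LC       | 0.060625  | (0.00174, 0.09337)   |

The medians halve from each category to the next less-threatened one;
the intervals tile the unit interval without overlap. Only the median
and the support are binding contracts, and the published descriptions of
how the underlying distribution was generated (a polynomial-regression
fit followed by median-matching resampling) are not reproducible in
detail. The pool is therefore constructed directly to satisfy the
contracts: one element equal to the median itself, and equally many
uniform draws on each side of it within the support. For any odd pool
size the middle order statistic — the empirical median — equals the
expected value with zero tolerance, which the tests assert as exact
float equality, not approximate equality.

Default pool size is 10,001 per category (configurable). The upstream
framework's per-category row counts (197,163 / 182,966 / 139,860 /
66,784 / 156,327, totalling 743,100) arise from defaults of tooling we
do not reproduce; with equal pool sizes the pooled DD/NE/NA mixture
weights the five categories equally rather than by those counts.

Category handling: RE (regionally extinct) and EW (extinct in the wild)
taxa draw from the CR pool. DD, NE and NA taxa draw, by default, from
the pooled concatenation of all five category pools — matching the
description of sampling "from the entire distribution" — spanning
(0.00174, 0.99999). A `dd_mode="uniform"` switch samples a uniform law
on that range instead, since the published wording admits either
reading; the pooled mixture is the default because it is the more
literal one.

### EDGE2 and resampling

`EDGE2_i = ED2_i × GE2_i`. Uncertainty is quantified by joint
resampling, 500 draws by default: each draw assigns *every* tip a fresh
GE2 value from its category pool, recomputes ED2 for all tips under
that joint assignment, and multiplies. Joint (rather than per-taxon
independent) resampling matters because ED2_i depends on all other
taxa's probabilities; it also makes runs exactly reproducible from one
seed. Per-taxon results are summarised by the median and interquartile
range (Q3 − Q1, linear interpolation between order statistics) of their
draws, and ranked by descending EDGE2 median with ties broken by ED2
median, then taxon label. Raising a taxon's category never lowers its
EDGE2 median at a fixed seed, which is asserted across all five
categories.

### ED–threat regression

ED is regressed (OLS, ED as response) on the ordinal threat weight
LC=0, NT=1, VU=2, EN=3, CR=4. Categories outside that map (RE, EW, DD,
NE, NA) are excluded rather than given invented weights. Both plain and
adjusted r² are returned: the adjusted value can be negative for weak
fits, and published regional analyses of this kind report such values,
so conflating the two would make results uninterpretable. A constant
response returns slope 0 and r² = 0 explicitly instead of propagating a
0/0.

## Barcode discriminatory power

Kimura two-parameter distances separate transition (P) and transversion
(Q) proportions: `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`. Sites carrying a
gap or any non-ACGT symbol in either sequence of a pair are deleted
pairwise — the plastid spacer markers this targets are indel rich, and
complete deletion would discard most of the matrix. Ambiguity codes are
treated as missing, not partially matched. Pairs whose log arguments
are non-positive (saturation) are flagged undefined, excluded from all
summaries and tallied in a diagnostics count; nothing is clamped. A
minimum usable-site count per pair (default 1 in the library, 50 in the
CLI, where real markers are the expected input) guards against
distances computed on a handful of sites.

Within/total diversity decomposes as: π_total = mean over all defined
pairs; π_within = *equal-weight* mean over species of the within-species
mean distance (species with a single accession contribute no
within-species information and are absent from this mean, not counted
as zero); δ_between = π_total − π_within; coefficient of differentiation
= 1 − π_within/π_total. The equal-weight-by-species convention for
π_within is fixed by an internal consistency check: applied to the
published per-marker rounded means it reproduces the published
between-species diversity exactly for one marker and all four published
coefficients within 1e-3, which a per-pair weighting does not. The
plain per-pair means over the intra and inter sets are reported
separately as mean *distances*.

The barcoding gap is quantified by a one-way fixed-effects ANOVA with
each pairwise distance as one observation in the intra or inter group.
The ANOVA is computed from the between/within sums of squares directly
so degenerate layouts have defined answers (no between-group variation:
F=0, p=1), and is cross-checked against an independent ANOVA routine in
the tests. Treating pairwise distances as independent observations
overstates the effective sample size — the same caveat applies to the
standard use of this test in the barcoding literature — so the p-value
is a descriptive index of separation, not a calibrated error rate.

The "±" dispersions published alongside such tables rarely state their
method; a site-resampling bootstrap (columns resampled with
replacement, statistic recomputed, SD across replicates) is provided as
the package's dispersion estimate and is not claimed to match any
published values.

## Tabulations and trait correlations

Threat ordinals for rank analyses are LC=1 … CR=5, RE=6; DD/NE/NA are
excluded pairwise. "Threatened" means VU ∪ EN ∪ CR. "Assessed" excludes
NE/NA but includes DD and RE. Percentages round half away from zero to
integers, matching the published style (55/91 → 60%).

Trade is coded 0 = untraded, 1 = ornamental, 2 = medicinal, 3 = both.
The published coding defines 1–3 only for traded taxa, but correlating
across the whole flora requires a baseline level, so untraded taxa sit
at 0. The traded total is computed by inclusion–exclusion
(ornamental + medicinal − both), which the tests confirm equals the
count of non-zero codes.

Spearman's correlation is tie-corrected (Pearson on mid-ranks, as
implemented in scipy). The default p-value is the t approximation; a
seeded permutation test (≥ 10⁴ permutations, two-sided on |r_s|) is
available and agrees with the t approximation within 0.02 on null data
at n ≥ 50, which is asserted. Published p-values for these correlations
are internally inconsistent with their coefficients under any standard
Spearman test and are not a reproduction target. |r_s| is labelled very
weak (< 0.2), weak (< 0.4), moderate (< 0.6) or strong (≥ 0.6). No
multiple-testing correction is applied across the four traits,
matching the analysis this mirrors.

## The synthetic-data generator

The generator's defaults are the study conditions, not tuning knobs:

* **Tree**: pure-birth (Yule), 134 tips, rescaled to a 110 Myr root —
  the flora's tree size and the root age used for dating. Pure birth is
  the simplest model delivering ultrametric trees, and the analysis
  consumes any ultrametric tree, so diversification realism is
  irrelevant here. The process is stopped at the n-th tip and pendant
  edges are extended by the exponential waiting time to the next
  speciation, so terminal branches are strictly positive.
* **Categories**: multinomial draws from the regional tallies
  (CR 35, EN 17, VU 24, NT 8, LC 30, DD 4, RE 17 of 135) and national
  tallies (CR 5, EN 16, VU 22, NT 13, LC 70, DD 4 of 130). The two
  scopes are drawn independently; the real flora's scopes are
  correlated, which only matters for cross-scope comparisons no test
  relies on.
* **Traits**: a Gaussian-copula threshold model. The taxon's threat
  ordinal is mapped to a normal score (Blom scores of mid-ranks); a
  latent `z = a·s + √(1−a²)·ε` is thresholded into the trait's code set
  at quantiles matching the flora-wide prevalences (habit 54:84,
  specificity 47:91, mating 10:61 with 67 unknown, trade 88:41:2:7).
  The loading `a` is calibrated by Monte Carlo so the resulting
  Spearman correlation hits the target ρ*: a fixed
  common-random-numbers noise vector makes the map from `a` to r_s
  deterministic, a 21-point grid locates the bracketing cell (the map
  can collapse near a → 1 when few distinct scores all land in one
  level), and 14 bisection steps refine it. Targets beyond the
  thresholded maximum raise a calibration error. Default targets are
  0.5 (specificity), 0.35 (mating), 0.12 (trade) and 0.1 (habit) —
  positively oriented associations of the magnitudes the regional
  analysis reports. Recovery is verified: |r_s − ρ*| ≤ 0.1 in ≥ 95% of
  200 seeds at n = 500 for ρ* ∈ {0.1, 0.35, 0.55}.
* **Sequences**: evolved site-independently under the Kimura
  two-parameter process (closed-form per-edge substitution
  probabilities, κ = 3 by default) — deliberately the same model family
  the K2P distance inverts, so the estimator-consistency tests are
  meaningful. The per-site rate is set from the tree's mean pairwise
  path length so a random heterospecific pair sits at 0.08
  substitutions/site in expectation; conspecific accessions hang on
  independent branchlets of half the intraspecific target (0.003), a
  star within each species, making conspecific accessions
  exchangeable. No indels, rate heterogeneity or alignment error are
  simulated: passing barcode tests show the statistics behave correctly
  under the distance model's own assumptions, not that real spacer
  alignments are this clean.

All generators are pure functions of (config, seed); fixture bundles
are byte-identical under a repeated seed.

## Numerical and interface choices

* Taxon labels are canonicalised (trim, collapse space/underscore runs
  to `_`) at parse time in both the tree and table readers, so files
  written by software that swaps spaces for underscores still join.
* All randomness flows through explicit `numpy` generators or seeds; no
  global state. Derived seeds stay below 2³¹.
* Validation errors carry the offending labels/rows; the CLI maps
  package errors to exit 1 and usage errors to exit 2, and writes a
  `manifest.txt` (inputs' SHA-256, parameters, seed, version) beside
  every result set.
* Problem sizes in the test-suite properties (for example 1000
  enumeration maps, 200 recovery seeds, 200 ANOVA fixtures, a 134-tip
  end-to-end run at 500 draws) are the package's chosen verification
  sizes: large enough that the asserted rates (≥ 95%, ≥ 99%) are
  meaningful, small enough to run routinely.

## Known limitations

* The published 134-taxon results (total PD 4,170.90 Myr, per-taxon ED
  and EDGE2 rankings, per-marker distance tables, the printed
  correlation coefficients) depend on the deposited sequence data and
  dated tree and are not reproduction targets; the package verifies the
  *method* on synthetic data with the same structure.
* The DD/NE pooled distribution weights categories equally (by pool
  size), not by the upstream framework's row counts.
* The ANOVA on pairwise distances inherits the non-independence caveat
  above.
* The trait generator calibrates each trait against the realised
  category vector marginally; joint trait–trait correlations are not
  modelled.
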