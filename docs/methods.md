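# Methods

This note documents the statistical procedures the package implements, the
synthetic data model used to exercise them, and the numerical and design
choices made where more than one defensible option existed.

## Study model and units

A study is an 8-group gavage design: administered doses 0 (controls), 4,
10, 20, 40, 100, 200, 400 µg/kg body weight per gavage, 3 gavages/week for
90 days, 8 animals per group. Concentrations are matrix-native: pg/mg for
hair, ng/mL for urine and plasma. Slope fitting needs exposure as a rate;
the default `weekly_average` transform spreads the weekly intake over seven
days:

    T(dose) = dose [µg/kg] × gavages_per_week / 7 / 1000   [mg/kg per day]

The mapping from a per-gavage dose to a daily rate is a convention, not a
law, so it is configurable (`per_gavage` and `identity` are also
provided); all correlation statistics are invariant to the choice, only
the slope's scale changes.

## Censoring

The LOD is operationally the lowest concentration the assay reported, so
detection is closed at the LOD (`value ≥ LOD`). Non-detects are stored as
absent values, never as 0 or ½LOD: imputation is an explicit stage, and an
imputed record keeps `detected=False`, so downstream code can always
distinguish measured from substituted values. Two rules coexist by design:

* association statistics (slope, Pearson, Spearman, and the adjustment r²)
  use **detected values only**;
* inter-group testing and RCA use the **½-LOD-imputed** table, so every
  animal contributes.

Group-level detection (the detection matrix, the per-level compound counts,
and the "detected in ≥ 4 levels" eligibility rules for association and RCA)
uses the weakest aggregation consistent with "positive detection": at least
one animal in the group detected.

## Association

Per compound × matrix the subset of detected records is regressed by
ordinary least squares (intercept included — controls genuinely carry
background concentrations, so an origin-forced fit would be misspecified).
Pearson's r carries a two-sided p from the t distribution with n−2 df;
Spearman is the Pearson correlation of midranks, which matters here because
doses repeat within groups and ties are pervasive. With detection in fewer
than 4 dose levels the statistics are not computed (`NA`); with no detected
record the status is `ND`. The reported concentration range is the min and
max of *group means* over detected values (single-animal extremes are a
possible alternative reading; group means are what the summary exports).

## Inter-group ladder

Each pairwise comparison is a two-sided pooled-variance t test if both
groups pass Shapiro–Wilk normality and the pair passes a median-centered
Levene variance test, all gated at 0.05 (the conventional gate of the
desktop statistics packages this procedure mirrors); otherwise a two-sided
Mann–Whitney rank-sum test. scipy's implementation enumerates the exact
rank-sum null for small tie-free samples and otherwise uses the normal
approximation with midrank tie correction; a pair of completely tied
samples has zero rank variance and is short-circuited to p = 1. A
zero-variance group cannot be tested for normality and falls to
Mann–Whitney.

The walk maintains a reference group: top-down it starts at 400 µg/kg and
tests against the next lower group; significance records a bracket and
moves the reference down, non-significance keeps the reference and skips
onward. The same procedure is re-applied down-top from the control group.
Both passes always run and their comparisons are merged per pair keeping
the smaller p — the only reading under which all groups are covered; this
also means a pair found non-significant in one pass may still be bracketed
by the other. Categories: significant (p ≤ α, default 0.05), marginal
(α < p ≤ 0.10, a concrete band for "slightly greater than 0.05"), ns. No
family-wise error control is applied, deliberately.

## Reverse Classification Analysis

Score: the probability that `subset_size = 5` animals drawn uniformly
without replacement (all groups pooled), sorted ascending by concentration,
have a non-decreasing dose sequence — animals sharing a dose may appear in
any order. Monte-Carlo estimation uses 10,000 iterations by default;
`mc_se = 100·sqrt(p(1−p)/iterations)` is attached. An exact oracle
enumerates all C(N, k) subsets (bounded at 10⁶) under identical selection
and tie rules. Concentration ties — common after ½-LOD imputation — are
scored optimistically by default (correct if *some* ordering of the tied
block is dose-non-decreasing, the natural analogue of the dose-equality
allowance); implementation-wise, sorting tied blocks dose-ascending
realises the optimum, dose-descending realises the pessimistic variant,
available behind a flag. Stratified sampling (one animal from each of 5
distinct groups) is likewise available but off by default, since the
procedure is defined over all animals. Compounds detected in fewer than 4
dose groups are `not_conducted`.

Under the null (concentrations independent of dose, distinct doses) every
ordering of a 5-subset is equiprobable, so the expected score is 1/5! ≈
0.833%. Note this expectation is over fresh concentration draws: a *fixed*
8-animal dataset exposes only its own C(8,5) = 56 subsets, and the number
of correctly ordered subsets of a random permutation is heavy-tailed
(83% of permutations contribute zero), so calibration checks redraw the
concentrations per iteration rather than pooling a few fixed datasets.

## Adjustments

Volume adjustment multiplies the urinary concentration by the 24-h urine
volume (amount excreted, ng); creatinine adjustment divides by urinary
creatinine (ng per mg). Both are compared to the raw concentration by the
squared Pearson correlation with exposure rate under the *same*
detected-only inclusion rule as the association table, so the comparison
is not confounded with a change of sample set. The pigmentation analysis
regresses white-hair on black-hair concentrations through the origin (two
measurements of the same analyte in the same animal have no physical
intercept; the with-intercept fit is available behind a flag); a slope
near 1 indicates pigmentation-independent incorporation.

## Synthetic data model

Per compound, matrix, and animal the latent concentration is

    c = (a0 + b · T(dose)) · exp(ε),   ε ~ N(0, σ²),  σ = sqrt(ln(1+cv²)),

i.e. a linear dose-response with multiplicative lognormal noise of
coefficient of variation `cv`. Multiplicative noise (rather than additive
Gaussian) reproduces the right-skew and high outliers of real
concentration data and guarantees positivity; `a0 > 0` models the
background exposure that makes some analytes detectable in controls.
Censoring is applied after noise on the latent value — records below the
matrix LOD become non-detects — matching how an assay truncates. Urinary
volume and creatinine are lognormal with means 15 mL/24 h and 0.8 mg/mL
(typical adult-rat values) and cv 0.30/0.25. Pigmentation pairs set
white = ratio · black · exp(noise).

The default registry (12 analytes across five chemical classes) spans
slopes from ~1 to ~600 concentration units per mg/kg/day and is arranged
to produce every qualitative case the pipeline must handle: full detection
including controls, detection only at high doses (NA), absence from a
matrix (ND), and a metabolite present everywhere but unrelated to dose.
The default cv of 0.4 is a fixture choice — a realistic within-group
biological plus analytical variability for this kind of assay — not an
estimate from data; no published within-group variances were available to
calibrate it.

Known simplifications: no shared per-animal random effect (errors are
independent across compounds and matrices, so cross-analyte correlations
in real data are not emulated), no toxicokinetics (end-of-study
concentrations only), and identical noise families across matrices.
Passing tests therefore demonstrate the *procedures* are correct and
calibrated under the stated model, not that any particular matrix is
superior in real animals.

## Numerical choices and degenerate inputs

* Detection is `value ≥ LOD`; a present value below the LOD is legal but
  always `detected=False` (that is exactly an imputed ½-LOD).
* The CSV reader parses floats in round-trip precision so write→read is
  bit-exact; non-detects are empty cells.
* Slope fitting requires ≥ 2 distinct exposure values; correlations
  require n ≥ 3 and non-zero variance (zero rank variance makes Spearman
  undefined); violations raise typed errors rather than returning NaN.
* RCA requires at least `subset_size` animals with values; the exact
  enumerator refuses > 10⁶ subsets and points to Monte Carlo.
* One pipeline seed drives the generator and the RCA resampler through
  independent spawned streams, and each compound × matrix RCA cell gets
  its own child stream, so changing the iteration count of one analysis
  never perturbs another. Identical config + seed gives byte-identical
  CSV outputs.

## Problem sizes used in the checks

The automated checks run at the scale the procedures are used in practice:
64-animal studies; RCA with 10,000 Monte-Carlo iterations validated
against exact enumeration of C(16,5) = 4,368 subsets on 20 tie-varied
fixtures; slope recovery over 100 replicate studies per slope in
{1, 10, 100, 600} at cv = 0.4 (median relative error ≤ 15%); and
two-group test calibration over 5,000 simulated null pairs
(rejection rate 5% ± 1 percentage point).
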