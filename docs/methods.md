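# Methods

## Scope and data model

The pipeline starts at *called* peak tables — one row per peak with size
(bp), height, and optionally area and scan index — as exported by
fragment-sizing software. Peak calling from raw fluorescence and binary
chromatogram containers are out of scope. Heights, not areas, quantify
expansion throughout.

Peak sizes are mapped to integer CAG counts by a linear calibration
anchored on one internal-standard sample per gene and plate: a sample of
known repeat count pins the map, and the default slope is 3 bp per repeat
(CAG is a trinucleotide). Fractional repeats are binned to the nearest
integer, ties away from zero; electrophoretic mobility drift is sub-repeat,
so nearest-repeat binning is standard practice. Peaks rounding to the same
repeat are summed.

## Expansion index

A trace holds both alleles. Analysis is restricted to the expanded-allele
cluster by a per-gene CAG window whose default lower edge is the locus's
pathological threshold (ATXN1 ≥ 39, ATXN2 ≥ 33, ATXN3 ≥ 55, ATXN7 ≥ 36) —
the least arbitrary separation rule in the absence of per-sample
annotation. The window is configurable for carriers with unusually large
normal alleles.

Within the window, with anchor height `h0` at the reference modal CAG,
expanded peaks at offsets `d ≥ 1` are filtered at `theta * h0`
(default `theta = 0.03`, placed where genuine low-intensity peaks separate
from software background) *before* normalization; with
`S = h0 + sum(retained)`, `EI = sum((h/S) * d)`. Stutter peaks (`d < 0`)
never contribute. Design choices worth stating:

* **Normalizing sum.** `S` includes the modal peak and only
  threshold-retained expanded peaks. The alternative — normalizing over all
  detected expanded peaks — is available via `subthreshold_in_norm=True`.
* **Threshold monotonicity.** Under retained-only normalization, EI is
  non-increasing in `theta` for traces whose expansion tail decays
  monotonically (the observed morphology), but *not* for arbitrary height
  patterns: dropping a low-offset peak shrinks `S` and can raise the
  weighted mean. Under the all-detected normalization monotonicity holds
  unconditionally. The property tests assert exactly these two scoped
  forms.
* **Modal calling.** The tallest in-window peak wins; ties break toward the
  smaller CAG so stutter asymmetry cannot inflate the reference.
* **Longitudinal anchoring.** One reference modal per individual — the
  diagnostic repeat count when available, else the earliest trace's modal.
  When a later trace's tallest peak has drifted above the reference, `h0`
  is still the height *at the reference* and taller peaks at `d ≥ 1` count
  as expansion; this is what makes a +1 modal drift between visits
  measurable instead of silently re-anchored.
* **Gaps** in the expanded ladder contribute nothing; no interpolation.
* **% mutant alleles** is `100 * h / S` over the reference-modal peak plus
  retained expanded peaks and sums to 100 by construction.

Left-of-modal (contraction) indices and area-based quantification are
deliberately not implemented.

## Cohort statistics

* **Expansion rate (ER).** Per-individual OLS of EI on age over all visits;
  at least two visits at distinct ages are required, and single-visit
  individuals are excluded from ER analyses (the slope is not estimable).
  The intercept is reported as the theoretical EI at birth.
* **Mixed model.** `EI ~ age_c * cag_c * group` with a random intercept per
  individual, fitted by REML (statsmodels MixedLM). Age and (CAG)n are
  mean-centered by group on first-visit characteristics, so each group's
  slope describes a "mean individual" of that group. The three-way
  interaction is tested by a Type II Wald chi-square (df = number of groups
  − 1); with all lower-order terms present this is the joint test of the
  highest-order coefficients. Per-group slopes are linear combinations of
  fixed effects at centered covariates = 0, with SEs from the fixed-effect
  covariance. A singular fit (random variance ~0) degrades to a warning:
  the fixed effects then equal pooled OLS.
* **Degrees of freedom.** Slope tests and contrasts use the large-sample
  residual df (observations minus fixed-effect count). A Kenward-Roger
  small-sample correction is not available in the host stack; at ~184
  individuals the difference is immaterial. The substitution is logged.
* **Slope contrasts.** All pairwise slope differences with single-step
  Tukey adjustment: `q = |diff|/se * sqrt(2)` referred to the
  studentized-range distribution with `k` = number of groups.
* **Correlations.** Pearson r with the two-sided p of the regression slope
  (identical to the correlation t test); zero variance raises an error
  rather than returning NaN.
* **Residualized status comparisons.** First-visit EI is residualized
  within group on age and (CAG)n, ER on (CAG)n alone; classes
  (premanifest/manifest by clinical signs, or preataxic/ataxic by
  SARA > 3.5) are compared by two-sided Wilcoxon rank-sum tests — exact
  null distribution for pooled n ≤ 25 without ties, normal approximation
  with tie correction otherwise. A quadratic-age term is testable per group
  for model checking but never auto-selected.
* **Severity** is SARA points per year of disease duration; non-positive
  durations flag the record as missing.
* **Descriptives** report n, mean and sample SD (n−1 denominator), rounded
  half away from zero to two decimals. Published tables occasionally print
  a population SD for two-sample groups (e.g. 0.02 where the sample SD is
  0.03); the sample SD is reported regardless.
* Significance is two-sided 0.05 throughout.

## Synthetic data

The generators define the conditions under which the pipeline is validated.

**Traces.** Expected heights: modal peak `h0`; geometric stutter
`h0 * decay^k` at −k (k = 1..4, default decay 0.45); a normal-allele
cluster at the locus's typical normal repeat; and an expansion tail of
geometric shape in the offset (truncated Poisson selectable) whose total
mass is solved in closed form so the noise-free EI of the threshold-retained
peaks equals the requested target exactly. Tail support is the longest
prefix whose faintest peak clears the detection threshold — with a 2×
margin where the target allows, because a peak sitting exactly at the
threshold is dropped by noise about half the time, biasing measured EI low;
sub-threshold products are not emitted at all, as sizing software would not
call them. Peak-height noise is multiplicative lognormal with constant CV
(default 0.05): fluorescence noise scales with intensity. Presets draw
fetal targets from EI 0.03–0.10 (the near-zero range of first/second
trimester tissues) and adult-blood targets from 0.4–1.5.

**Cohorts.** Per individual: (CAG)n ~ rounded normal with group-specific
mean/SD (defaults 48.2/5, 39.7/3, 71.5/4, 44.1/6); baseline age uniform on
25–65; 2–3 visits spanning on average 8.5 years;
`EI = b0 + s_g * (1 + gamma*(cag − mean_g)) * age + eps`, floored at 0,
with `b0 ~ N(0.05, 0.12²)` (near-zero EI at birth, per fetal stability),
`eps ~ N(0, 0.18²)`, and group slopes `s_g` = 0.023/0.012/0.008/0.055
EI/yr. `gamma = 0.05` encodes the repeat-length dependence of expansion;
it yields first-visit EI–CAG correlations of roughly 0.4–0.7 across groups
— strong for the fast-expanding loci, weak for the slow ones, as observed
in such cohorts. The noise SDs were chosen so the simulated cohort's slope
standard errors (~0.0015–0.0025) match the dispersion reported for cohorts
of this design. Disease status follows a SARA trajectory (1.2 points/year
after a CAG-dependent onset age) crossing the 3.5 cutoff. What the
generator does **not** emulate: visit-schedule informativeness (dropout,
death censoring), plate/batch effects on EI, non-linear EI trajectories,
and measurement error correlated within a plate — passing recovery tests
therefore shows estimator correctness under the assumed model, not
robustness to those violations.

**Tissue panels** draw per-tissue target EIs from ranges ordered
cerebellum (0.3–0.7) < brainstem (1.0–1.8) < frontal cortex (1.6–2.6) and
shift the cerebellar modal one repeat below the reference. Panel traces use
a long flat tail (mean offset 6): cortical EIs above ~2 generated from a
short tail would require a +1 peak taller than the main peak, displacing
the modal call.

All generators are deterministic given a seed.

## Expression

ΔCt = Ct(target) − Ct(PPIA-style reference) per record; ΔΔCt subtracts the
same individual's cerebellum baseline; fold change = 2^−ΔΔCt. Technical
replicates are averaged on the Ct scale before differencing (the field
convention). Amplification-efficiency correction is not applied. Heatmap
scaling standardizes each gene row to zero mean and unit sample variance;
constant rows become zeros with a warning. Extreme fold changes are never
clipped in stored values.

## Numerical notes and problem sizes

* EI arithmetic is plain double precision; the brute-force oracle agreement
  is asserted at 1e-12 on traces of up to 12 peaks.
* The generator's target-EI inversion is exact (closed form per candidate
  support), so forward-inverse identity holds to machine precision on
  noise-free traces.
* Simulation-based tests use 40–120 replicates for calibration/power
  checks, 100 replicates for mixed-model recovery at the full 184-individual
  design, 500 draws for the fetal contrast, and 2,000 null simulations for
  rank-sum type-I error; these sizes keep Monte-Carlo error well inside the
  asserted bands while the whole suite stays fast.
* `scripts/acceptance.py` averages mixed-model slopes over 20 replicate
  cohorts so the reported estimates carry Monte-Carlo error an order of
  magnitude below the per-cohort SE.

## Known limitations

* The expanded-allele window assumes the normal allele lies below the
  pathological threshold; carriers with intermediate alleles near the
  window edge need a manual window.
* Only a random-intercept covariance structure is offered; random slopes
  would need a trivial extension but are not exposed.
* Sequence interruptions within the repeat, which modulate stability, are
  invisible to fragment sizing and outside this package's scope.
* The Wilcoxon implementation switches from exact to asymptotic at pooled
  n > 25; near the switch, p values change by O(1e-3).
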