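# cagmosaic

Quantification of **somatic CAG-repeat mosaicism** from fragment-analysis
peak traces, with the longitudinal cohort statistics used to study repeat
instability in the polyglutamine spinocerebellar ataxias (SCA1, SCA2, SCA3,
SCA7 — *ATXN1/2/3/7*).

The expanded CAG allele of an SCA carrier is not one length: somatic
expansion during life produces a distribution of repeat sizes in every
tissue, visible in a capillary-electrophoresis trace as a ladder of peaks to
the right of the main (modal) peak. `cagmosaic` is for geneticists and
biostatisticians who need to turn exported peak tables into per-sample
instability metrics and cohort-level inferences.

## The expansion index

For a trace with modal-peak height $h_0$ and expanded peaks at repeat
offsets $d_i \ge 1$ with heights $h_i$, peaks below a relative detection
threshold $\theta$ (default 0.03) are excluded, and with
$S = h_0 + \sum_{\mathrm{retained}} h_i$,

$$\mathrm{EI} \;=\; \sum_{\mathrm{retained}} \frac{h_i}{S}\, d_i .$$

EI = 0 means no expansion beyond the inherited allele. Peaks left of the
modal peak are PCR stutter and are never counted. For longitudinal series
the same reference modal CAG (the diagnostic repeat count) anchors every
visit of an individual. Derived quantities:

* **% mutant alleles** — $100\,h/S$ per repeat length, the fraction of
  cells carrying each CAG size;
* **expansion rate (ER)** — per-individual OLS slope of EI on age
  (EI/year), with the intercept as the theoretical EI at birth;
* **group slopes** — a linear mixed model of EI on
  age × (CAG)n × disease group (random intercept per individual, REML;
  covariates mean-centered by group on first-visit characteristics), with
  per-group slopes, a Type II Wald test of the three-way interaction, and
  Tukey-adjusted pairwise slope contrasts;
* **status comparisons** — Wilcoxon rank-sum tests on EI/ER residuals after
  within-group adjustment for age and (CAG)n;
* **2^-ΔΔCt expression** — relative qPCR quantification normalized per
  individual to the cerebellum.

A synthetic-data module generates electropherograms with exactly known EI,
longitudinal visit tables following the mixed model's data-generating
process, and postmortem-style tissue panels (cerebellum-low, cortex-high,
with the cerebellar modal peak one repeat below the reference).

## Worked example

Generate a noisy ATXN7 blood-like trace with ground-truth EI 0.9 and push
it back through the EI engine:

```python
import numpy as np
from cagmosaic.simulate import TraceGenConfig, generate_trace
from cagmosaic.instability import compute_ei

cfg = TraceGenConfig(gene="ATXN7", modal_cag=44, tail_mean=3.0, noise_cv=0.05)
sim = generate_trace(cfg, target_ei=0.9, rng=np.random.default_rng(7))
profile = compute_ei(sim.trace, reference_modal=44, cal=sim.calibration)
print(f"modal CAG     : {profile.modal_cag}")
print(f"EI            : {profile.ei:.3f}   (generator ground truth {sim.true_ei})")
print(f"extra repeats : {profile.n_additional_cags}")
for cag, pct in profile.percent_by_cag.items():
    print(f"  CAG {cag}: {pct:5.2f} %")
```

```
modal CAG     : 44
EI            : 0.869   (generator ground truth 0.9)
extra repeats : 4
  CAG 44: 57.28 %
  CAG 45: 17.52 %
  CAG 46: 11.60 %
  CAG 47:  8.18 %
  CAG 48:  5.42 %
```

The modal peak carries 57% of the retained signal; the remaining 43% sits
at +1 to +4 repeats, and their position-weighted share gives an EI of 0.87
— 5% noise on peak heights moves the measured EI a few percent off the
noise-free truth.

The same operations are available from the shell:

```sh
cagmosaic simulate cohort --seed 3 --out sim/
cagmosaic cohort er  --visits sim/visits.tsv --out er.tsv
cagmosaic cohort lmm --visits sim/visits.tsv --out lmm.json
cagmosaic ei compute --peaks peaks.tsv --samples samples.tsv \
    --calibration cal.yaml --threshold 0.03
```

## Layout

```
src/cagmosaic/
  trace_io.py     peak-table/visit-table I/O, bp→CAG calibration
  instability.py  modal calling, EI, % mutant alleles
  cohort.py       ER, mixed model, contrasts, correlations, Wilcoxon
  expression.py   2^-ΔΔCt, heatmap scaling
  simulate.py     synthetic traces, cohorts, tissue panels, Ct tables
  datasets.py     bundled published reference EI values
docs/methods.md   model assumptions, parameter choices, limitations
```
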