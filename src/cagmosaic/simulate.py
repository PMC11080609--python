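"""Synthetic electropherograms, longitudinal cohorts and tissue panels.

Real data for somatic CAG mosaicism studies are clinical and rarely shared;
this module generates inputs with the exact statistical structure the
analysis pipeline assumes, with ground truth attached, so every stage can be
validated end to end.

**Traces.**  A synthetic trace reproduces the morphology of a capillary
electrophoresis profile of an expanded CAG allele: a normal-allele cluster,
a modal expanded peak with geometric PCR stutter to its left, and a
right-hand tail of somatically expanded products whose shape is geometric in
the repeat offset (truncated Poisson selectable).  The tail mass is solved
so that the *noise-free* expansion index of the threshold-retained peaks
equals a requested target exactly; multiplicative lognormal noise (constant
coefficient of variation, as fluorescence noise scales with intensity) is
then applied per peak.  Products that would fall below the relative
detection threshold are not emitted — fragment-sizing software would not
call them.

**Cohorts.**  Longitudinal visit tables follow the data-generating process
of the random-intercept model: per individual, EI grows linearly with age at
a group-specific rate modulated by the germline repeat length, around a
random birth-level intercept, with i.i.d. residual noise and a floor at 0.
Group defaults (sizes 30/50/74/30; mean repeats 48.2/39.7/71.5/44.1; EI
slopes 0.023/0.012/0.008/0.055 per year; mean follow-up span 8.5 years)
match the study conditions of a four-disease SCA cohort.

**Tissue panels.**  Per-donor panels draw target EIs from tissue-specific
ranges ordered cerebellum < brainstem < cortex, with the cerebellar modal
peak shifted one repeat below the reference — both hallmarks of postmortem
repeat-instability data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cagmosaic.errors import TargetUnreachableError
from cagmosaic.trace_io import Peak, SizeCalibration, Trace

#: Typical normal-allele repeat counts per locus, used to place the
#: non-pathological allele cluster in synthetic traces.
NORMAL_ALLELE_CAG = {"ATXN1": 29, "ATXN2": 22, "ATXN3": 23, "ATXN7": 10}

#: Flanking amplicon length (bp) outside the repeat, per locus primer pair.
FLANK_BP = {"ATXN1": 120, "ATXN2": 100, "ATXN3": 140, "ATXN7": 110}

#: Target-EI ranges for the trace presets.  The fetal range brackets the
#: near-zero indices measured in first/second-trimester tissues; the adult
#: blood range covers mid-life blood draws of expansion-prone loci.
FETAL_EI_RANGE = (0.03, 0.10)
ADULT_BLOOD_EI_RANGE = (0.4, 1.5)

SCA_GENE = {"SCA1": "ATXN1", "SCA2": "ATXN2", "SCA3": "ATXN3", "SCA7": "ATXN7"}


@dataclass(frozen=True)
class TraceGenConfig:
    """Parameters of one synthetic electropherogram.

    ``tail_mean`` is the mean repeat offset of the (untruncated) expansion
    tail; larger values are needed to reach high target EIs.  ``noise_cv``
    is the per-peak coefficient of variation of the multiplicative height
    noise.
    """

    gene: str = "ATXN1"
    modal_cag: int = 48
    stutter_decay: float = 0.45
    tail_mean: float = 2.0
    tail_shape: str = "geometric"  # or "poisson"
    max_tail: int = 25
    main_height: float = 10000.0
    noise_cv: float = 0.05
    threshold: float = 0.03
    include_normal_allele: bool = True
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.stutter_decay < 1:
            raise ValueError("stutter_decay must lie in (0, 1)")
        if self.tail_mean <= 1:
            raise ValueError("tail_mean must exceed 1 (offsets start at 1)")


@dataclass(frozen=True)
class TraceSim:
    """A generated trace with its ground truth attached."""

    trace: Trace
    true_ei: float
    calibration: SizeCalibration
    config: TraceGenConfig


def _tail_weights(cfg: TraceGenConfig) -> np.ndarray:
    d = np.arange(1, cfg.max_tail + 1, dtype=float)
    if cfg.tail_shape == "geometric":
        p = 1.0 / cfg.tail_mean
        w = (1 - p) ** (d - 1) * p
    elif cfg.tail_shape == "poisson":
        lam = cfg.tail_mean
        w = np.exp(d * math.log(lam) - lam - np.array([math.lgamma(x + 1) for x in d]))
    else:
        raise ValueError(f"unknown tail shape {cfg.tail_shape!r}")
    return w / w.sum()


def _solve_tail_heights(cfg: TraceGenConfig, target_ei: float) -> dict[int, float]:
    """Expected expanded-peak heights whose noise-free EI equals the target.

    For a tail support of the first D offsets with relative weights ``w`` and
    total expanded height E, the retained-peak EI is
    ``E * sum(w_d d) / (h0 + E * sum(w_d))`` — increasing and continuous in
    E — so E has the closed form ``target * h0 / (A - target * B)``.  D is
    the longest support whose smallest peak still clears the detection
    threshold at the required E, keeping the emitted tail as long (and the
    morphology as realistic) as the target allows.
    """
    h0 = cfg.main_height
    theta = cfg.threshold
    if target_ei == 0:
        return {}
    w = _tail_weights(cfg)
    d = np.arange(1, cfg.max_tail + 1, dtype=float)

    max_achievable = 0.0
    # Prefer supports whose faintest peak clears the threshold with a 2x
    # safety margin, so height noise cannot knock it below detection and
    # bias the measured EI low; fall back to margin 1 for targets so small
    # that a near-threshold peak is unavoidable.
    for margin in (2.0, 1.0):
        best: dict[int, float] | None = None
        for D in range(1, cfg.max_tail + 1):
            A = float(np.sum(w[:D] * d[:D]))
            B = float(np.sum(w[:D]))
            # EI at the largest admissible mass (q -> 0.99 of total signal)
            e_cap = 99.0 * h0
            ei_cap = e_cap * A / (h0 + e_cap * B)
            max_achievable = max(max_achievable, ei_cap)
            if target_ei >= ei_cap or A - target_ei * B <= 0:
                continue
            E = target_ei * h0 / (A - target_ei * B)
            if E <= 0 or E > e_cap:
                continue
            if E * float(np.min(w[:D])) >= margin * theta * h0:
                best = {k + 1: float(E * w[k]) for k in range(D)}
        if best is not None:
            return best
    raise TargetUnreachableError(
        f"target EI {target_ei} is unreachable with tail_mean="
        f"{cfg.tail_mean}; achievable maximum ~ {max_achievable:.4f} "
        f"(increase tail_mean for larger indices)"
    )


def expected_peak_heights(cfg: TraceGenConfig, target_ei: float) -> dict[int, float]:
    """Noise-free expected heights keyed by CAG for one synthetic trace."""
    if target_ei < 0:
        raise ValueError("target_ei must be >= 0")
    heights: dict[int, float] = {cfg.modal_cag: cfg.main_height}
    for k in range(1, 5):  # PCR stutter left of the modal peak
        heights[cfg.modal_cag - k] = cfg.main_height * cfg.stutter_decay**k
    for delta, h in _solve_tail_heights(cfg, target_ei).items():
        heights[cfg.modal_cag + delta] = h
    if cfg.include_normal_allele:
        normal = NORMAL_ALLELE_CAG[cfg.gene]
        heights[normal] = cfg.main_height * 1.1
        for k in range(1, 3):
            heights[normal - k] = cfg.main_height * 1.1 * cfg.stutter_decay**k
    return heights


def default_calibration(cfg: TraceGenConfig) -> SizeCalibration:
    return SizeCalibration(
        anchor_bp=FLANK_BP[cfg.gene] + 3.0 * cfg.modal_cag,
        anchor_cag=cfg.modal_cag,
        gene=cfg.gene,
        plate_id="sim",
    )


def generate_trace(
    cfg: TraceGenConfig,
    target_ei: float,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    **trace_meta,
) -> TraceSim:
    """Generate one trace whose noise-free EI equals ``target_ei``.

    Returns the noisy trace, the exact noise-free EI (== ``target_ei``), and
    the bp-to-CAG calibration matching the synthetic sizes.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    heights = expected_peak_heights(cfg, target_ei)
    cal = default_calibration(cfg)
    sigma = math.sqrt(math.log1p(cfg.noise_cv**2))
    peaks = []
    for cag in sorted(heights):
        h = heights[cag]
        if cfg.noise_cv > 0:
            h *= float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        peaks.append(Peak(size_bp=cal.cag_to_bp(cag), height=h))
    trace = Trace(sample_id=sample_id, peaks=peaks, gene=cfg.gene, **trace_meta)
    return TraceSim(trace=trace, true_ei=float(target_ei), calibration=cal, config=cfg)


def generate_preset_trace(
    preset: str, rng: np.random.Generator, cfg: TraceGenConfig | None = None, **kw
) -> TraceSim:
    """Draw a trace from the ``"fetal"`` or ``"adult_blood"`` preset.

    Fetal targets are uniform on :data:`FETAL_EI_RANGE`; adult blood targets
    on :data:`ADULT_BLOOD_EI_RANGE` with a longer expansion tail.
    """
    if preset == "fetal":
        cfg = cfg or TraceGenConfig()
        lo, hi = FETAL_EI_RANGE
    elif preset == "adult_blood":
        cfg = cfg or TraceGenConfig(tail_mean=3.0)
        lo, hi = ADULT_BLOOD_EI_RANGE
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return generate_trace(cfg, float(rng.uniform(lo, hi)), rng=rng, **kw)


# ---------------------------------------------------------------------------
# Longitudinal cohort generator


@dataclass(frozen=True)
class GroupConfig:
    """Generating parameters of one disease group."""

    n_individuals: int
    cag_mean: float
    cag_sd: float
    ei_slope_per_year: float  # EI/year at the group-mean repeat length


@dataclass(frozen=True)
class CohortGenConfig:
    """Data-generating process of the longitudinal visit table.

    ``cag_slope_modifier`` (gamma) scales an individual's EI slope by
    ``1 + gamma * (cag - group mean)``, encoding the repeat-length dependence
    of expansion; the default yields EI-vs-CAG correlations in the 0.5-0.8
    band typical of expansion-prone loci.  ``ei_at_birth`` is the mean
    random intercept — near zero, as fetal tissues show almost no expansion.
    """

    groups: Mapping[str, GroupConfig] = field(
        default_factory=lambda: {
            "SCA1": GroupConfig(30, 48.2, 5.0, 0.023),
            "SCA2": GroupConfig(50, 39.7, 3.0, 0.012),
            "SCA3": GroupConfig(74, 71.5, 4.0, 0.008),
            "SCA7": GroupConfig(30, 44.1, 6.0, 0.055),
        }
    )
    ei_at_birth: float = 0.05
    intercept_sd: float = 0.12
    residual_sd: float = 0.18
    cag_slope_modifier: float = 0.05
    visit_counts: tuple[int, ...] = (2, 3)
    mean_span_years: float = 8.5
    span_sd_years: float = 2.5
    baseline_age_range: tuple[float, float] = (25.0, 65.0)
    onset_age_mean: float = 40.0
    onset_per_cag: float = 0.8  # years earlier onset per extra repeat
    sara_per_year: float = 1.2  # SARA points per year after onset
    seed: int | None = None


def generate_cohort(
    cfg: CohortGenConfig | None = None, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a longitudinal visit table plus per-individual ground truth.

    Returns ``(visits, truth)``.  ``visits`` has one row per visit with
    columns ``individual_id, group, gene, visit, age, cag_n, ei, sara,
    disease_duration, status_clinical, status_sara``; ``truth`` carries each
    individual's generating slope and intercept.
    """
    cfg = cfg or CohortGenConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    visit_rows, truth_rows = [], []
    for group, g in cfg.groups.items():
        gene = SCA_GENE.get(group, group)
        for i in range(g.n_individuals):
            ind = f"{group}_{i + 1:03d}"
            cag = int(round(rng.normal(g.cag_mean, g.cag_sd)))
            slope = g.ei_slope_per_year * (
                1.0 + cfg.cag_slope_modifier * (cag - g.cag_mean)
            )
            b0 = rng.normal(cfg.ei_at_birth, cfg.intercept_sd)
            onset = rng.normal(
                cfg.onset_age_mean - cfg.onset_per_cag * (cag - g.cag_mean), 5.0
            )
            n_visits = int(rng.choice(cfg.visit_counts))
            base_age = rng.uniform(*cfg.baseline_age_range)
            span = float(np.clip(rng.normal(cfg.mean_span_years, cfg.span_sd_years), 1.0, 31.0))
            ages = [base_age]
            if n_visits > 2:
                ages.extend(sorted(rng.uniform(base_age, base_age + span, n_visits - 2)))
            ages.append(base_age + span)
            truth_rows.append(
                {
                    "individual_id": ind,
                    "group": group,
                    "gene": gene,
                    "cag_n": cag,
                    "true_slope": slope,
                    "true_intercept": b0,
                    "onset_age": onset,
                }
            )
            for v, age in enumerate(ages, start=1):
                ei = max(0.0, b0 + slope * age + rng.normal(0.0, cfg.residual_sd))
                duration = age - onset
                if duration > 0:
                    sara = float(
                        np.clip(cfg.sara_per_year * duration + rng.normal(0, 1.0), 0, 40)
                    )
                else:
                    sara = float(np.clip(rng.uniform(0, 3.0), 0, 3.5))
                visit_rows.append(
                    {
                        "individual_id": ind,
                        "group": group,
                        "gene": gene,
                        "visit": v,
                        "age": age,
                        "cag_n": cag,
                        "ei": ei,
                        "sara": sara,
                        "disease_duration": max(duration, 0.0) if duration > 0 else None,
                        "status_clinical": "manifest" if duration > 0 else "premanifest",
                        "status_sara": "ataxic" if sara > 3.5 else "preataxic",
                    }
                )
    return pd.DataFrame(visit_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Tissue panels


#: Default target-EI ranges per tissue, ordered cerebellum < brainstem <
#: cortex as observed in postmortem panels.
DEFAULT_TISSUE_EI_RANGES = {
    "cerebellum": (0.3, 0.7),
    "brainstem": (1.0, 1.8),
    "frontal cortex": (1.6, 2.6),
}


def generate_tissue_panel(
    gene: str,
    modal_cag: int,
    rng: np.random.Generator,
    tissue_ei_ranges: Mapping[str, tuple[float, float]] | None = None,
    donor_id: str = "donor",
    cfg: TraceGenConfig | None = None,
) -> dict[str, TraceSim]:
    """Generate one synthetic brain donor's per-tissue traces.

    Target EIs are drawn uniformly from each tissue's range.  The cerebellum
    preset shifts the modal peak one repeat below the reference modal, the
    characteristic cerebellar pattern.  At least two tissues are required
    unless a single-tissue mapping is passed explicitly.
    """
    ranges = dict(tissue_ei_ranges or DEFAULT_TISSUE_EI_RANGES)
    # long flat tail: cortical EIs above ~2 must come from far-spread
    # products, not a pile-up at +1 that would displace the modal peak
    base = cfg or TraceGenConfig(gene=gene, modal_cag=modal_cag, tail_mean=6.0)
    out: dict[str, TraceSim] = {}
    for tissue, (lo, hi) in ranges.items():
        modal = modal_cag - 1 if tissue == "cerebellum" else modal_cag
        tissue_cfg = replace(base, gene=gene, modal_cag=modal)
        target = float(rng.uniform(lo, hi))
        out[tissue] = generate_trace(
            tissue_cfg,
            target,
            rng=rng,
            sample_id=f"{donor_id}_{tissue.replace(' ', '_')}",
            tissue=tissue,
            individual_id=donor_id,
        )
    return out


# ---------------------------------------------------------------------------
# Ct tables


def generate_ct_table(
    rng: np.random.Generator,
    individuals: Sequence[str] = ("donor1", "donor2"),
    tissues: Sequence[str] = ("cerebellum", "frontal cortex", "blood"),
    genes: Sequence[str] = ("ATXN1", "MSH3", "FAN1"),
    cerebellum_boost: float = 1.5,
    replicate_sd: float = 0.15,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table with cerebellum-high target expression.

    Target Cts in the cerebellum are lowered by ``cerebellum_boost`` cycles
    (higher expression), mimicking the cerebellum-high / cortex-low pattern
    of ataxin and DNA-repair gene expression.
    """
    rows = []
    for ind in individuals:
        for tissue in tissues:
            ref_ct = rng.normal(20.0, 0.3)
            for gene in genes:
                base = rng.normal(26.0, 0.5)
                if tissue == "cerebellum":
                    base -= cerebellum_boost
                rows.append(
                    {
                        "individual_id": ind,
                        "tissue": tissue,
                        "gene_of_interest": gene,
                        "ct_target": base + rng.normal(0, replicate_sd),
                        "ct_reference": ref_ct + rng.normal(0, replicate_sd),
                    }
                )
    return pd.DataFrame(rows)
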