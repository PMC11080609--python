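"""Per-trace somatic instability metrics: modal CAG, expansion index, profiles.

A fragment-analysis trace of an expanded CAG allele peaks around a main
signal — the modal repeat, used for diagnosis.  Peaks *left* of the modal
peak are dominated by PCR stutter (polymerase slippage shortens products) and
are never counted.  Peaks *right* of the modal peak are somatically expanded
repeats; their heights, relative to the total retained signal, quantify the
fraction of cells carrying each longer repeat.

The expansion index (EI) summarises a trace in one number.  With modal-peak
height ``h0``, expanded peaks at offsets ``d_i >= 1`` (in repeats) with
heights ``h_i``, and a relative detection threshold ``theta`` (default 0.03,
set where genuine low-intensity peaks separate from background):

* peaks with ``h_i < theta * h0`` are excluded,
* ``S = h0 + sum(retained h_i)``,
* ``EI = sum over retained peaks of (h_i / S) * d_i``.

EI is 0 exactly when no expanded peak survives the threshold — no expansion
beyond the inherited allele.  The normalizing sum uses only threshold-retained
peaks; normalization over all detected expanded peaks is available via
``subthreshold_in_norm=True`` for sensitivity analyses.

For longitudinal series the *same* reference modal CAG (normally the
diagnostic repeat count) is used for every trace of an individual, so that a
somatic +1 shift of the tallest peak between visits registers as expansion
rather than silently re-anchoring the index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from cagmosaic.errors import EmptyWindowError, MissingModalPeakError
from cagmosaic.trace_io import (
    PATHOLOGICAL_THRESHOLD,
    SizeCalibration,
    Trace,
    bp_to_cag,
)


@dataclass(frozen=True)
class RepeatPeak:
    """A peak re-indexed on the repeat scale, relative to the reference modal."""

    cag: int
    delta: int
    height: float
    rel_height: float


@dataclass(frozen=True)
class InstabilityProfile:
    """Instability summary of one trace.

    ``modal_cag`` is the trace's own tallest in-window peak; it can differ
    from ``reference_modal_cag`` (the per-individual fixed value) — e.g.
    cerebellar traces typically call one repeat less than the diagnostic CAG.
    ``percent_by_cag`` covers the reference-modal peak plus retained expanded
    peaks and sums to 100.  ``n_additional_cags`` is the largest retained
    offset.
    """

    trace_id: str
    modal_cag: int
    reference_modal_cag: int
    ei: float
    threshold: float
    retained: tuple[RepeatPeak, ...]
    percent_by_cag: Mapping[int, float]
    n_additional_cags: int


def _window_bounds(
    trace: Trace, expanded_window: tuple[int, int | None] | None
) -> tuple[int, float]:
    if expanded_window is not None:
        lo, hi = expanded_window
        return lo, float("inf") if hi is None else hi
    if trace.gene is not None:
        return PATHOLOGICAL_THRESHOLD[trace.gene], float("inf")
    return 1, float("inf")


def heights_by_cag(
    trace: Trace,
    cal: SizeCalibration,
    expanded_window: tuple[int, int | None] | None = None,
) -> dict[int, float]:
    """Bin peak heights by integer CAG inside the expanded-allele window.

    Traces carry both alleles; the window (default: the locus's pathological
    range, ``[threshold, inf)``) restricts analysis to the expanded-allele
    cluster.  Peaks rounding to the same repeat are summed.
    """
    lo, hi = _window_bounds(trace, expanded_window)
    out: dict[int, float] = {}
    for p in trace.peaks:
        cag = bp_to_cag(p.size_bp, cal)
        if lo <= cag <= hi:
            out[cag] = out.get(cag, 0.0) + p.height
    return out


def call_modal_peak(
    trace: Trace,
    cal: SizeCalibration,
    expanded_window: tuple[int, int | None] | None = None,
) -> int:
    """Return the CAG of the tallest peak in the expanded-allele window.

    Ties break toward the smaller CAG so that stutter asymmetry cannot
    inflate the reference.
    """
    heights = heights_by_cag(trace, cal, expanded_window)
    if not heights:
        lo, hi = _window_bounds(trace, expanded_window)
        raise EmptyWindowError(
            f"trace {trace.sample_id!r}: no peak maps into the CAG window "
            f"[{lo}, {hi}]"
        )
    return min(heights, key=lambda c: (-heights[c], c))


def compute_ei(
    trace: Trace,
    reference_modal: int,
    cal: SizeCalibration,
    threshold: float = 0.03,
    expanded_window: tuple[int, int | None] | None = None,
    subthreshold_in_norm: bool = False,
) -> InstabilityProfile:
    """Compute the expansion index and profile of one trace.

    Parameters
    ----------
    reference_modal:
        The per-individual fixed modal CAG; the peak at this repeat supplies
        the anchor height ``h0``.  See
        :func:`longitudinal_reference_modal`.
    threshold:
        Relative cutoff ``theta`` in (0, 1); expanded peaks below
        ``theta * h0`` are excluded before normalization.
    subthreshold_in_norm:
        If True, the normalizing sum S includes sub-threshold expanded peaks
        (they still contribute nothing to the weighted sum).  Off by default.

    Raises
    ------
    MissingModalPeakError
        If the reference-modal peak is absent or has zero height in the
        window — usually a trace/visit modal mismatch.
    """
    if reference_modal < 1:
        raise ValueError(f"reference_modal must be >= 1, got {reference_modal}")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")

    heights = heights_by_cag(trace, cal, expanded_window)
    h0 = heights.get(reference_modal, 0.0)
    if h0 <= 0:
        raise MissingModalPeakError(
            f"trace {trace.sample_id!r}: no peak at reference modal CAG "
            f"{reference_modal} inside the expanded window; re-call the modal "
            f"peak for this trace"
        )

    expanded = {c: h for c, h in heights.items() if c > reference_modal}
    retained = {c: h for c, h in expanded.items() if h >= threshold * h0}

    norm = h0 + sum(retained.values())
    if subthreshold_in_norm:
        norm = h0 + sum(expanded.values())

    peaks = tuple(
        RepeatPeak(cag=c, delta=c - reference_modal, height=h, rel_height=h / h0)
        for c, h in sorted(retained.items())
    )
    ei = sum((p.height / norm) * p.delta for p in peaks)

    profile_heights = {reference_modal: h0, **retained}
    s_profile = sum(profile_heights.values())
    percent = {c: 100.0 * h / s_profile for c, h in sorted(profile_heights.items())}

    return InstabilityProfile(
        trace_id=trace.sample_id,
        modal_cag=call_modal_peak(trace, cal, expanded_window),
        reference_modal_cag=reference_modal,
        ei=ei,
        threshold=threshold,
        retained=peaks,
        percent_by_cag=percent,
        n_additional_cags=max((p.delta for p in peaks), default=0),
    )


def percent_mutant_alleles(
    trace: Trace,
    reference_modal: int,
    cal: SizeCalibration,
    threshold: float = 0.03,
    expanded_window: tuple[int, int | None] | None = None,
) -> dict[int, float]:
    """"% mutant alleles" profile: percentage of retained signal per CAG.

    Over the reference-modal peak plus threshold-retained expanded peaks,
    ``percent(cag) = 100 * h / S``; the values sum to 100.
    """
    profile = compute_ei(
        trace, reference_modal, cal, threshold=threshold, expanded_window=expanded_window
    )
    return dict(profile.percent_by_cag)


def longitudinal_reference_modal(
    traces: Sequence[Trace],
    cal: SizeCalibration,
    diagnostic_cag: int | None = None,
    expanded_window: tuple[int, int | None] | None = None,
) -> int:
    """Pick the single reference modal CAG for all traces of one individual.

    The diagnostic repeat count wins when supplied; otherwise the modal of
    the earliest trace (by sampling age, falling back to input order) is
    used.  Later traces whose tallest peak has drifted upward then score that
    drift as expansion instead of re-anchoring.
    """
    if diagnostic_cag is not None:
        return diagnostic_cag
    if not traces:
        raise ValueError("at least one trace is required")
    with_age = [t for t in traces if t.age_at_sample is not None]
    earliest = min(with_age, key=lambda t: t.age_at_sample) if with_age else traces[0]
    return call_modal_peak(earliest, cal, expanded_window)


def profiles_to_table(profiles: Sequence[InstabilityProfile]):
    """Per-trace summary table (one row per trace) ready to write as TSV."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "trace_id": p.trace_id,
                "modal_cag": p.modal_cag,
                "reference_modal": p.reference_modal_cag,
                "ei": p.ei,
                "n_additional_cags": p.n_additional_cags,
            }
            for p in profiles
        ]
    )


def percent_profiles_long(profiles: Sequence[InstabilityProfile]):
    """Long-format table of the percent-by-CAG profiles."""
    import pandas as pd

    rows = []
    for p in profiles:
        for cag, pct in p.percent_by_cag.items():
            rows.append({"trace_id": p.trace_id, "cag": cag, "percent": pct})
    return pd.DataFrame(rows)
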