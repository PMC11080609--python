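"""Expansion-index engine: modal calling, EI, percent profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from cagmosaic.errors import EmptyWindowError, MissingModalPeakError
from cagmosaic.instability import (
    call_modal_peak,
    compute_ei,
    longitudinal_reference_modal,
    percent_mutant_alleles,
)

WINDOW = (39, None)


def brute_force_ei(heights_by_cag, reference_modal, threshold):
    """Independent direct translation of the EI definition.

    From a {cag: height} mapping: anchor height at the reference modal;
    candidate expanded peaks strictly right of it; drop those below
    threshold * h0; EI = sum of (h / (h0 + retained sum)) * offset.
    """
    h0 = heights_by_cag[reference_modal]
    retained = {}
    for cag, h in heights_by_cag.items():
        d = cag - reference_modal
        if d >= 1 and h >= threshold * h0:
            retained[d] = h
    S = h0 + sum(retained.values())
    return sum(h / S * d for d, h in retained.items())


class TestModalCall:
    def test_singleton(self, make_trace, cal):
        assert call_modal_peak(make_trace({54: 900}), cal, WINDOW) == 54

    def test_cerebellar_minus_one_shift(self, make_trace, cal):
        """A trace whose tallest peak sits one repeat below the diagnostic
        CAG (the cerebellar pattern) calls the shifted modal."""
        tr = make_trace({72: 900, 73: 880, 74: 300})
        assert call_modal_peak(tr, cal, WINDOW) == 72

    def test_tie_breaks_to_smaller_cag(self, make_trace, cal):
        for heights in ({45: 500, 46: 500}, {46: 500, 45: 500}):
            assert call_modal_peak(make_trace(heights), cal, WINDOW) == 45

    def test_normal_allele_outside_window_ignored(self, make_trace, cal):
        tr = make_trace({29: 2000, 54: 900, 55: 300})
        assert call_modal_peak(tr, cal, WINDOW) == 54

    def test_empty_window_raises(self, make_trace, cal):
        with pytest.raises(EmptyWindowError):
            call_modal_peak(make_trace({29: 2000}), cal, WINDOW)


class TestComputeEI:
    def test_modal_only_is_zero(self, make_trace, cal):
        prof = compute_ei(make_trace({45: 1000}), 45, cal, expanded_window=WINDOW)
        assert prof.ei == 0.0
        assert prof.n_additional_cags == 0

    def test_hand_worked_example(self, make_trace, cal):
        """h0=1000 with expanded peaks 300/90/20 at +1/+2/+3 and theta=0.03:
        the +3 peak (20 < 30) is dropped, S=1390, EI=(300+180)/1390."""
        tr = make_trace({45: 1000, 46: 300, 47: 90, 48: 20})
        prof = compute_ei(tr, 45, cal, threshold=0.03, expanded_window=WINDOW)
        assert prof.ei == pytest.approx(480 / 1390, abs=1e-12)
        assert prof.n_additional_cags == 2
        assert [p.delta for p in prof.retained] == [1, 2]

    def test_all_below_threshold_is_zero(self, make_trace, cal):
        tr = make_trace({45: 1000, 46: 29.9, 47: 5})
        prof = compute_ei(tr, 45, cal, threshold=0.03, expanded_window=WINDOW)
        assert prof.ei == 0.0

    def test_stutter_side_never_counted(self, make_trace, cal):
        tr = make_trace({43: 500, 44: 800, 45: 1000})
        prof = compute_ei(tr, 45, cal, expanded_window=WINDOW)
        assert prof.ei == 0.0

    def test_missing_modal_raises(self, make_trace, cal):
        with pytest.raises(MissingModalPeakError):
            compute_ei(make_trace({46: 1000}), 45, cal, expanded_window=WINDOW)

    def test_reference_below_trace_modal_keeps_taller_peaks(self, make_trace, cal):
        """With a fixed per-individual reference, a later visit whose tallest
        peak drifted to +1 scores that peak as expansion signal."""
        tr = make_trace({42: 800, 43: 1000})
        prof = compute_ei(tr, 42, cal, expanded_window=WINDOW)
        assert prof.ei == pytest.approx(1000 / 1800 * 1)
        assert prof.modal_cag == 43

    def test_scale_invariance(self, make_trace, cal, rng):
        heights = {45 + k: float(h) for k, h in enumerate(rng.uniform(50, 2000, 8))}
        heights[45] = 3000.0
        tr = make_trace(heights)
        base = compute_ei(tr, 45, cal, expanded_window=WINDOW)
        for c in (0.01, 3.7, 1000.0):
            scaled = compute_ei(tr.scaled(c), 45, cal, expanded_window=WINDOW)
            assert scaled.ei == pytest.approx(base.ei, rel=1e-12)
            assert scaled.modal_cag == base.modal_cag
            for cag in base.percent_by_cag:
                assert scaled.percent_by_cag[cag] == pytest.approx(
                    base.percent_by_cag[cag], rel=1e-12
                )

    def test_threshold_monotonicity_decaying_tail(self, make_trace, cal, rng):
        """On traces with a monotone-decaying expansion tail (the observed
        morphology) raising the detection threshold can only drop the
        farthest, faintest peaks, so EI is non-increasing in theta."""
        for _ in range(20):
            n = int(rng.integers(1, 9))
            heights = {45: 1000.0}
            h = 900.0
            for k in range(1, n + 1):
                h *= float(rng.uniform(0.3, 0.9))
                heights[45 + k] = h
            tr = make_trace(heights)
            eis = [
                compute_ei(tr, 45, cal, threshold=t, expanded_window=WINDOW).ei
                for t in (0.01, 0.03, 0.1, 0.3, 0.6)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(eis, eis[1:]))

    def test_threshold_monotonicity_all_detected_norm(self, make_trace, cal, rng):
        """With the normalizing sum over all detected peaks, threshold
        monotonicity holds for arbitrary peak-height patterns."""
        for _ in range(20):
            n = int(rng.integers(1, 9))
            heights = {45: 1000.0}
            for k in range(1, n + 1):
                heights[45 + k] = float(rng.uniform(1, 900))
            tr = make_trace(heights)
            eis = [
                compute_ei(
                    tr,
                    45,
                    cal,
                    threshold=t,
                    expanded_window=WINDOW,
                    subthreshold_in_norm=True,
                ).ei
                for t in (0.01, 0.03, 0.1, 0.3, 0.6)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(eis, eis[1:]))

    def test_ei_below_max_retained_delta_and_farthest_peak_increases(
        self, make_trace, cal
    ):
        heights = {45: 1000.0, 46: 400.0, 49: 200.0}
        prof = compute_ei(make_trace(heights), 45, cal, expanded_window=WINDOW)
        assert prof.ei < max(p.delta for p in prof.retained)
        taller = dict(heights)
        taller[49] = 300.0
        prof2 = compute_ei(make_trace(taller), 45, cal, expanded_window=WINDOW)
        assert prof2.ei > prof.ei

    @given(data=hst.data())
    @settings(deadline=None, max_examples=150)
    def test_oracle_equivalence_random_traces(self, data):
        """compute_ei matches the independent brute-force definition to 1e-12
        on random traces of up to 12 peaks."""
        from cagmosaic.trace_io import Peak, SizeCalibration, Trace

        cal = SizeCalibration(anchor_bp=250.0, anchor_cag=54)
        n = data.draw(hst.integers(min_value=0, max_value=11))
        deltas = data.draw(
            hst.lists(
                hst.integers(min_value=-4, max_value=15),
                min_size=n,
                max_size=n,
                unique=True,
            )
        )
        heights = {
            54
            + d: data.draw(
                hst.floats(min_value=0.5, max_value=5000, allow_nan=False)
            )
            for d in deltas
            if d != 0
        }
        heights[54] = data.draw(hst.floats(min_value=1, max_value=5000))
        threshold = data.draw(hst.sampled_from([0.01, 0.03, 0.1, 0.25]))
        tr = Trace(
            sample_id="h",
            peaks=[Peak(size_bp=cal.cag_to_bp(c), height=h) for c, h in heights.items()],
        )
        prof = compute_ei(tr, 54, cal, threshold=threshold, expanded_window=(40, None))
        expected = brute_force_ei(heights, 54, threshold)
        assert prof.ei == pytest.approx(expected, abs=1e-12)

    def test_subthreshold_in_norm_flag(self, make_trace, cal):
        tr = make_trace({45: 1000, 46: 300, 47: 20})
        strict = compute_ei(tr, 45, cal, expanded_window=WINDOW)
        loose = compute_ei(
            tr, 45, cal, expanded_window=WINDOW, subthreshold_in_norm=True
        )
        assert strict.ei == pytest.approx(300 / 1300)
        assert loose.ei == pytest.approx(300 / 1320)


class TestPercentProfile:
    def test_singleton(self, make_trace, cal):
        pct = percent_mutant_alleles(make_trace({45: 777}), 45, cal)
        assert pct == {45: 100.0}

    def test_three_peak_profile(self, make_trace, cal):
        pct = percent_mutant_alleles(
            make_trace({45: 1000, 46: 300, 47: 90}), 45, cal
        )
        assert pct[45] == pytest.approx(100 * 1000 / 1390, abs=5e-3)
        assert pct[46] == pytest.approx(100 * 300 / 1390, abs=5e-3)
        assert pct[47] == pytest.approx(100 * 90 / 1390, abs=5e-3)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_two_equal_peaks_split_evenly(self, make_trace, cal):
        pct = percent_mutant_alleles(make_trace({45: 600, 46: 600}), 45, cal)
        assert pct[45] == pytest.approx(50.0)
        assert pct[46] == pytest.approx(50.0)

    def test_sums_to_100_random(self, make_trace, cal, rng):
        for _ in range(25):
            heights = {45: 1000.0}
            for k in range(1, int(rng.integers(2, 10))):
                heights[45 + k] = float(rng.uniform(1, 1500))
            pct = percent_mutant_alleles(make_trace(heights), 45, cal)
            assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)


class TestLongitudinalReference:
    def test_diagnostic_wins(self, make_trace, cal):
        traces = [
            make_trace({43: 900}, sample_id="v2", age_at_sample=50),
            make_trace({44: 900}, sample_id="v3", age_at_sample=57),
        ]
        assert longitudinal_reference_modal(traces, cal, diagnostic_cag=42) == 42

    def test_fallback_to_earliest_trace_modal(self, make_trace, cal):
        traces = [
            make_trace({44: 900}, sample_id="v2", age_at_sample=57),
            make_trace({42: 900}, sample_id="v1", age_at_sample=44),
        ]
        assert longitudinal_reference_modal(traces, cal) == 42

    def test_single_trace_fallback(self, make_trace, cal):
        assert longitudinal_reference_modal([make_trace({54: 1})], cal) == 54

    def test_consistency_across_identical_traces(self, make_trace, cal):
        traces = [make_trace({54: 900}, sample_id=f"v{i}") for i in range(3)]
        assert longitudinal_reference_modal(traces, cal) == 54
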