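import numpy as np
import pytest

from cagmosaic.trace_io import Peak, SizeCalibration, Trace


@pytest.fixture
def cal():
    """Calibration anchored at 250 bp = 54 CAG, 3 bp per repeat."""
    return SizeCalibration(anchor_bp=250.0, anchor_cag=54, plate_id="p1", gene="ATXN1")


@pytest.fixture
def make_trace(cal):
    """Build a trace from a {cag: height} mapping using the test calibration."""

    def _make(heights, sample_id="t1", gene="ATXN1", **meta):
        peaks = [
            Peak(size_bp=cal.cag_to_bp(cag), height=h) for cag, h in heights.items()
        ]
        return Trace(sample_id=sample_id, peaks=peaks, gene=gene, **meta)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
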