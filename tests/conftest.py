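import numpy as np
import pytest

from movelements.io import TrajectoryRecording
from movelements.preprocess import VelocityRecording


@pytest.fixture
def make_recording():
    """Factory for uniformly sampled position recordings (mm, s)."""

    def _make(axes: dict, rate: float = 100.0, **meta) -> TrajectoryRecording:
        axes = {k: np.asarray(v, dtype=float) for k, v in axes.items()}
        n = len(next(iter(axes.values())))
        return TrajectoryRecording(
            time=np.arange(n) / rate, axes=axes, sampling_rate=rate, metadata=meta
        )

    return _make


@pytest.fixture
def make_velocity():
    """Factory for velocity recordings given raw per-axis samples (mm/s)."""

    def _make(axes: dict, rate: float = 1.0) -> VelocityRecording:
        axes = {k: np.asarray(v, dtype=float) for k, v in axes.items()}
        n = len(next(iter(axes.values())))
        return VelocityRecording(
            time=np.arange(n) / rate, axes=axes, sampling_rate=rate
        )

    return _make


@pytest.fixture
def run_pipeline():
    """Differentiate (optionally low-pass) a recording and segment all axes."""
    from movelements import decompose as dec
    from movelements import preprocess as pp

    def _run(recording, cutoff_hz=None, axes=None, criteria=None):
        rec = pp.lowpass(recording, cutoff_hz) if cutoff_hz else recording
        vel = pp.differentiate(rec)
        elements = []
        for axis in axes or vel.axis_names:
            elements.extend(dec.segment(vel, axis))
        if criteria is None:
            return elements
        kept, discarded = dec.apply_filters(elements, criteria)
        return kept, discarded

    return _run
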