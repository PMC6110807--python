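"""Low-pass filtering and per-axis numerical differentiation.

Marker positions are smoothed with a zero-phase Butterworth filter (4th order,
10 Hz cut-off by default, applied forward-backward) before differentiation.
Zero-phase filtering preserves the timing of velocity zero crossings, which
the downstream segmentation depends on.  Velocity is obtained by central
differences at interior samples and one-sided differences at the endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from movelements.io import TrajectoryRecording

__all__ = ["VelocityRecording", "lowpass", "differentiate"]

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_ORDER = 4


@dataclass
class VelocityRecording:
    """Per-axis velocity (mm/s) on the same time base as its source recording.

    ``provenance`` records the source metadata and the filter settings that
    produced the positions this velocity was derived from.
    """

    time: np.ndarray
    axes: dict[str, np.ndarray]
    sampling_rate: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(self.axes.keys())


def lowpass(
    recording: TrajectoryRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> TrajectoryRecording:
    """Zero-phase Butterworth low-pass of every position axis.

    The filter is applied forward and backward (``filtfilt``) so it introduces
    no phase lag; constant (DC) series pass through unchanged.  Reflective
    padding suppresses edge transients that would otherwise create spurious
    zero crossings near the series boundaries.

    Raises ``ValueError`` if ``cutoff_hz`` is at or above the Nyquist
    frequency of the recording.
    """
    nyquist = recording.sampling_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=recording.sampling_rate, output="sos")
    n = recording.n_samples
    padlen = min(n - 1, max(3 * (2 * order + 1), 24))
    axes = {
        name: signal.sosfiltfilt(sos, series, padtype="even", padlen=padlen)
        for name, series in recording.axes.items()
    }
    meta = dict(recording.metadata)
    meta["filter"] = {"type": "butterworth", "order": order, "cutoff_hz": cutoff_hz, "zero_phase": True}
    return TrajectoryRecording(
        time=recording.time.copy(),
        axes=axes,
        sampling_rate=recording.sampling_rate,
        metadata=meta,
    )


def differentiate(recording: TrajectoryRecording) -> VelocityRecording:
    """Differentiate each position axis to velocity (mm/s).

    Central differences at interior samples (second-order accurate, exact for
    quadratics), plain one-sided differences at the two endpoints (exact for
    lines).  Requires at least 3 samples.
    """
    if recording.n_samples < 3:
        raise ValueError(
            f"need at least 3 samples to differentiate, got {recording.n_samples}"
        )
    # uniform sampling is a validated invariant: differentiate against the
    # scalar step, which keeps constant series at exactly zero velocity
    dt = 1.0 / recording.sampling_rate
    axes = {
        name: np.gradient(series, dt, edge_order=1)
        for name, series in recording.axes.items()
    }
    return VelocityRecording(
        time=recording.time.copy(),
        axes=axes,
        sampling_rate=recording.sampling_rate,
        provenance={"source_metadata": dict(recording.metadata)},
    )
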