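"""Zero-crossing segmentation of per-axis velocity into movement elements.

A movement element is a maximal time segment over which one axis's velocity
keeps a single sign, bounded by zero crossings of the velocity time series.
Crossing times are interpolated linearly between the bracketing samples, which
matters because the cost-of-time constant K scales as t_f^6.  Task-specific
minimum displacement / duration / velocity thresholds discard elements that
could not be detected reliably at realistic signal-to-noise ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from movelements.preprocess import VelocityRecording

logger = logging.getLogger(__name__)

__all__ = [
    "MovementElement",
    "ElementFilterCriteria",
    "segment",
    "apply_filters",
    "task_criteria",
    "TASK_CRITERIA",
]


@dataclass
class MovementElement:
    """One zero-crossing-bounded velocity segment on a single axis.

    ``D`` is the signed displacement (trapezoidal integral of velocity over
    the element, including the interpolated zero endpoints), ``t_f`` the
    duration between crossing times, and the identity
    ``mean_abs_velocity == |D| / t_f`` holds by construction.
    ``boundary_flag`` marks segments truncated by the start or end of the
    series rather than a zero crossing; their duration is not defined by two
    crossings, so they are excluded from scaling fits by default.
    """

    axis: str
    t_start: float
    t_end: float
    D: float
    sign: int
    boundary_flag: bool
    sample_times: np.ndarray
    sample_velocities: np.ndarray
    peak_abs_velocity: float = 0.0
    fit_r: Optional[float] = None
    K: Optional[float] = None
    kept: Optional[bool] = None
    reason: Optional[str] = None

    @property
    def t_f(self) -> float:
        return self.t_end - self.t_start

    @property
    def mean_abs_velocity(self) -> float:
        return abs(self.D) / self.t_f

    @property
    def n_samples(self) -> int:
        return int(np.asarray(self.sample_times).size)

    def to_row(self) -> dict:
        return {
            "axis": self.axis,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "t_f": self.t_f,
            "D": self.D,
            "mean_abs_velocity": self.mean_abs_velocity,
            "peak_abs_velocity": self.peak_abs_velocity,
            "sign": self.sign,
            "boundary": self.boundary_flag,
            "fit_r": self.fit_r,
            "K": self.K,
            "kept": self.kept,
            "reason": self.reason,
        }


@dataclass
class ElementFilterCriteria:
    """Task-specific acceptance thresholds, internal units (mm, s, mm/s).

    ``min_velocity_mm_s`` is compared against the peak absolute velocity
    within the element; a mean-velocity test would duplicate the
    displacement and duration criteria through v_bar = |D|/t_f.
    """

    min_displacement_mm: float = 0.0
    min_duration_s: float = 0.0
    min_velocity_mm_s: float = 0.0
    exclude_boundary: bool = True

    def __post_init__(self) -> None:
        if min(self.min_displacement_mm, self.min_duration_s, self.min_velocity_mm_s) < 0:
            raise ValueError("thresholds must be non-negative")


#: Published per-task thresholds: drawing/handwriting 5 mm, 3D reaching 3 mm,
#: 1D ruler movements 20 mm; durations 100 ms (200 ms for 1D); peak velocity
#: 10 mm/s for every task.
TASK_CRITERIA = {
    "drawing": ElementFilterCriteria(5.0, 0.1, 10.0),
    "handwriting": ElementFilterCriteria(5.0, 0.1, 10.0),
    "movement_3d": ElementFilterCriteria(3.0, 0.1, 10.0),
    "movement_1d": ElementFilterCriteria(20.0, 0.2, 10.0),
}


def task_criteria(task_name: str) -> ElementFilterCriteria:
    """Return the published filter thresholds for a named task."""
    try:
        return TASK_CRITERIA[task_name]
    except KeyError:
        raise KeyError(
            f"unknown task {task_name!r}; valid tasks: {sorted(TASK_CRITERIA)}"
        ) from None


def _zero_runs_to_crossings(v: np.ndarray, t: np.ndarray) -> list[float]:
    """Crossing times of a velocity series.

    Sign changes between nonzero samples are interpolated linearly; an exact
    zero sample is itself a crossing point.  A run of two or more consecutive
    zeros (a rest period) yields crossings at both ends of the run, so an
    element abutting a rest keeps its true onset/offset and no zero-length
    element is created (the all-zero span in between carries no movement and
    is dropped downstream).  Because the central-difference operator smears a
    rest-to-movement junction by one sample on each side, the rest-adjacent
    crossing is refined by extrapolating the first (last) two moving samples
    linearly back to zero; K scales as t_f^6, so this sub-sample timing
    accuracy dominates the K estimate.
    """
    crossings: list[float] = []
    n = v.size
    dt = float(t[1] - t[0]) if n > 1 else 0.0

    def _rest_boundary(samples: list[int], fallback: float, lo: float, hi: float) -> float:
        """Sub-sample time at which motion departs from (or settles into) rest.

        ``samples`` are the indices of the 4 moving samples nearest the rest,
        nearest first.  A movement leaving rest smoothly has v ~ c*tau^2 near
        the boundary, and the central-difference estimate carries a constant
        bias of (dt^2/6)*v'' = c*dt^2/3 wherever its window does not straddle
        the boundary; the two nearest samples DO straddle it, so they are
        dropped and v = c*((t - t0)^2 + dt^2/3) is solved on the next two.
        Falls back to a plain secant through the two nearest samples, then to
        the rest-run endpoint.
        """
        samples = [k for k in samples if 0 <= k < n]
        vals = [abs(v[k]) for k in samples]
        same_sign = len({np.sign(v[k]) for k in samples}) == 1
        if len(vals) == 4 and same_sign and all(x > 0 for x in vals) and vals[3] > vals[2] > 0:
            t1, t2 = t[samples[2]], t[samples[3]]
            r = vals[2] / vals[3]
            h = dt * dt / 3.0
            a = 1.0 - r
            b = -2.0 * (t1 - r * t2)
            c = t1 * t1 - r * t2 * t2 + h * (1.0 - r)
            disc = b * b - 4.0 * a * c
            if a != 0.0 and disc >= 0.0:
                roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
                inside = [x for x in roots if lo <= x <= hi]
                if inside:
                    return float(min(inside, key=lambda x: abs(x - fallback)))
        if len(vals) >= 2 and vals[0] > 0 and vals[1] > vals[0]:
            t1, t2 = t[samples[0]], t[samples[1]]
            tc = t1 - vals[0] * (t2 - t1) / (vals[1] - vals[0])
            return float(np.clip(tc, lo, hi))
        return fallback

    def _extrapolate_onset(j: int) -> float:
        # rest run ends at sample j; motion begins within (t[j], t[j+2])
        return _rest_boundary(
            [j + 1, j + 2, j + 3, j + 4],
            fallback=float(t[j]),
            lo=float(t[j]),
            hi=float(t[min(j + 2, n - 1)]),
        )

    def _extrapolate_offset(i: int) -> float:
        # rest run starts at sample i; motion ends within (t[i-2], t[i])
        return _rest_boundary(
            [i - 1, i - 2, i - 3, i - 4],
            fallback=float(t[i]),
            lo=float(t[max(i - 2, 0)]),
            hi=float(t[i]),
        )

    rest_spans: list[tuple[float, float]] = []
    i = 0
    while i < n:
        if v[i] == 0.0:
            j = i
            while j + 1 < n and v[j + 1] == 0.0:
                j += 1
            if j > i:
                left = _extrapolate_offset(i)
                right = max(_extrapolate_onset(j), left)
                crossings.extend([left, right])
                rest_spans.append((left, right))
            else:
                crossings.append(float(t[i]))
            i = j + 1
        else:
            if i + 1 < n and v[i + 1] != 0.0 and v[i] * v[i + 1] < 0.0:
                # linear interpolation between bracketing samples
                tc = t[i] + (t[i + 1] - t[i]) * v[i] / (v[i] - v[i + 1])
                crossings.append(float(tc))
            i += 1
    return crossings, rest_spans


def segment(velocity_recording: VelocityRecording, axis: str) -> list[MovementElement]:
    """Segment one axis's velocity series at zero crossings.

    Returns ordered, non-overlapping elements; contiguous elements alternate
    in sign; every nonzero sample of the series belongs to exactly one
    element.  Segments consisting solely of exact zeros (rest periods at the
    series boundaries) carry no movement and are dropped.  An all-zero series
    returns an empty list with a warning.
    """
    if axis not in velocity_recording.axes:
        raise KeyError(
            f"axis {axis!r} not in recording (has {velocity_recording.axis_names})"
        )
    t = np.asarray(velocity_recording.time, dtype=float)
    v = np.asarray(velocity_recording.axes[axis], dtype=float)

    if not np.any(v != 0.0):
        logger.warning("axis %s: velocity identically zero; no elements", axis)
        return []

    crossings, rest_spans = _zero_runs_to_crossings(v, t)

    # Segment boundaries: series start, crossings, series end.
    bounds: list[tuple[float, bool]] = []  # (time, is_crossing)
    if not crossings or crossings[0] > t[0]:
        bounds.append((float(t[0]), False))
    for tc in crossings:
        bounds.append((tc, True))
    if not crossings or crossings[-1] < t[-1]:
        bounds.append((float(t[-1]), False))

    elements: list[MovementElement] = []
    for k, ((ta, a_is_x), (tb, b_is_x)) in enumerate(zip(bounds[:-1], bounds[1:])):
        if tb <= ta:
            continue
        # spans between the refined boundaries of a rest period carry only the
        # central-difference smear of the neighbouring movements, not movement
        if any(ta >= lo - 1e-12 and tb <= hi + 1e-12 for lo, hi in rest_spans):
            continue
        # half-open membership so each sample lands in exactly one segment;
        # a sample sitting exactly on a crossing is the crossing point itself
        inside = (t > ta) & (t <= tb)
        if k == 0 and not a_is_x:
            inside |= t == ta
        ts = t[inside]
        vs = v[inside]
        nonzero = vs[vs != 0.0]
        if nonzero.size == 0:
            continue  # pure rest between/around crossings
        sign = 1 if nonzero[0] > 0 else -1
        # integration support: interpolated zero endpoints at crossings
        it = ts
        iv = vs
        if a_is_x and (it.size == 0 or it[0] > ta):
            it = np.concatenate(([ta], it))
            iv = np.concatenate(([0.0], iv))
        if b_is_x and (it.size == 0 or it[-1] < tb):
            it = np.concatenate((it, [tb]))
            iv = np.concatenate((iv, [0.0]))
        D = float(np.trapezoid(iv, it))
        elements.append(
            MovementElement(
                axis=axis,
                t_start=float(ta),
                t_end=float(tb),
                D=D,
                sign=sign,
                boundary_flag=not (a_is_x and b_is_x),
                sample_times=ts,
                sample_velocities=vs,
                peak_abs_velocity=float(np.max(np.abs(vs))),
            )
        )
    return elements


def apply_filters(
    elements: Sequence[MovementElement], criteria: ElementFilterCriteria
) -> tuple[list[MovementElement], list[MovementElement]]:
    """Split elements into (kept, discarded) by the acceptance thresholds.

    Each discarded element carries the first failing criterion as its
    ``reason`` code: "boundary", "displacement", "duration" or "velocity".
    """
    kept: list[MovementElement] = []
    discarded: list[MovementElement] = []
    for el in elements:
        reason = None
        if criteria.exclude_boundary and el.boundary_flag:
            reason = "boundary"
        elif abs(el.D) < criteria.min_displacement_mm:
            reason = "displacement"
        elif el.t_f < criteria.min_duration_s:
            reason = "duration"
        elif el.peak_abs_velocity < criteria.min_velocity_mm_s:
            reason = "velocity"
        el.kept = reason is None
        el.reason = reason
        (kept if el.kept else discarded).append(el)
    return kept, discarded
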