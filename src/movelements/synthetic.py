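"""Synthetic motion-capture-like recordings built from minimum-jerk primitives.

Every generator emulates one task of an upper-limb motor battery — 1D
point-to-point sequences along a ruler (with and without targets), ellipse
drawing, pure-frequency curve tracing, and 3D scribbling — by composing
bell-shaped minimum-jerk velocity arches whose durations follow the
cost-of-time duration law t_f = (60 D)^{1/3} K^{1/6}.  Because the timing law
is built in, the mean speed of every generated element obeys the two-thirds
scaling law exactly, which makes these recordings a controlled substrate for
validating the decomposition and regression pipeline without real data.

Each generator is a pure function of its parameters and seed, and returns a
:class:`SyntheticResult` carrying the recording together with a ground-truth
element table (true per-axis t_start, t_f, D) and the full parameter set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from movelements.io import TrajectoryRecording
from movelements.minjerk import duration_from_displacement, position_profile

__all__ = [
    "ResolutionError",
    "SyntheticResult",
    "SyntheticSpec",
    "gen_element",
    "gen_sequence_1d",
    "gen_sequence_1d_no_targets",
    "gen_ellipse",
    "gen_pure_frequency",
    "gen_random_3d",
    "add_noise",
    "ruler_displacements",
    "generate",
    "SCENARIOS",
]

#: minimum samples per generated element; fewer would alias the arch and make
#: the t_f^6-sensitive K estimate meaningless
MIN_SAMPLES_PER_ELEMENT = 5

#: default rest between successive 1D elements (s); exact rest guarantees
#: clean zero crossings at element boundaries
DEFAULT_PAUSE_S = 0.3

GROUND_TRUTH_COLUMNS = ["axis", "t_start", "t_f", "D"]


class ResolutionError(ValueError):
    """An element's duration is too short for the requested sampling rate."""


@dataclass
class SyntheticResult:
    """A generated recording plus its ground truth and provenance."""

    recording: TrajectoryRecording
    ground_truth: pd.DataFrame
    spec: dict


@dataclass
class SyntheticSpec:
    """Serializable scenario description for the `simulate` command."""

    scenario: str
    params: dict = field(default_factory=dict)
    sampling_rate: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(
            scenario=d["scenario"],
            params=dict(d.get("params", {})),
            sampling_rate=float(d.get("sampling_rate", 100.0)),
            noise_sd=float(d.get("noise_sd", 0.0)),
            seed=int(d.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# element chains (1 axis)


def _element_samples(D_signed: float, K: float, rate: float) -> tuple[np.ndarray, float]:
    """Positions of one min-jerk element at local times 1/rate .. t_f.

    Returns (relative positions excluding the onset sample, true t_f).  The
    last sample lands exactly on the terminal displacement.
    """
    D = abs(D_signed)
    if D <= 0 or K <= 0:
        raise ValueError("displacement and K must be positive")
    t_f = duration_from_displacement(D, K)
    n = int(np.ceil(t_f * rate))
    if t_f * rate < MIN_SAMPLES_PER_ELEMENT:
        raise ResolutionError(
            f"element of duration {t_f:.4g} s spans only {t_f * rate:.2f} samples "
            f"at {rate} Hz (< {MIN_SAMPLES_PER_ELEMENT}); increase K, |D| or the rate"
        )
    t_local = np.minimum(np.arange(1, n + 1) / rate, t_f)
    pos = position_profile(D, t_f, t_local)
    return np.sign(D_signed) * pos, t_f


def _chain(
    displacements: Sequence[float],
    K: float,
    rate: float,
    pause_s: float,
    pad_s: float,
    axis: str,
) -> tuple[np.ndarray, list[dict]]:
    """Concatenate min-jerk elements with exact-rest pauses into one series."""
    pad_n = int(round(pad_s * rate))
    pause_n = int(round(pause_s * rate))
    pos_parts = [np.zeros(pad_n + 1)]
    truth: list[dict] = []
    current = 0.0
    n_so_far = pad_n + 1
    for i, d in enumerate(displacements):
        if d == 0:
            raise ValueError(f"displacement {i} is zero")
        rel, t_f = _element_samples(d, K, rate)
        t_start = (n_so_far - 1) / rate
        truth.append({"axis": axis, "t_start": t_start, "t_f": t_f, "D": float(d)})
        pos_parts.append(current + rel)
        current += np.sign(d) * abs(d)
        n_so_far += rel.size
        if i < len(displacements) - 1 and pause_n:
            pos_parts.append(np.full(pause_n, current))
            n_so_far += pause_n
    if pad_n:
        pos_parts.append(np.full(pad_n, current))
    return np.concatenate(pos_parts), truth


def _make_recording(
    axes: dict[str, np.ndarray], rate: float, meta: dict
) -> TrajectoryRecording:
    n = len(next(iter(axes.values())))
    return TrajectoryRecording(
        time=np.arange(n) / rate,
        axes={k: np.asarray(v, dtype=float) for k, v in axes.items()},
        sampling_rate=rate,
        metadata=meta,
    )


def gen_element(
    D_signed: float,
    K: float,
    rate: float = 100.0,
    pad_s: float = DEFAULT_PAUSE_S,
) -> SyntheticResult:
    """One min-jerk point-to-point movement on the x axis.

    The arch is framed by exact rest of ``pad_s`` seconds on both sides so
    that decomposition recovers it as a single crossing-bounded element.
    Raises :class:`ResolutionError` when the duration-law t_f spans fewer
    than 5 samples at the requested rate.
    """
    pos, truth = _chain([D_signed], K, rate, 0.0, pad_s, "x")
    spec = {"scenario": "element", "D": D_signed, "K": K, "rate": rate, "pad_s": pad_s}
    return SyntheticResult(
        recording=_make_recording({"x": pos}, rate, {"task": "movement_1d", "spec": spec}),
        ground_truth=pd.DataFrame(truth, columns=GROUND_TRUTH_COLUMNS),
        spec=spec,
    )


def ruler_displacements(
    n: int = 45, seed: int = 0, mark_spacing_mm: float = 25.0, n_marks: int = 60
) -> np.ndarray:
    """Signed displacements of a cued ruler-pointing sequence.

    Emulates pointing at ``n`` randomly cued marks on a ruler with ``n_marks``
    marks spaced ``mark_spacing_mm`` apart: each displacement is the
    difference between successive mark positions (resampled when zero).
    """
    rng = np.random.default_rng(seed)
    positions = rng.integers(0, n_marks, size=n + 1)
    for i in range(1, n + 1):
        while positions[i] == positions[i - 1]:
            positions[i] = rng.integers(0, n_marks)
    return np.diff(positions) * mark_spacing_mm


def gen_sequence_1d(
    displacements: Optional[Sequence[float]] = None,
    K: float = 1e-9,
    pause_s: float = DEFAULT_PAUSE_S,
    rate: float = 100.0,
    seed: int = 0,
    n_movements: int = 45,
) -> SyntheticResult:
    """A 1D target-directed movement sequence ("movements with targets").

    Each sub-movement is a min-jerk element whose duration follows the
    duration law with the shared cost-of-time constant ``K``; exact-rest
    pauses separate the elements.  When ``displacements`` is omitted, a
    seeded ruler-pointing sequence of ``n_movements`` cues is drawn.
    """
    if displacements is None:
        displacements = ruler_displacements(n_movements, seed)
    displacements = np.asarray(displacements, dtype=float)
    pos, truth = _chain(displacements, K, rate, pause_s, pause_s, "x")
    spec = {
        "scenario": "sequence_1d_targets",
        "displacements": [float(d) for d in displacements],
        "K": K,
        "pause_s": pause_s,
        "rate": rate,
        "seed": seed,
    }
    return SyntheticResult(
        recording=_make_recording({"x": pos}, rate, {"task": "movement_1d", "spec": spec}),
        ground_truth=pd.DataFrame(truth, columns=GROUND_TRUTH_COLUMNS),
        spec=spec,
    )


def gen_sequence_1d_no_targets(
    speed: float = 150.0,
    reversal_times: Optional[Sequence[float]] = None,
    rate: float = 100.0,
    seed: int = 0,
    n_reversals: int = 45,
    ramp_fraction: float = 0.1,
    speed_jitter: float = 0.05,
) -> SyntheticResult:
    """A 1D back-and-forth sweep at near-constant speed ("movements without
    targets").

    The hand moves at roughly constant ``speed`` and reverses direction at
    externally cued times, so each element's displacement is speed x interval
    while its mean speed stays near ``speed``: displacement and mean speed
    are decoupled by construction, the situation in which the two-thirds
    scaling law is expected to vanish.  ``speed_jitter`` is the SD of a
    seeded lognormal per-segment speed multiplier modelling natural human
    speed variability when no target constrains the movement; without it the
    tiny systematic v_bar shortfall caused by the reversal ramps would make
    mean speed a deterministic function of interval length.  Each reversal is
    smoothed with a cosine ramp lasting ``ramp_fraction`` of the shorter
    adjacent interval, which keeps the ramp-induced v_bar shortfall roughly
    the same for long and short elements (a fixed ramp duration would
    re-couple mean speed to duration).  When ``reversal_times`` is omitted,
    ``n_reversals`` intervals are drawn uniformly from [0.5, 3] s with the
    given seed.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    rng = np.random.default_rng(seed)
    if reversal_times is None:
        intervals = rng.uniform(0.5, 3.0, size=n_reversals)
        reversal_times = 0.5 + np.cumsum(intervals)
    reversal_times = np.asarray(reversal_times, dtype=float)
    if reversal_times.size < 3:
        raise ValueError("need at least 3 reversal times")
    if np.any(np.diff(reversal_times) <= 0):
        raise ValueError("reversal times must be strictly increasing")

    n_segments = reversal_times.size + 1
    magnitudes = speed * np.exp(rng.normal(0.0, speed_jitter, size=n_segments))
    signs = (-1.0) ** np.arange(n_segments)

    total = reversal_times[-1] + 0.5
    t = np.arange(int(round(total * rate)) + 1) / rate
    ends = np.concatenate((reversal_times, [t[-1]]))
    starts = np.concatenate(([t[0]], reversal_times))
    seg_lengths = ends - starts
    vel = np.full_like(t, signs[0] * magnitudes[0])
    for k, tr in enumerate(reversal_times):
        va = signs[k] * magnitudes[k]
        vb = signs[k + 1] * magnitudes[k + 1]
        ramp_s = ramp_fraction * min(seg_lengths[k], seg_lengths[k + 1])
        lo, hi = tr - ramp_s / 2.0, tr + ramp_s / 2.0
        in_ramp = (t >= lo) & (t <= hi)
        u = (t[in_ramp] - lo) / ramp_s
        vel[in_ramp] = 0.5 * (va + vb) + 0.5 * (va - vb) * np.cos(np.pi * u)
        vel[t > hi] = vb

    # renormalise each inter-crossing span so its mean |v| equals exactly the
    # drawn segment speed: the cosine ramps otherwise shave a duration-
    # dependent fraction off v_bar, deterministically re-coupling mean speed
    # to displacement
    dt = 1.0 / rate
    sign_change = np.flatnonzero(np.diff(np.sign(vel)) != 0) + 1
    cross_t = t[sign_change - 1] + dt * vel[sign_change - 1] / (
        vel[sign_change - 1] - vel[sign_change]
    )
    span_edges_t = np.concatenate(([t[0]], cross_t, [t[-1]]))
    span_edges_i = np.concatenate(([0], sign_change, [t.size]))
    for k, (i0, i1) in enumerate(zip(span_edges_i[:-1], span_edges_i[1:])):
        if k >= n_segments or i1 - i0 < 2:
            continue
        ta, tb = span_edges_t[k], span_edges_t[k + 1]
        seg_t = np.concatenate(([ta], t[i0:i1], [tb]))
        seg_v = np.concatenate(([0.0], vel[i0:i1], [0.0]))
        area = np.trapezoid(np.abs(seg_v), seg_t)
        if area > 0 and tb > ta:
            vel[i0:i1] *= magnitudes[k] * (tb - ta) / area
    pos = np.concatenate(([0.0], cumulative_trapezoid(vel, t)))

    bounds = np.concatenate(([t[0]], reversal_times, [t[-1]]))
    truth = [
        {
            "axis": "x",
            "t_start": float(a),
            "t_f": float(b - a),
            "D": float(signs[k] * magnitudes[k] * (b - a)),
        }
        for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]
    spec = {
        "scenario": "sequence_1d_no_targets",
        "speed": speed,
        "reversal_times": [float(x) for x in reversal_times],
        "rate": rate,
        "seed": seed,
        "ramp_fraction": ramp_fraction,
        "speed_jitter": speed_jitter,
    }
    return SyntheticResult(
        recording=_make_recording({"x": pos}, rate, {"task": "movement_1d", "spec": spec}),
        ground_truth=pd.DataFrame(truth, columns=GROUND_TRUTH_COLUMNS),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# 2D drawing tasks


def _pad_hold(axes: dict[str, np.ndarray], pad_n: int) -> dict[str, np.ndarray]:
    if pad_n <= 0:
        return axes
    return {
        k: np.concatenate((np.full(pad_n, v[0]), v, np.full(pad_n, v[-1])))
        for k, v in axes.items()
    }


def gen_ellipse(
    a: float,
    b: float,
    n_reps: int = 1,
    K: float = 1e-9,
    rate: float = 100.0,
    mode: str = "harmonic",
    pad_s: float = 0.0,
) -> SyntheticResult:
    """Repeated ellipse drawing with semi-axes ``a`` > ``b`` (mm).

    ``harmonic`` mode traces x = a cos(wt), y = b sin(wt), starting at an
    x-velocity zero, with the half period set by the duration law for a
    displacement of 2a — so each repetition contributes two x-axis movement
    elements of displacement 2a whose timing follows the cost-of-time model,
    and the trace satisfies the one-third speed-curvature law exactly.
    ``minjerk_composition`` mode instead chains alternating min-jerk elements
    on each axis with a quarter-cycle offset, exercising the element-fit
    pathway with profile-exact arches.
    """
    if not (a > b > 0):
        raise ValueError(f"need a > b > 0, got a={a}, b={b}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    T_half = duration_from_displacement(2.0 * a, K)
    if T_half * rate < 2 * MIN_SAMPLES_PER_ELEMENT:
        raise ResolutionError(
            f"half period {T_half:.4g} s too short at {rate} Hz"
        )
    pad_n = int(round(pad_s * rate))
    spec = {
        "scenario": "ellipse",
        "a": a,
        "b": b,
        "n_reps": n_reps,
        "K": K,
        "rate": rate,
        "mode": mode,
        "pad_s": pad_s,
    }

    if mode == "harmonic":
        omega = np.pi / T_half
        total = 2.0 * T_half * n_reps
        t = np.arange(int(round(total * rate)) + 1) / rate
        axes = {"x": a * np.cos(omega * t), "y": b * np.sin(omega * t)}
        truth = []
        for rep in range(n_reps):
            for half in range(2):
                t0 = (2 * rep + half) * T_half + pad_s
                sgn = -1.0 if half == 0 else 1.0
                truth.append(
                    {"axis": "x", "t_start": t0, "t_f": T_half, "D": sgn * 2.0 * a}
                )
        # interior y arches (the first and last quarter-cycles are halves)
        for k in range(2 * n_reps - 1):
            t0 = (k + 0.5) * T_half + pad_s
            sgn = -1.0 if k % 2 == 0 else 1.0
            truth.append({"axis": "y", "t_start": t0, "t_f": T_half, "D": sgn * 2.0 * b})
    elif mode == "minjerk_composition":
        x_disp = [-2.0 * a if k % 2 == 0 else 2.0 * a for k in range(2 * n_reps)]
        y_disp = [2.0 * b if k % 2 == 0 else -2.0 * b for k in range(2 * n_reps - 1)]
        # x spans the full trace; y is offset by a quarter cycle (half element)
        x_pos, x_truth = _chain(x_disp, K, rate, 0.0, 0.0, "x")
        n_half = int(round(T_half * rate / 2.0))
        y_core = []
        current = -b
        for d in y_disp:
            # y elements stretched to the shared half period T_half
            t_loc = np.minimum(np.arange(1, int(round(T_half * rate)) + 1) / rate, T_half)
            y_core.append(current + np.sign(d) * position_profile(abs(d), T_half, t_loc))
            current += d
        y_pos = np.concatenate([np.full(n_half + 1, -b)] + y_core + [np.full(n_half, current)])
        n = min(x_pos.size, y_pos.size)
        x_pos, y_pos = x_pos[:n] + 0.0, y_pos[:n]
        x_pos += a - x_pos[0]
        truth = [dict(r, t_start=r["t_start"] + pad_s) for r in x_truth]
        for k, d in enumerate(y_disp):
            truth.append(
                {
                    "axis": "y",
                    "t_start": (n_half / rate) + k * T_half + pad_s,
                    "t_f": T_half,
                    "D": float(d),
                }
            )
        axes = {"x": x_pos, "y": y_pos}
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'harmonic' or 'minjerk_composition'")

    axes = _pad_hold(axes, pad_n)
    return SyntheticResult(
        recording=_make_recording(axes, rate, {"task": "drawing", "spec": spec}),
        ground_truth=pd.DataFrame(truth, columns=GROUND_TRUTH_COLUMNS),
        spec=spec,
    )


def gen_pure_frequency(
    epsilon: float,
    nu: float,
    size: float = 120.0,
    K: float = 1e-9,
    rate: float = 100.0,
    theta_points: int = 20000,
) -> SyntheticResult:
    """Trace a pure-frequency curve at constant affine velocity.

    The shape is defined by a sinusoidal log radius-of-curvature profile
    log r(theta) = epsilon * sin(nu * theta) along the tangent angle theta
    (nu = 0 gives a circle), scaled so the horizontal width equals ``size``
    mm.  The trace is timed with v = k * r^{1/3} (constant affine velocity,
    hence the one-third law holds by construction), with the gain k set so
    that the largest x-axis excursion obeys the duration law with the given
    ``K``.
    """
    if epsilon < 0 or nu < 0 or size <= 0:
        raise ValueError("epsilon, nu must be >= 0 and size > 0")
    frac = Fraction(nu).limit_denominator(64) if nu > 0 else Fraction(0)
    n_turns = frac.denominator if nu > 0 else 1
    theta = np.linspace(0.0, 2.0 * np.pi * n_turns, theta_points)
    r = np.exp(epsilon * np.sin(nu * theta))
    # ds = r dtheta; integrate the unit tangent to get the shape
    x = np.concatenate(([0.0], cumulative_trapezoid(r * np.cos(theta), theta)))
    y = np.concatenate(([0.0], cumulative_trapezoid(r * np.sin(theta), theta)))
    width = float(np.ptp(x))
    if width <= 0:
        raise ValueError("degenerate (zero-width) curve")
    scale = size / width
    x, y, r = x * scale, y * scale, r * scale

    # constant affine velocity: v = r^{1/3}  =>  dt = r^{2/3} dtheta (gain 1)
    tau = np.concatenate(([0.0], cumulative_trapezoid(r ** (2.0 / 3.0), theta)))
    # x extrema sit where cos(theta) = 0; find the largest monotonic excursion
    dx_sign = np.sign(np.cos(theta))
    turn_idx = np.flatnonzero(np.diff(dx_sign) != 0) + 1
    seg_bounds = np.unique(np.concatenate(([0], turn_idx, [theta.size - 1])))
    best_D, best_dt = 0.0, 1.0
    for i0, i1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        D_seg = abs(x[i1] - x[i0])
        if D_seg > best_D:
            best_D, best_dt = D_seg, tau[i1] - tau[i0]
    t_f_target = duration_from_displacement(best_D, K)
    time = tau * (t_f_target / best_dt)

    n = int(np.floor(time[-1] * rate)) + 1
    t_grid = np.arange(n) / rate
    axes = {"x": np.interp(t_grid, time, x), "y": np.interp(t_grid, time, y)}
    truth = []
    for i0, i1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        truth.append(
            {
                "axis": "x",
                "t_start": float(time[i0]),
                "t_f": float(time[i1] - time[i0]),
                "D": float(x[i1] - x[i0]),
            }
        )
    spec = {
        "scenario": "pure_frequency",
        "epsilon": epsilon,
        "nu": nu,
        "size": size,
        "K": K,
        "rate": rate,
    }
    return SyntheticResult(
        recording=_make_recording(axes, rate, {"task": "drawing", "spec": spec}),
        ground_truth=pd.DataFrame(truth, columns=GROUND_TRUTH_COLUMNS),
        spec=spec,
    )


def gen_random_3d(
    n_elements: int = 20,
    D_range: tuple[float, float] = (10.0, 200.0),
    K: float = 1e-9,
    rate: float = 100.0,
    seed: int = 0,
    pause_range_s: tuple[float, float] = (0.2, 0.5),
) -> SyntheticResult:
    """Random 3D scribbling: independent min-jerk chains on x, y and z.

    Each axis receives ``n_elements`` alternating-sign elements with seeded
    magnitudes drawn log-uniformly from ``D_range`` and seeded inter-element
    pauses, plus a random initial delay so the axes are desynchronized.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = D_range
    axes: dict[str, np.ndarray] = {}
    truth: list[dict] = []
    for axis in ("x", "y", "z"):
        mags = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_elements))
        start_sign = rng.choice([-1.0, 1.0])
        disp = mags * start_sign * (-1.0) ** np.arange(n_elements)
        delay_s = float(rng.uniform(0.0, 0.5))
        pad_n = int(round(delay_s * rate))
        parts = [np.zeros(pad_n + 1)]
        current, n_so_far = 0.0, pad_n + 1
        for i, d in enumerate(disp):
            rel, t_f = _element_samples(d, K, rate)
            truth.append(
                {"axis": axis, "t_start": (n_so_far - 1) / rate, "t_f": t_f, "D": float(d)}
            )
            parts.append(current + rel)
            current += d
            n_so_far += rel.size
            if i < n_elements - 1:
                pause_n = int(round(rng.uniform(*pause_range_s) * rate))
                parts.append(np.full(pause_n, current))
                n_so_far += pause_n
        axes[axis] = np.concatenate(parts)
    n_max = max(v.size for v in axes.values())
    axes = {
        k: np.concatenate((v, np.full(n_max - v.size, v[-1]))) for k, v in axes.items()
    }
    spec = {
        "scenario": "random_3d",
        "n_elements": n_elements,
        "D_range": list(D_range),
        "K": K,
        "rate": rate,
        "seed": seed,
    }
    return SyntheticResult(
        recording=_make_recording(axes, rate, {"task": "movement_3d", "spec": spec}),
        ground_truth=pd.DataFrame(truth, columns=GROUND_TRUTH_COLUMNS),
        spec=spec,
    )


def add_noise(
    recording: TrajectoryRecording, sd_mm: float, seed: int = 0
) -> TrajectoryRecording:
    """Add independent Gaussian position noise (mm) per sample and axis."""
    if sd_mm < 0:
        raise ValueError("noise sd must be >= 0")
    if sd_mm == 0:
        return TrajectoryRecording(
            time=recording.time.copy(),
            axes={k: v.copy() for k, v in recording.axes.items()},
            sampling_rate=recording.sampling_rate,
            metadata=dict(recording.metadata),
        )
    rng = np.random.default_rng(seed)
    axes = {k: v + rng.normal(0.0, sd_mm, size=v.shape) for k, v in recording.axes.items()}
    meta = dict(recording.metadata)
    meta["noise"] = {"sd_mm": sd_mm, "seed": seed}
    return TrajectoryRecording(
        time=recording.time.copy(),
        axes=axes,
        sampling_rate=recording.sampling_rate,
        metadata=meta,
    )


SCENARIOS = {
    "element": gen_element,
    "sequence_1d_targets": gen_sequence_1d,
    "sequence_1d_no_targets": gen_sequence_1d_no_targets,
    "ellipse": gen_ellipse,
    "pure_frequency": gen_pure_frequency,
    "random_3d": gen_random_3d,
}


def generate(spec: SyntheticSpec) -> SyntheticResult:
    """Dispatch a :class:`SyntheticSpec` to its generator, then add noise."""
    try:
        fn = SCENARIOS[spec.scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {spec.scenario!r}; valid: {sorted(SCENARIOS)}"
        ) from None
    params = dict(spec.params)
    params.setdefault("rate", spec.sampling_rate)
    if "seed" in fn.__code__.co_varnames[: fn.__code__.co_argcount]:
        params.setdefault("seed", spec.seed)
    result = fn(**params)
    if spec.noise_sd > 0:
        result = SyntheticResult(
            recording=add_noise(result.recording, spec.noise_sd, spec.seed + 1),
            ground_truth=result.ground_truth,
            spec=dict(result.spec, noise_sd=spec.noise_sd, noise_seed=spec.seed + 1),
        )
    return result
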