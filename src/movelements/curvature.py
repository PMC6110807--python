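"""Plane-curve kinematics: curvature series and the classical power laws.

For a 2D trajectory (x(t), y(t)) the instantaneous speed is v = sqrt(x'^2 +
y'^2), the curvature C = |x'y'' - y'x''| / v^3, the radius of curvature
r = 1/C, and the tangent angle theta = atan2(y', x') (unwrapped).  The
identity |dtheta/dt| = v * C holds at every regular point.

Two empirical regularities of curvilinear hand movement are fitted on log-log
axes:

* the one-third law, v ~ k_v * r^{1/3} (speed vs. radius of curvature), and
* the equivalent two-thirds angular form, |dtheta/dt| ~ k_theta * C^{2/3}.

A harmonic ellipse (x = a cos wt, y = b sin wt) satisfies both exactly, which
makes it the canonical validation input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from movelements.io import TrajectoryRecording

__all__ = [
    "CurvatureSeries",
    "PowerLawFit",
    "DegenerateRegressionError",
    "compute_curvature",
    "fit_speed_curvature_law",
    "fit_angular_curvature_law",
]

#: samples slower than this (mm/s) are masked out of log-domain fits; matches
#: the global minimum-velocity element threshold
SPEED_FLOOR_MM_S = 10.0
#: curvature floor (1/mm) below which a sample is treated as straight-line
CURVATURE_FLOOR_PER_MM = 1e-6


class DegenerateRegressionError(ValueError):
    """Raised when a power-law fit has no variance in its regressor."""


@dataclass
class CurvatureSeries:
    """Per-sample differential geometry of a planar trajectory.

    All arrays share one time base.  ``valid_mask`` flags samples usable in
    log-domain fits (speed above the validity floor, curvature above the
    straight-line floor); r and C are NaN where invalid.
    """

    time: np.ndarray
    speed: np.ndarray
    curvature: np.ndarray
    radius: np.ndarray
    tangent_angle: np.ndarray
    angular_speed: np.ndarray
    valid_mask: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid_mask))


@dataclass
class PowerLawFit:
    """OLS power-law fit on log10 axes; ``log_gain`` is the intercept
    (log10 of the gain constant k_v or k_theta)."""

    exponent: float
    log_gain: float
    pearson_r: float
    n_valid: int

    def to_row(self) -> dict:
        return {
            "exponent": self.exponent,
            "log_gain": self.log_gain,
            "pearson_r": self.pearson_r,
            "n_valid": self.n_valid,
        }


def compute_curvature(
    trajectory: TrajectoryRecording,
    axes: tuple[str, str] = ("x", "y"),
    speed_floor: float = SPEED_FLOOR_MM_S,
    curvature_floor: float = CURVATURE_FLOOR_PER_MM,
) -> CurvatureSeries:
    """Compute speed, curvature, radius and tangent-angle series.

    Derivatives use the same central-difference operator as velocity
    computation, for consistency across the pipeline.  Requires two position
    axes and at least 5 samples.
    """
    missing = [a for a in axes if a not in trajectory.axes]
    if missing:
        raise KeyError(f"axes {missing} not present in recording")
    if trajectory.n_samples < 5:
        raise ValueError(f"need at least 5 samples, got {trajectory.n_samples}")
    t = trajectory.time
    dt = 1.0 / trajectory.sampling_rate
    x = trajectory.axes[axes[0]]
    y = trajectory.axes[axes[1]]
    xd = np.gradient(x, dt, edge_order=1)
    yd = np.gradient(y, dt, edge_order=1)
    xdd = np.gradient(xd, dt, edge_order=1)
    ydd = np.gradient(yd, dt, edge_order=1)
    speed = np.hypot(xd, yd)
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = np.abs(xd * ydd - yd * xdd) / speed**3
    theta = np.unwrap(np.arctan2(yd, xd))
    angular_speed = np.gradient(theta, dt, edge_order=1)
    valid = (speed >= speed_floor) & np.isfinite(curvature) & (curvature >= curvature_floor)
    # first/last samples rest on one-sided derivative stencils whose curvature
    # is unreliable; a zero-phase low-pass (recorded in the metadata) further
    # smears ~2.5 settling lengths of transient into each end of the trace
    guard = 2
    filt = trajectory.metadata.get("filter")
    if isinstance(filt, dict) and filt.get("cutoff_hz"):
        guard = max(guard, int(np.ceil(2.5 * trajectory.sampling_rate / filt["cutoff_hz"])))
    guard = min(guard, max(1, t.size // 4))
    valid[:guard] = False
    valid[-guard:] = False
    curvature = np.where(valid, curvature, np.nan)
    with np.errstate(divide="ignore"):
        radius = 1.0 / curvature
    return CurvatureSeries(
        time=t.copy(),
        speed=speed,
        curvature=curvature,
        radius=radius,
        tangent_angle=theta,
        angular_speed=angular_speed,
        valid_mask=valid,
    )


def _ols_loglog(xs: np.ndarray, ys: np.ndarray, n_min: int, what: str) -> PowerLawFit:
    ok = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[ok], ys[ok]
    if xs.size < n_min:
        raise ValueError(f"{what}: need at least {n_min} valid samples, got {xs.size}")
    # a numerically traced circle leaves ~0.1-1% spread in r; anything under
    # a few percent of a decade cannot support a power-law slope estimate
    if np.ptp(xs) < 0.02:
        raise DegenerateRegressionError(
            f"{what}: regressor spans only {np.ptp(xs):.2g} decades"
        )
    res = stats.linregress(xs, ys)
    return PowerLawFit(
        exponent=float(res.slope),
        log_gain=float(res.intercept),
        pearson_r=float(res.rvalue),
        n_valid=int(xs.size),
    )


def fit_speed_curvature_law(curv: CurvatureSeries, n_min: int = 10) -> PowerLawFit:
    """OLS slope of log10 v on log10 r — the one-third-law exponent.

    Raises :class:`DegenerateRegressionError` when the radius has no variance
    (e.g. a perfect circle).
    """
    m = curv.valid_mask & (curv.speed > 0)
    return _ols_loglog(
        np.log10(curv.radius[m]), np.log10(curv.speed[m]), n_min, "speed-curvature law"
    )


def fit_angular_curvature_law(curv: CurvatureSeries, n_min: int = 10) -> PowerLawFit:
    """OLS slope of log10 |dtheta/dt| on log10 C — the two-thirds angular
    exponent.  Equals 1 + (speed-law exponent after the r -> C change of
    variable), since |dtheta/dt| = v * C."""
    m = curv.valid_mask & (np.abs(curv.angular_speed) > 0)
    return _ols_loglog(
        np.log10(curv.curvature[m]),
        np.log10(np.abs(curv.angular_speed[m])),
        n_min,
        "angular-curvature law",
    )
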