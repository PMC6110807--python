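"""Closed-form minimum-jerk theory for point-to-point movements.

A point-to-point movement of displacement ``D`` that minimises integrated
squared jerk under a cost-of-time trade-off (duration penalised linearly with
weight ``1/K`` relative to smoothness) has

* duration  ``t_f = (60 D)^{1/3} K^{1/6}``  (the duration law),
* a bell-shaped velocity profile
  ``v(t) = D (30 s^4 - 60 s^3 + 30 s^2) / t_f`` with ``s = t / t_f``,
* mean speed  ``v_bar = D^{2/3} / (60^{1/3} K^{1/6})``  — the two-thirds
  scaling law, since ``v_bar = D / t_f``.

``K`` is the cost-of-time constant; under the package's internal units
(millimetres, seconds) it carries units mm^-2 s^6.  All functions are
vectorised over their time argument where applicable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "velocity_profile",
    "position_profile",
    "duration_from_displacement",
    "estimate_K",
    "mean_velocity_law",
    "fit_element",
    "pearson_r",
    "convert_K",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be positive, got {value!r}")


def velocity_profile(D: float, t_f: float, t):
    """Bell-shaped minimum-jerk velocity at time ``t`` in [0, t_f].

    Parameters
    ----------
    D : float
        Displacement magnitude, mm.
    t_f : float
        Movement duration, s.
    t : float or array_like
        Time(s) since movement onset, s.

    Returns
    -------
    float or ndarray
        Velocity in mm/s; zero at both endpoints, peak ``1.875 D / t_f``
        at ``t = t_f / 2``, symmetric about the midpoint.
    """
    _check_positive(t_f=t_f)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > t_f):
        raise ValueError(f"t must lie in [0, {t_f}]")
    s = t / t_f
    out = D * (30.0 * s**4 - 60.0 * s**3 + 30.0 * s**2) / t_f
    return out if out.ndim else float(out)


def position_profile(D: float, t_f: float, t):
    """Minimum-jerk position (antiderivative of :func:`velocity_profile`).

    ``x(t) = D (6 s^5 - 15 s^4 + 10 s^3)`` with ``s = t/t_f``; runs from 0
    at onset to ``D`` at ``t_f``.
    """
    _check_positive(t_f=t_f)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > t_f):
        raise ValueError(f"t must lie in [0, {t_f}]")
    s = t / t_f
    out = D * (6.0 * s**5 - 15.0 * s**4 + 10.0 * s**3)
    return out if out.ndim else float(out)


def duration_from_displacement(D: float, K: float) -> float:
    """Duration law: ``t_f = (60 D)^{1/3} K^{1/6}``."""
    _check_positive(D=D, K=K)
    return float((60.0 * D) ** (1.0 / 3.0) * K ** (1.0 / 6.0))


def estimate_K(D: float, t_f: float) -> float:
    """Invert the duration law: ``K = t_f^6 / (60 D)^2``.

    Note the sixth-power dependence on ``t_f``: small timing errors in the
    segmentation are amplified strongly, which motivates sub-sample
    (interpolated) zero-crossing times upstream.
    """
    _check_positive(D=D, t_f=t_f)
    return float(t_f**6 / (60.0 * D) ** 2)


def mean_velocity_law(D: float, K: float) -> float:
    """Two-thirds scaling law: ``v_bar = D^{2/3} / (60^{1/3} K^{1/6})``.

    Algebraically identical to ``D / duration_from_displacement(D, K)``.
    """
    _check_positive(D=D, K=K)
    return float(D ** (2.0 / 3.0) / (60.0 ** (1.0 / 3.0) * K ** (1.0 / 6.0)))


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(np.sum(da * da))
    nb = np.sqrt(np.sum(db * db))
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero variance in one of the series")
    return float(np.dot(da, db) / (na * nb))


def fit_element(element) -> float:
    """Correlate an element's speed samples with its theoretical profile.

    The theoretical profile is fully determined by the element's own
    displacement magnitude ``|D|`` and duration ``t_f`` — no free parameter is
    fitted.  The Pearson correlation is computed sample-wise between
    ``|observed velocity|`` at the element's recorded sample times and
    ``velocity_profile(|D|, t_f, t - t_start)`` at those same times.

    Parameters
    ----------
    element : MovementElement
        Must expose ``sample_times``, ``sample_velocities``, ``t_start``,
        ``t_end``, ``D`` and ``t_f`` with at least 4 samples.

    Returns
    -------
    float
        Pearson correlation in [-1, 1].
    """
    t = np.asarray(element.sample_times, dtype=float)
    v = np.abs(np.asarray(element.sample_velocities, dtype=float))
    if t.size < 4:
        raise ValueError(f"element has {t.size} samples; need at least 4")
    tau = np.clip(t - element.t_start, 0.0, element.t_f)
    theory = velocity_profile(abs(element.D), element.t_f, tau)
    return pearson_r(v, theory)


_LENGTH_FACTORS_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def convert_K(K: float, from_unit: str = "mm", to_unit: str = "m") -> float:
    """Re-express the cost-of-time constant in another length unit.

    K carries units length^-2 s^6, so changing the length unit by a factor f
    multiplies K by f^2 (e.g. mm -> m multiplies by 1e6).  Useful when
    comparing K values across reports that use different conventions.
    """
    try:
        f_from = _LENGTH_FACTORS_MM[from_unit]
        f_to = _LENGTH_FACTORS_MM[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown length unit {exc}") from None
    return float(K * (f_to / f_from) ** 2)
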