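"""Two-thirds power-law fitting across movement elements.

The duration law t_f = (60 D)^{1/3} K^{1/6} implies that the mean speed of a
movement element scales with its displacement as v_bar = D^{2/3} /
(60^{1/3} K^{1/6}).  On a log-log plot of v_bar against |D| this is a straight
line of slope 2/3; the fitted slope is the scaling exponent alpha.  Fits pool
elements across axes and repetitions by default, mirroring how per-task
regressions are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from movelements.decompose import MovementElement

__all__ = ["ScalingFit", "TaskSummary", "fit_scaling", "summarize_task"]


@dataclass
class ScalingFit:
    """Log-log regression of mean element speed on element displacement.

    alpha is the slope (the scaling exponent); intercept is log10 of the
    speed (mm/s) at |D| = 1 mm; pearson_r is the correlation of the point
    cloud (log10 |D|, log10 v_bar).
    """

    alpha: float
    intercept: float
    pearson_r: float
    n_elements: int
    axes_used: tuple[str, ...]

    def to_row(self) -> dict:
        return {
            "alpha": self.alpha,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "n_elements": self.n_elements,
            "axes_used": "+".join(self.axes_used),
        }


@dataclass
class TaskSummary:
    """Per-task descriptive summary mirroring the per-task result reporting.

    fit_r is the per-element Pearson correlation against the theoretical
    minimum-jerk profile; K the per-element cost-of-time constant.  Standard
    deviations are sample (n-1) SDs, NaN when fewer than two values exist.
    """

    task: str
    fit_r_mean: float
    fit_r_sd: float
    alpha: float
    regression_r: float
    K_mean: float
    K_sd: float
    n_kept: int
    n_discarded: int

    def to_row(self) -> dict:
        return {
            "task": self.task,
            "fit_r_mean": self.fit_r_mean,
            "fit_r_sd": self.fit_r_sd,
            "alpha": self.alpha,
            "regression_r": self.regression_r,
            "K_mean": self.K_mean,
            "K_sd": self.K_sd,
            "n_kept": self.n_kept,
            "n_discarded": self.n_discarded,
        }


def fit_scaling(elements: Sequence[MovementElement]) -> ScalingFit:
    """Ordinary least-squares line through (log10 |D|, log10 v_bar).

    Requires at least 3 elements with positive |D| and v_bar and nonzero
    variance in log10 |D|.  The result is invariant to element ordering and
    axis relabeling; rescaling every D by a constant c shifts the intercept
    by alpha*log10(c) and leaves alpha unchanged.
    """
    els = [e for e in elements if abs(e.D) > 0 and e.t_f > 0]
    if len(els) < 3:
        raise ValueError(f"need at least 3 elements with |D| > 0, got {len(els)}")
    log_d = np.log10([abs(e.D) for e in els])
    log_v = np.log10([e.mean_abs_velocity for e in els])
    if np.ptp(log_d) == 0.0:
        raise ValueError("zero variance in log10 |D|; regression is degenerate")
    res = stats.linregress(log_d, log_v)
    axes_used = tuple(sorted({e.axis for e in els}))
    return ScalingFit(
        alpha=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n_elements=len(els),
        axes_used=axes_used,
    )


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return float(arr.mean()), sd


def summarize_task(
    elements: Sequence[MovementElement],
    scaling_fit: Optional[ScalingFit],
    task: str,
    n_discarded: int = 0,
) -> TaskSummary:
    """Descriptive mean +/- SD of fit_r and K over kept elements, plus the
    task's scaling fit, in one record."""
    if not elements:
        raise ValueError("empty element list")
    fit_r_mean, fit_r_sd = _mean_sd([e.fit_r for e in elements if e.fit_r is not None])
    k_mean, k_sd = _mean_sd([e.K for e in elements if e.K is not None])
    return TaskSummary(
        task=task,
        fit_r_mean=fit_r_mean,
        fit_r_sd=fit_r_sd,
        alpha=scaling_fit.alpha if scaling_fit else math.nan,
        regression_r=scaling_fit.pearson_r if scaling_fit else math.nan,
        K_mean=k_mean,
        K_sd=k_sd,
        n_kept=len(elements),
        n_discarded=n_discarded,
    )
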