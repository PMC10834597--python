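"""Survival curves as right-continuous step functions, and curve summaries.

The step convention: a curve is 1 before its first time point; ``surv[i]``
applies on ``[times[i], times[i+1])``. Time-at-risk (TaR) is the first time
the curve reaches 90% mortality (survival <= 0.1 by default); restricted mean
survival time (RMST) is the area under the step curve up to a horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurvivalCurve", "time_at_risk", "rmst", "drmst", "risk_difference"]


@dataclass
class SurvivalCurve:
    """Right-continuous survival step function."""

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.surv = np.asarray(self.surv, dtype=float).ravel()
        if self.times.size != self.surv.size:
            raise ValueError("times and surv must have equal length")
        if self.times.size == 0:
            raise ValueError("empty survival curve")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sorted ascending")
        if np.any(self.surv < -1e-12) or np.any(self.surv > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.surv) > 1e-9):
            raise ValueError("survival curve must be nonincreasing")
        self.surv = np.clip(self.surv, 0.0, 1.0)

    def evaluate(self, t):
        """S(t) under the right-continuous convention (1 before first time)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.surv[np.maximum(idx, 0)], 1.0)
        return out if out.ndim else float(out)

    def __call__(self, t):
        return self.evaluate(t)


def time_at_risk(curve: SurvivalCurve, mortality_threshold: float = 0.90):
    """First time predicted survival falls to ``1 - mortality_threshold``.

    Returns ``(months, capped)``. If the curve never reaches the threshold
    the last time point is returned with ``capped=True`` — the curve's
    support is not extrapolated.
    """
    if not 0.0 < mortality_threshold < 1.0:
        raise ValueError("mortality_threshold must be in (0, 1)")
    target = 1.0 - mortality_threshold
    below = curve.surv <= target + 1e-12
    if below.any():
        return float(curve.times[int(np.argmax(below))]), False
    return float(curve.times[-1]), True


def rmst(curve: SurvivalCurve, tau: float) -> float:
    """Restricted mean survival time: area under the step curve on [0, tau]."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    knots = np.concatenate(([0.0], curve.times[curve.times < tau], [tau]))
    knots = np.unique(knots)
    heights = curve.evaluate(knots[:-1])
    return float(np.sum(np.atleast_1d(heights) * np.diff(knots)))


def drmst(curve_a: SurvivalCurve, curve_b: SurvivalCurve, tau: float) -> float:
    """RMST difference A - B (months gained by group A by time tau)."""
    return rmst(curve_a, tau) - rmst(curve_b, tau)


def risk_difference(curve_a: SurvivalCurve, curve_b: SurvivalCurve,
                    horizon: float) -> float:
    """Mortality risk difference at the horizon, in percentage points.

    ``100 * [(1 - S_B(h)) - (1 - S_A(h))]``; positive favors group A. Curves
    ending before the horizon carry their last value forward.
    """
    sa = float(np.asarray(curve_a.evaluate(horizon)))
    sb = float(np.asarray(curve_b.evaluate(horizon)))
    return 100.0 * (sa - sb)
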