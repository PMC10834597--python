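"""Counterfactual inference: survival curves, time-at-risk, ITE, recommendations.

A fitted model predicts a log hazard ratio ``s`` for a subject under either
counterfactual arm; combined with the arm's Breslow baseline cumulative
hazard this gives the individual survival distribution
``S(t) = exp(-H0_arm(t) * exp(s))``. The time-at-risk (TaR) is the first
time this curve reaches 90% mortality; the individual treatment effect is

    ITE = TaR(arm 1) - TaR(arm 0),

and a subject is recommended for treatment exactly when ITE > 0. Curves that
never reach the mortality threshold within the baseline's support are capped
at the last observed baseline time and flagged rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import SurvivalCurve
from .data import SurvivalDataset

__all__ = [
    "ITEResult",
    "predict_survival",
    "individual_treatment_effect",
    "recommend_batch",
]


@dataclass
class ITEResult:
    """Per-patient counterfactual summary.

    ``ite == tar1 - tar0`` exactly; ``recommendation`` is 1 (treat) iff
    ``ite > 0``, else 0 — a zero effect defaults to control.
    """

    tar0: float
    tar1: float
    ite: float
    tar0_capped: bool
    tar1_capped: bool
    recommendation: int


def _scores_and_curves(results, X, arm):
    times, cumhaz = results.baselines[arm]
    scores = results.predict_score(X, arm)
    curves = [SurvivalCurve(times, np.exp(-cumhaz * np.exp(s))) for s in scores]
    return scores, curves


def predict_survival(results, x, arm: int):
    """Counterfactual survival curve(s) under treatment ``arm``.

    A single covariate vector yields one :class:`SurvivalCurve`; a matrix
    yields a list of curves.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    _, curves = _scores_and_curves(results, np.atleast_2d(x), arm)
    return curves[0] if single else curves


def _tar_table(results, X, mortality_threshold):
    """Vectorized TaR under both arms; returns dict of arrays."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = {}
    target = 1.0 - mortality_threshold
    for arm in (0, 1):
        times, cumhaz = results.baselines[arm]
        scores = results.predict_score(X, arm)
        # S(t) <= target  <=>  H0(t) >= -ln(target) * exp(-s)
        need = -np.log(target) * np.exp(-scores)
        idx = np.searchsorted(cumhaz, need - 1e-12, side="left")
        capped = idx >= cumhaz.size
        tar = np.where(capped, times[-1], times[np.minimum(idx, cumhaz.size - 1)])
        out[f"tar{arm}"] = tar
        out[f"capped{arm}"] = capped
    out["ite"] = out["tar1"] - out["tar0"]
    out["recommendation"] = (out["ite"] > 0).astype(int)
    return out


def individual_treatment_effect(results, x,
                                mortality_threshold: float = 0.90) -> ITEResult:
    """Counterfactual TaR under both arms, their difference, and the
    resulting recommendation for a single subject."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single covariate vector; use "
                         "recommend_batch for matrices")
    t = _tar_table(results, x[None, :], mortality_threshold)
    return ITEResult(
        tar0=float(t["tar0"][0]), tar1=float(t["tar1"][0]),
        ite=float(t["ite"][0]),
        tar0_capped=bool(t["capped0"][0]), tar1_capped=bool(t["capped1"][0]),
        recommendation=int(t["recommendation"][0]),
    )


def recommend_batch(results, data, mortality_threshold: float = 0.90) -> pd.DataFrame:
    """Per-subject TaR/ITE table with treatment recommendations.

    ``data`` may be a :class:`SurvivalDataset` or a covariate matrix.
    Deterministic in evaluation mode: identical rows get identical rows out.
    """
    if isinstance(data, SurvivalDataset):
        X, ids = data.X, data.ids
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        ids = np.arange(X.shape[0])
    if X.shape[0] == 0:
        return pd.DataFrame(columns=["id", "tar0", "tar1", "ite",
                                     "capped0", "capped1", "recommendation"])
    t = _tar_table(results, X, mortality_threshold)
    return pd.DataFrame({
        "id": ids,
        "tar0": t["tar0"], "tar1": t["tar1"], "ite": t["ite"],
        "capped0": t["capped0"], "capped1": t["capped1"],
        "recommendation": t["recommendation"],
    })
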