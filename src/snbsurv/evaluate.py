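"""Recommendation-effect evaluation.

Subjects are split into the *consistent* group (actual treatment matched the
model's recommendation) and the *inconsistent* group, and the survival
advantage of consistency is quantified by: a multivariate Cox hazard ratio
(HR), the mortality risk difference at a horizon (RD, percentage points),
the difference in restricted mean survival time (dRMST, months), and a
weighted log-rank test — each unadjusted and after inverse probability of
treatment weighting (IPTW) to debias the contrast. Model calibration is
measured by arm-wise IPCW integrated Brier scores (IBS). The default horizon
is 120 months (10 years).

Standard model fits are delegated: the propensity model to scikit-learn
logistic regression and the (weighted, robust) Cox fit to lifelines; the
weighted product-limit estimator, weighted log-rank statistic and IPCW Brier
integration are implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, linalg
from sklearn.linear_model import LogisticRegression

from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cox import breslow_baseline
from .curves import SurvivalCurve, drmst, risk_difference, rmst
from .data import SurvivalDataset
from .inference import recommend_batch

logger = logging.getLogger(__name__)

__all__ = [
    "label_consistency",
    "IPTWWeights",
    "iptw_weights",
    "standardized_mean_differences",
    "kaplan_meier",
    "logrank_test",
    "cox_hr",
    "brier_scores",
    "integrated_brier",
    "feature_ablation",
    "tlearner_cph",
    "rule_recommender",
    "RecommendationReport",
    "evaluate",
]


# --------------------------------------------------------------------------
# consistency labels and IPTW
# --------------------------------------------------------------------------

def label_consistency(actual, recommended) -> np.ndarray:
    """Boolean per-subject flag: True where actual treatment == recommendation."""
    actual = np.asarray(actual).ravel()
    recommended = np.asarray(recommended).ravel()
    if actual.shape != recommended.shape:
        raise ValueError(
            f"length mismatch: {actual.shape[0]} actual vs "
            f"{recommended.shape[0]} recommended")
    return actual == recommended


@dataclass
class IPTWWeights:
    """Inverse-probability weights with their propensity scores."""

    weights: np.ndarray
    propensity: np.ndarray
    stabilized: bool
    truncation: tuple[float, float] | None
    dropped_columns: list[int] = field(default_factory=list)


def _full_rank_columns(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent, non-constant column subset."""
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    if not keep:
        return np.array([], dtype=int)
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    _, R, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    chosen = sorted(piv[:rank])
    return np.asarray([keep[j] for j in chosen], dtype=int)


def iptw_weights(X: np.ndarray, group, stabilize: bool = True,
                 truncate: tuple[float, float] | None = (0.01, 0.99)) -> IPTWWeights:
    """Inverse probability weights from a logistic propensity model.

    ``weight = g/e(x) + (1-g)/(1-e(x))``, optionally stabilized by the
    marginal group probabilities and truncated at the stated weight
    quantiles. Constant covariate columns are dropped with a warning;
    (near-)perfect separation raises with a diagnostic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    g = np.asarray(group).astype(int).ravel()
    if not (g == 0).any() or not (g == 1).any():
        raise ValueError("both groups must be non-empty to fit a propensity model")
    keep = _full_rank_columns(X)
    dropped = [j for j in range(X.shape[1]) if j not in set(keep.tolist())]
    constant = [j for j in dropped if np.ptp(X[:, j]) == 0]
    if constant:
        warnings.warn(f"dropping constant covariate columns {constant} "
                      "from the propensity model")
    Xu = X[:, keep] if keep.size else np.zeros((X.shape[0], 0))
    if Xu.shape[1] == 0:
        e = np.full(X.shape[0], g.mean())
    else:
        lr = LogisticRegression(C=np.inf, max_iter=2000)
        lr.fit(Xu, g)
        if np.max(np.abs(lr.coef_)) > 30:
            raise ValueError(
                "propensity model shows (near-)perfect separation "
                f"(max |coef| = {np.max(np.abs(lr.coef_)):.1f}); "
                "IPTW weights would be unstable")
        e = lr.predict_proba(Xu)[:, 1]
    e = np.clip(e, 1e-12, 1 - 1e-12)
    w = g / e + (1 - g) / (1 - e)
    if stabilize:
        p1 = g.mean()
        w = np.where(g == 1, p1, 1 - p1) * w
    if truncate is not None:
        lo, hi = np.quantile(w, truncate)
        w = np.clip(w, lo, hi)
    return IPTWWeights(weights=w, propensity=e, stabilized=stabilize,
                       truncation=truncate, dropped_columns=dropped)


def standardized_mean_differences(X: np.ndarray, group,
                                  weights=None) -> np.ndarray:
    """Per-column absolute standardized mean difference between groups.

    The denominator is the pooled (unweighted) standard deviation, the usual
    balance diagnostic for IPTW.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    g = np.asarray(group).astype(int).ravel()
    w = np.ones_like(g, dtype=float) if weights is None else np.asarray(weights, float)
    out = np.zeros(X.shape[1])
    m1, m0 = g == 1, g == 0
    for j in range(X.shape[1]):
        mu1 = np.average(X[m1, j], weights=w[m1])
        mu0 = np.average(X[m0, j], weights=w[m0])
        s = np.sqrt(0.5 * (X[m1, j].var(ddof=1) + X[m0, j].var(ddof=1)))
        out[j] = 0.0 if s == 0 else abs(mu1 - mu0) / s
    return out


# --------------------------------------------------------------------------
# weighted KM and log-rank
# --------------------------------------------------------------------------

def kaplan_meier(time, event, weights=None) -> SurvivalCurve:
    """(Weighted) product-limit estimator as a right-continuous step curve."""
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).astype(int).ravel()
    w = np.ones_like(time) if weights is None else np.asarray(weights, float).ravel()
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("all weights are zero")
    ev_times = np.unique(time[event == 1])
    if ev_times.size == 0:
        return SurvivalCurve(np.array([time.max() if time.size else 0.0]),
                             np.array([1.0]))
    surv = np.empty(ev_times.size)
    s = 1.0
    for i, t in enumerate(ev_times):
        at_risk = w[time >= t].sum()
        d = w[(time == t) & (event == 1)].sum()
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        surv[i] = s
    return SurvivalCurve(ev_times, surv)


def logrank_test(time_a, event_a, time_b, event_b,
                 weights_a=None, weights_b=None):
    """(Weighted) two-sample log-rank test; returns ``(chi2, p)`` at 1 df.

    Case weights enter the at-risk and event counts, the standard construction
    for IPTW-adjusted log-rank comparisons.
    """
    ta = np.asarray(time_a, dtype=float).ravel()
    ea = np.asarray(event_a).astype(int).ravel()
    tb = np.asarray(time_b, dtype=float).ravel()
    eb = np.asarray(event_b).astype(int).ravel()
    wa = np.ones_like(ta) if weights_a is None else np.asarray(weights_a, float)
    wb = np.ones_like(tb) if weights_b is None else np.asarray(weights_b, float)
    if ea.sum() == 0 or eb.sum() == 0:
        raise ValueError("log-rank test requires events in both groups")
    ev = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O_minus_E = 0.0
    V = 0.0
    for t in ev:
        na = wa[ta >= t].sum()
        nb = wb[tb >= t].sum()
        da = wa[(ta == t) & (ea == 1)].sum()
        db = wb[(tb == t) & (eb == 1)].sum()
        n = na + nb
        d = da + db
        if n <= 1 or d == 0:
            continue
        O_minus_E += da - d * na / n
        V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if V <= 0:
        return 0.0, 1.0
    chi2 = O_minus_E ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# --------------------------------------------------------------------------
# Cox hazard ratio
# --------------------------------------------------------------------------

def cox_hr(time, event, group, covariates=None, weights=None,
           robust: bool | None = None):
    """Hazard ratio of ``group`` from a (weighted) multivariate Cox fit.

    Breslow tie handling; when the weights are non-unit, the CI uses the
    robust sandwich variance. Returns ``(hr, (lo, hi), p)``.
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).astype(int).ravel()
    g = np.asarray(group).astype(int).ravel()
    df = pd.DataFrame({"time": time, "event": event, "group": g})
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        keep = _full_rank_columns(cov)
        for k, j in enumerate(keep):
            df[f"z{k}"] = cov[:, j]
    kwargs = {}
    if weights is not None:
        df["_w"] = np.asarray(weights, dtype=float)
        kwargs["weights_col"] = "_w"
        if robust is None:
            robust = not np.allclose(df["_w"], 1.0)
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event",
                    robust=bool(robust), **kwargs)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model did not converge: {err}") from err
    hr = float(np.exp(cph.params_["group"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["group"]).to_numpy()
    p = float(cph.summary.loc["group", "p"])
    return hr, (float(lo), float(hi)), p


# --------------------------------------------------------------------------
# IPCW Brier score
# --------------------------------------------------------------------------

def _censoring_km(time, event):
    """KM of the censoring distribution G(t) (events treated as censorings)."""
    return kaplan_meier(time, 1 - np.asarray(event).astype(int))


def brier_scores(curves, time, event, grid):
    """IPCW Brier score BS(t) on a time grid.

    ``curves`` holds one predicted :class:`SurvivalCurve` per subject.
    Subjects dead by t are weighted by 1/G(T_i-), still-at-risk subjects by
    1/G(t), where G is the KM estimate of the censoring distribution.
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).astype(int).ravel()
    grid = np.asarray(grid, dtype=float).ravel()
    n = time.size
    if len(curves) != n:
        raise ValueError("need one predicted curve per subject")
    G = _censoring_km(time, event)
    # left limit of G at each subject's own time
    G_minus = np.asarray(G.evaluate(np.nextafter(time, -np.inf)))
    S = np.vstack([c.evaluate(grid) for c in curves])  # (n, len(grid))
    out = np.empty(grid.size)
    for k, t in enumerate(grid):
        Gt = float(np.asarray(G.evaluate(t)))
        dead = (time <= t) & (event == 1)
        alive = time > t
        if alive.any() and Gt <= 0:
            raise ValueError(
                f"censoring distribution reaches 0 before t={t:.1f}; "
                "use a smaller horizon")
        if dead.any() and np.any(G_minus[dead] <= 0):
            raise ValueError("censoring distribution reaches 0 within the "
                             "horizon; use a smaller horizon")
        total = 0.0
        if dead.any():
            total += np.sum(S[dead, k] ** 2 / G_minus[dead])
        if alive.any():
            total += np.sum((1.0 - S[alive, k]) ** 2 / Gt)
        out[k] = total / n
    return out


def integrated_brier(curves, time, event, horizon: float) -> float:
    """IPCW Brier score integrated over [0, horizon], normalized by horizon."""
    time = np.asarray(time, dtype=float).ravel()
    if horizon > time.max():
        raise ValueError("horizon exceeds maximum follow-up")
    G = _censoring_km(time, event)
    if float(np.asarray(G.evaluate(horizon))) <= 0:
        raise ValueError("censoring distribution reaches 0 by the horizon; "
                         "use a smaller horizon")
    ev = np.unique(time[(np.asarray(event).astype(int).ravel() == 1)
                        & (time <= horizon)])
    grid = np.unique(np.concatenate([[0.0], ev, [horizon]]))
    bs = brier_scores(curves, time, event, grid)
    return float(np.trapezoid(bs, grid) / horizon)


# --------------------------------------------------------------------------
# comparators
# --------------------------------------------------------------------------

class _TLearnerResults:
    """Adapter exposing the prediction surface of a fitted T-learner CPH so
    the TaR/ITE/recommendation machinery is reused verbatim."""

    def __init__(self, coefs, baselines, keep):
        self._coefs = coefs
        self.baselines = baselines
        self._keep = keep

    def predict_score(self, X, arm):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, self._keep] @ self._coefs[arm]


def tlearner_cph(train: SurvivalDataset, test: SurvivalDataset,
                 mortality_threshold: float = 0.90) -> pd.DataFrame:
    """T-learner Cox baseline: one Cox model per arm, shared ITE machinery.

    Fits an (unpenalized, Breslow) Cox model per treatment arm, estimates
    Breslow baselines, and derives TaR/ITE/recommendations exactly as the
    network model does. Deterministic.
    """
    train.require_both_arms_with_events()
    keep = _full_rank_columns(train.X)
    coefs, baselines = {}, {}
    for a in (0, 1):
        arm = train.arm(a)
        df = pd.DataFrame(arm.X[:, keep],
                          columns=[f"z{k}" for k in range(keep.size)])
        df["time"], df["event"] = arm.time, arm.event
        cph = CoxPHFitter(penalizer=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        beta = cph.params_.to_numpy()
        coefs[a] = beta
        scores = arm.X[:, keep] @ beta
        baselines[a] = breslow_baseline(scores, arm.time, arm.event)
    adapter = _TLearnerResults(coefs, baselines, keep)
    return recommend_batch(adapter, test, mortality_threshold=mortality_threshold)


_RULE_OPS = {
    "<": np.less, "<=": np.less_equal, ">": np.greater,
    ">=": np.greater_equal, "==": np.equal, "!=": np.not_equal,
}


def rule_recommender(rules: list[dict], X: pd.DataFrame) -> np.ndarray:
    """Declarative guideline comparator: first matching rule per subject.

    Each rule is ``{"column", "op", "value", "recommend"}`` or a catch-all
    ``{"recommend": r}``. Subjects matching no rule raise an error listing
    their ids.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("rule_recommender expects a DataFrame of covariates")
    n = len(X)
    rec = np.full(n, -1, dtype=int)
    for rule in rules:
        if "column" not in rule:
            matches = np.ones(n, dtype=bool)
        else:
            if rule["column"] not in X.columns:
                raise KeyError(f"rule references unknown column {rule['column']!r}")
            op = _RULE_OPS[rule.get("op", "==")]
            matches = op(X[rule["column"]].to_numpy(), rule["value"])
        rec = np.where((rec < 0) & matches, int(rule["recommend"]), rec)
    unmatched = np.flatnonzero(rec < 0)
    if unmatched.size:
        raise ValueError(f"no rule matched subjects {unmatched.tolist()[:20]}"
                         + ("..." if unmatched.size > 20 else ""))
    return rec


# --------------------------------------------------------------------------
# feature ablation
# --------------------------------------------------------------------------

def _arm_ibs(results, data: SurvivalDataset, horizon: float):
    """Overall and arm-wise IBS of a fitted model on ``data``."""
    from .inference import predict_survival

    curves = [None] * data.n
    for a in (0, 1):
        idx = np.flatnonzero(data.treatment == a)
        if idx.size:
            for i, c in zip(idx, predict_survival(results, data.X[idx], a)):
                curves[i] = c
    h = min(horizon, float(data.time.max()))
    overall = integrated_brier(curves, data.time, data.event, h)
    out = {"overall": overall}
    for a in (0, 1):
        mask = data.treatment == a
        arm_curves = [curves[i] for i in np.flatnonzero(mask)]
        ha = min(horizon, float(data.time[mask].max()))
        out[f"arm{a}"] = integrated_brier(arm_curves, data.time[mask],
                                          data.event[mask], ha)
    return out


def feature_ablation(train: SurvivalDataset, test: SurvivalDataset,
                     config, feature_groups: dict[str, list[str]],
                     horizon: float = 120.0) -> pd.DataFrame:
    """Retrain without each feature group and report IBS changes.

    Each group names columns of the dataset; the model is refit with the
    same config and seed on the reduced covariates and the change in overall
    and arm-wise IBS on the test set (ablated minus full) is reported.
    """
    from .model import SNBModel

    name_to_idx = {n: i for i, n in enumerate(train.feature_names)}
    for gname, cols in feature_groups.items():
        unknown = [c for c in cols if c not in name_to_idx]
        if unknown:
            raise KeyError(f"feature group {gname!r} names unknown columns {unknown}")

    full = SNBModel(train, config).fit()
    full_ibs = _arm_ibs(full, test, horizon)

    rows = []
    for gname, cols in feature_groups.items():
        drop = {name_to_idx[c] for c in cols}
        keep = [i for i in range(train.p) if i not in drop]

        def reduced(ds):
            return SurvivalDataset(
                X=ds.X[:, keep], treatment=ds.treatment, time=ds.time,
                event=ds.event,
                feature_names=[ds.feature_names[i] for i in keep], ids=ds.ids)

        res = SNBModel(reduced(train), config).fit()
        abl = _arm_ibs(res, reduced(test), horizon)
        rows.append({
            "group": gname,
            "delta_ibs_overall": abl["overall"] - full_ibs["overall"],
            "delta_ibs_arm0": abl["arm0"] - full_ibs["arm0"],
            "delta_ibs_arm1": abl["arm1"] - full_ibs["arm1"],
        })
    return pd.DataFrame(rows).set_index("group")


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

@dataclass
class RecommendationReport:
    """Table-2-style summary of the recommendation effect."""

    hr: float
    hr_ci: tuple[float, float]
    hr_iptw: float | None
    hr_iptw_ci: tuple[float, float] | None
    rd: float
    rd_ci: tuple[float, float]
    rd_iptw: float | None
    rd_iptw_ci: tuple[float, float] | None
    drmst: float
    drmst_ci: tuple[float, float]
    drmst_iptw: float | None
    drmst_iptw_ci: tuple[float, float] | None
    ibs_arm0: float | None
    ibs_arm0_ci: tuple[float, float] | None
    ibs_arm1: float | None
    ibs_arm1_ci: tuple[float, float] | None
    logrank_p: float
    logrank_p_iptw: float | None
    horizon: float
    n_consistent: int
    n_inconsistent: int
    schema: int = 1

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, tuple):
                return [float(x) for x in v]
            return v
        return {k: conv(v) for k, v in self.__dict__.items()}

    def summary(self) -> str:
        def fmt(x, ci):
            if x is None:
                return "   --"
            s = f"{x:8.3f}"
            if ci is not None:
                s += f"  ({ci[0]:.3f}, {ci[1]:.3f})"
            return s
        lines = [
            "Recommendation effect (consistent vs inconsistent)",
            "=" * 52,
            f"n consistent / inconsistent: {self.n_consistent} / {self.n_inconsistent}",
            f"horizon: {self.horizon:.0f} months",
            f"HR            {fmt(self.hr, self.hr_ci)}",
            f"HR (IPTW)     {fmt(self.hr_iptw, self.hr_iptw_ci)}",
            f"RD %          {fmt(self.rd, self.rd_ci)}",
            f"RD % (IPTW)   {fmt(self.rd_iptw, self.rd_iptw_ci)}",
            f"dRMST mo      {fmt(self.drmst, self.drmst_ci)}",
            f"dRMST (IPTW)  {fmt(self.drmst_iptw, self.drmst_iptw_ci)}",
            f"IBS arm0      {fmt(self.ibs_arm0, self.ibs_arm0_ci)}",
            f"IBS arm1      {fmt(self.ibs_arm1, self.ibs_arm1_ci)}",
            f"log-rank p            {self.logrank_p:.4g}",
            f"log-rank p (IPTW)     "
            f"{self.logrank_p_iptw if self.logrank_p_iptw is None else format(self.logrank_p_iptw, '.4g')}",
        ]
        return "\n".join(lines)


def _km_metrics(time, event, consis, horizon, weights=None):
    wa = None if weights is None else weights[consis]
    wb = None if weights is None else weights[~consis]
    km_a = kaplan_meier(time[consis], event[consis], wa)
    km_b = kaplan_meier(time[~consis], event[~consis], wb)
    rd = risk_difference(km_a, km_b, horizon)
    dr = drmst(km_a, km_b, horizon)
    return rd, dr


def evaluate(data: SurvivalDataset, recommendations, results=None, *,
             horizon: float = 120.0, iptw: bool = True,
             propensity_target: str = "consistency",
             n_bootstrap: int = 200, weights=None,
             mortality_threshold: float = 0.90,
             seed: int = 0) -> RecommendationReport:
    """Assemble the full recommendation-effect report.

    Parameters
    ----------
    data : SurvivalDataset
        Evaluation cohort with actual treatments and outcomes.
    recommendations : array-like or DataFrame
        Per-subject recommended treatment (0/1); a DataFrame from
        :func:`snbsurv.inference.recommend_batch` is accepted.
    results : SNBResults or compatible, optional
        Fitted model used for the arm-wise integrated Brier scores; omitted,
        the IBS entries are None.
    horizon : float
        Time horizon in months for RD, dRMST and IBS (default 120 = 10 years).
    iptw : bool
        Also compute IPTW-adjusted metrics.
    propensity_target : {"consistency", "treatment"}
        Whether the propensity model predicts consistency-group membership
        (the default, mirroring the consistent/inconsistent contrast) or the
        actual treatment.
    weights : array-like, optional
        Externally supplied weights replacing the estimated IPTW weights
        (all-ones weights reproduce the unadjusted metrics exactly).
    n_bootstrap : int
        Replicates for percentile CIs of RD/dRMST/IBS; HR CIs come from the
        (robust) Cox variance.
    """
    if isinstance(recommendations, pd.DataFrame):
        recommendations = recommendations["recommendation"].to_numpy()
    rec = np.asarray(recommendations).astype(int).ravel()
    consis = label_consistency(data.treatment, rec)
    if consis.all() or (~consis).all():
        raise ValueError("both consistent and inconsistent groups must be "
                         "non-empty to evaluate a recommender")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 96929]))
    time, event, X = data.time, data.event, data.X
    horizon = min(horizon, float(time.max()))

    # --- unadjusted ---------------------------------------------------------
    rd, dr = _km_metrics(time, event, consis, horizon)
    _, logrank_p = logrank_test(time[consis], event[consis],
                                time[~consis], event[~consis])
    hr, hr_ci, _ = cox_hr(time, event, consis.astype(int), covariates=X)

    # --- IPTW ---------------------------------------------------------------
    w = rd_w = dr_w = hr_w = hr_w_ci = logrank_p_w = None
    if iptw or weights is not None:
        if weights is not None:
            w = np.asarray(weights, dtype=float).ravel()
        else:
            target = consis.astype(int) if propensity_target == "consistency" \
                else data.treatment
            w = iptw_weights(X, target).weights
        rd_w, dr_w = _km_metrics(time, event, consis, horizon, w)
        _, logrank_p_w = logrank_test(time[consis], event[consis],
                                      time[~consis], event[~consis],
                                      w[consis], w[~consis])
        hr_w, hr_w_ci, _ = cox_hr(time, event, consis.astype(int),
                                  covariates=X, weights=w)

    # --- arm-wise IBS -------------------------------------------------------
    ibs = {0: None, 1: None}
    arm_curves = {}
    if results is not None:
        from .inference import predict_survival
        for a in (0, 1):
            mask = data.treatment == a
            if mask.any():
                arm_curves[a] = predict_survival(results, X[mask], a)
                ha = min(horizon, float(time[mask].max()))
                ibs[a] = integrated_brier(arm_curves[a], time[mask],
                                          event[mask], ha)

    # --- bootstrap percentile CIs ------------------------------------------
    boot = {"rd": [], "dr": [], "rd_w": [], "dr_w": [], "ibs0": [], "ibs1": []}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, data.n, size=data.n)
        c_b = consis[idx]
        if c_b.all() or (~c_b).all() or event[idx][c_b].sum() == 0 \
                or event[idx][~c_b].sum() == 0:
            continue
        t_b, e_b = time[idx], event[idx]
        h_b = min(horizon, float(t_b.max()))
        r, d = _km_metrics(t_b, e_b, c_b, h_b)
        boot["rd"].append(r)
        boot["dr"].append(d)
        if w is not None:
            if weights is not None:
                w_b = w[idx]
            else:
                target_b = c_b.astype(int) if propensity_target == "consistency" \
                    else data.treatment[idx]
                try:
                    w_b = iptw_weights(X[idx], target_b).weights
                except ValueError:
                    w_b = None
            if w_b is not None:
                r, d = _km_metrics(t_b, e_b, c_b, h_b, w_b)
                boot["rd_w"].append(r)
                boot["dr_w"].append(d)
        if results is not None:
            for a in (0, 1):
                mask = data.treatment[idx] == a
                if not mask.any() or event[idx][mask].sum() == 0:
                    continue
                sub = idx[mask]
                pos = {orig: k for k, orig in
                       enumerate(np.flatnonzero(data.treatment == a))}
                curves_b = [arm_curves[a][pos[i]] for i in sub]
                ha = min(horizon, float(time[sub].max()))
                try:
                    boot[f"ibs{a}"].append(
                        integrated_brier(curves_b, time[sub], event[sub], ha))
                except ValueError:
                    pass

    def ci(samples):
        if len(samples) < 10:
            return None
        lo, hi = np.percentile(samples, [2.5, 97.5])
        return (float(lo), float(hi))

    return RecommendationReport(
        hr=hr, hr_ci=hr_ci, hr_iptw=hr_w, hr_iptw_ci=hr_w_ci,
        rd=rd, rd_ci=ci(boot["rd"]),
        rd_iptw=rd_w, rd_iptw_ci=ci(boot["rd_w"]),
        drmst=dr, drmst_ci=ci(boot["dr"]),
        drmst_iptw=dr_w, drmst_iptw_ci=ci(boot["dr_w"]),
        ibs_arm0=ibs[0], ibs_arm0_ci=ci(boot["ibs0"]),
        ibs_arm1=ibs[1], ibs_arm1_ci=ci(boot["ibs1"]),
        logrank_p=logrank_p, logrank_p_iptw=logrank_p_w,
        horizon=horizon,
        n_consistent=int(consis.sum()), n_inconsistent=int((~consis).sum()),
    )
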