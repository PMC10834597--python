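"""Cox partial likelihood (Breslow ties) and the Breslow baseline hazard.

These are the survival primitives shared by the network loss, the
counterfactual survival curves, and the T-learner Cox baseline. Scores are
log hazard ratios; ``cox_partial_loglik`` returns the *mean negative* log
partial likelihood (the quantity minimized during training), and
``breslow_baseline`` the cumulative baseline hazard step function.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cox_partial_loglik",
    "cox_partial_loglik_grad",
    "breslow_baseline",
]


def _prepare(scores, time, event):
    scores = np.asarray(scores, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).astype(int).ravel()
    if not (scores.shape == time.shape == event.shape):
        raise ValueError("scores, time and event must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if event.sum() == 0:
        raise ValueError("no events: Cox partial likelihood is undefined")
    return scores, time, event


def _risk_structure(scores, time, event):
    """Per-unique-event-time risk-set sums (Breslow convention).

    Returns ``(order, d, logS, S, first_idx)`` where, in time-ascending order,
    ``d[u]`` is the number of events at unique event time u, ``S[u]`` the sum
    of exp(score) over the risk set {j : t_j >= u}, and ``first_idx[u]`` the
    position of the first subject with t >= u.
    """
    order = np.argsort(time, kind="stable")
    t_s, e_s, s_s = time[order], event[order], scores[order]
    # stabilized exp
    smax = s_s.max()
    exp_s = np.exp(s_s - smax)
    # reverse cumulative sum: risk set sum for each position i is sum_{j>=i}
    rev_cum = np.cumsum(exp_s[::-1])[::-1]
    ev_times, d = np.unique(t_s[e_s == 1], return_counts=True)
    first_idx = np.searchsorted(t_s, ev_times, side="left")
    S = rev_cum[first_idx]  # still on the shifted scale
    logS = np.log(S) + smax
    return order, t_s, e_s, s_s, ev_times, d, logS, S * np.exp(smax), first_idx


def cox_partial_loglik(scores, time, event) -> float:
    """Mean negative Cox log partial likelihood with Breslow tie handling.

    Each event contributes ``score_i - log sum_{j in risk set} exp(score_j)``;
    the negated sum is averaged over the number of events. Invariant to adding
    a constant to every score.
    """
    scores, time, event = _prepare(scores, time, event)
    _, t_s, e_s, s_s, ev_times, d, logS, _, _ = _risk_structure(scores, time, event)
    event_scores_sum = s_s[e_s == 1].sum()
    ll = event_scores_sum - float(d @ logS)
    return -ll / event.sum()


def cox_partial_loglik_grad(scores, time, event):
    """Value and gradient of :func:`cox_partial_loglik` w.r.t. the scores.

    Uses the closed form d/ds_k = -(1/D) * (e_k - exp(s_k) * A_k) with
    ``A_k = sum over event times u <= t_k of d_u / S_u`` (the Breslow
    cumulative hazard evaluated at t_k).
    """
    scores, time, event = _prepare(scores, time, event)
    (order, t_s, e_s, s_s, ev_times, d, logS, S, _) = _risk_structure(
        scores, time, event)
    D = event.sum()
    ll = s_s[e_s == 1].sum() - float(d @ logS)
    # A(t) = sum_{u <= t} d_u / S_u, evaluated at each subject's time
    increments = d / S
    cumA = np.cumsum(increments)
    pos = np.searchsorted(ev_times, t_s, side="right")
    A = np.where(pos > 0, cumA[np.maximum(pos - 1, 0)], 0.0)
    grad_sorted = -(e_s - np.exp(s_s) * A) / D
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return -ll / D, grad


def breslow_baseline(scores, time, event):
    """Breslow cumulative baseline hazard H0(t) as a step function.

    Returns ``(times, cumhaz)``: unique event times in ascending order and
    H0 evaluated there; H0 is 0 before the first event time and constant
    between event times. With all scores equal to 0 this is the Nelson-Aalen
    estimator.
    """
    scores, time, event = _prepare(scores, time, event)
    _, _, _, _, ev_times, d, _, S, _ = _risk_structure(scores, time, event)
    return ev_times, np.cumsum(d / S)


def evaluate_step(times: np.ndarray, values: np.ndarray, t,
                  before: float = 0.0):
    """Evaluate a right-continuous step function at ``t`` (vectorized).

    ``values[i]`` applies on ``[times[i], times[i+1])``; ``before`` applies
    for t < times[0].
    """
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(times, t, side="right") - 1
    out = np.where(idx >= 0, values[np.maximum(idx, 0)], before)
    return out if out.ndim else float(out)
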