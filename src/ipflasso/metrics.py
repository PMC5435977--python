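"""Performance metrics for tuning and evaluation.

mse / misclassification / AUC for the uncensored families, and for
survival data the cross-validated Cox partial likelihood (Verweij-van
Houwelingen form) plus the time-dependent Brier score with inverse
probability of censoring weighting (IPCW) and its integral (IBS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .data import Outcome
from .objectives import BreslowIndex

#: metric name -> (direction, compatible family)
METRICS = {
    "mse": ("minimize", "gaussian"),
    "misclassification": ("minimize", "binomial"),
    "auc": ("maximize", "binomial"),
    "cox_cvpl": ("maximize", "cox"),
    "deviance": ("minimize", None),  # any family; family-specific log-loss
}


@dataclass(frozen=True)
class MetricSpec:
    name: str
    direction: str

    @classmethod
    def for_family(cls, name: str, family: str) -> "MetricSpec":
        if name not in METRICS:
            raise ValueError(f"unknown metric {name!r}; choose from {sorted(METRICS)}")
        direction, fam = METRICS[name]
        if fam is not None and fam != family:
            raise ValueError(f"metric {name!r} is defined for the {fam} family")
        return cls(name, direction)


def default_metric(family: str) -> str:
    return {"gaussian": "mse", "binomial": "misclassification", "cox": "cox_cvpl"}[family]


def mse(pred, y) -> float:
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.mean((pred - y) ** 2))


def misclassification_rate(prob, y) -> float:
    """Fraction of samples with thresholded probability != class; cut at 0.5.

    A probability of exactly 0.5 is classed as 1 (prob >= 0.5 rule).
    """
    prob = np.asarray(prob, dtype=float)
    y = np.asarray(y, dtype=float)
    if prob.size == 0:
        raise ValueError("empty input")
    if prob.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.mean((prob >= 0.5).astype(float) != y))


def auc(score, y) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count 1/2.

    Invariant under strictly increasing transforms of the score.
    """
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y, np.asarray(score, dtype=float)))


def binomial_deviance(prob, y) -> float:
    """Mean -2 log-likelihood of the held-out labels."""
    prob = np.clip(np.asarray(prob, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(np.mean(-2 * (y * np.log(prob) + (1 - y) * np.log(1 - prob))))


# ---------------------------------------------------------------------------
# survival metrics


def cox_cvpl(beta, X_full, out_full: Outcome, train_idx) -> float:
    """Held-out Cox partial-log-likelihood contribution of one CV fold.

    Verweij-van Houwelingen form: pl_full(beta_train) - pl_train(beta_train),
    where beta_train was estimated on the training part only.  Summed over
    folds this gives the cross-validated partial likelihood (maximized).
    """
    X_full = np.asarray(X_full, dtype=float)
    beta = np.asarray(beta, dtype=float)
    train_idx = np.asarray(train_idx)
    full = BreslowIndex(out_full.time, out_full.status)
    out_tr = out_full.subset(train_idx)
    if out_tr.status.sum() == 0:
        warnings.warn("training fold has no events; cvpl contribution set to 0")
        return 0.0
    train = BreslowIndex(out_tr.time, out_tr.status)
    eta_full = X_full @ beta
    return float(full.loglik(eta_full) - train.loglik(eta_full[train_idx]))


def null_cox_loglik(time, status) -> float:
    """Breslow partial log-likelihood at beta = 0 (closed form over risk sets)."""
    return float(BreslowIndex(time, status).loglik(np.zeros(len(np.asarray(time)))))


def _km_censoring(time, status):
    """Kaplan-Meier estimate of the censoring distribution G(t) = P(C > t).

    Returns step-function knots (censoring times) and values; right-
    continuous, G(0) = 1.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=float)
    order = np.argsort(time, kind="stable")
    t = time[order]
    cens = 1.0 - status[order]  # censoring is the "event" here
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - first
    d = np.add.reduceat(cens, first)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - d / at_risk
    G = np.cumprod(factors)
    return uniq, G


def _eval_step(knots, values, t, left=False):
    """Evaluate a right-continuous step function (1.0 before the first knot).

    With left=True returns the left limit G(t-).
    """
    t = np.asarray(t, dtype=float)
    side = "left" if left else "right"
    pos = np.searchsorted(knots, t, side=side)
    vals = np.concatenate([[1.0], values])
    return vals[pos]


@dataclass(frozen=True)
class BrierCurve:
    eval_times: np.ndarray
    scores: np.ndarray
    horizon: float


def brier_curve(surv_pred, out: Outcome, eval_times, train_outcome: Outcome = None) -> BrierCurve:
    """Time-dependent Brier score with IPCW (Graf weighting).

    BS(t) = (1/n) sum_i w_i(t) (1{T_i > t} - S_i(t))^2 with
    w_i(t) = 1{T_i <= t, d_i = 1} / G(T_i-) + 1{T_i > t} / G(t);
    subjects censored before t contribute weight 0.  The censoring
    distribution G is a Kaplan-Meier estimate on ``train_outcome``
    (defaults to the evaluation sample itself).

    ``surv_pred`` is an n x len(eval_times) matrix of predicted survival
    probabilities S_i(t).
    """
    eval_times = np.asarray(eval_times, dtype=float)
    surv_pred = np.asarray(surv_pred, dtype=float)
    if surv_pred.shape != (out.n, eval_times.size):
        raise ValueError("surv_pred must be n x len(eval_times)")
    src = train_outcome if train_outcome is not None else out
    knots, G = _km_censoring(src.time, src.status)

    T = out.time
    d = out.status
    G_Tm = _eval_step(knots, G, T, left=True)       # G(T_i-)
    G_t = _eval_step(knots, G, eval_times)          # G(t)

    scores = np.empty(eval_times.size)
    horizon = float(eval_times.max())
    for k, t in enumerate(eval_times):
        if G_t[k] <= 0:
            warnings.warn(
                f"censoring survival reaches 0 before t={t}; truncating horizon"
            )
            scores = scores[:k]
            eval_times = eval_times[:k]
            horizon = float(eval_times.max()) if eval_times.size else 0.0
            break
        event_before = (T <= t) & (d == 1)
        alive = T > t
        w = np.zeros(out.n)
        with np.errstate(divide="ignore"):
            w[event_before] = 1.0 / G_Tm[event_before]
        w[alive] = 1.0 / G_t[k]
        ind = alive.astype(float)
        scores[k] = np.sum(w * (ind - surv_pred[:, k]) ** 2) / out.n
    return BrierCurve(eval_times, scores, horizon)


def integrated_brier(curve: BrierCurve) -> float:
    """Trapezoidal integral of BS(t) over [0, horizon], divided by horizon.

    The curve is taken to start at BS(0) = 0 at t = 0.
    """
    if curve.eval_times.size < 2:
        raise ValueError("need at least two evaluation times")
    t = np.concatenate([[0.0], curve.eval_times])
    s = np.concatenate([[0.0], curve.scores])
    return float(np.trapezoid(s, t) / curve.horizon)


def default_eval_times(out: Outcome, horizon: float = None) -> np.ndarray:
    """Unique event times up to the horizon (default: 95th time percentile)."""
    if horizon is None:
        horizon = float(np.quantile(out.time, 0.95))
    t = np.unique(out.time[(out.status == 1) & (out.time <= horizon)])
    if t.size == 0:
        raise ValueError("no event times below the horizon")
    return t


def evaluate_metric(name, family, pred, out: Outcome) -> float:
    """Dispatch a prediction-based metric by name."""
    if name == "mse":
        return mse(pred, out.y)
    if name == "misclassification":
        return misclassification_rate(pred, out.y)
    if name == "auc":
        return auc(pred, out.y)
    if name == "deviance":
        if family == "binomial":
            return binomial_deviance(pred, out.y)
        if family == "gaussian":
            return mse(pred, out.y)
        raise ValueError("deviance dispatch: use cox_cvpl for survival data")
    raise ValueError(f"metric {name!r} is not prediction-based")
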