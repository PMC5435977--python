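"""Smooth loss functions, gradients and IRLS working quantities.

All losses are scaled by 1/n (1/(2n) for the gaussian residual sum of
squares) so that the penalty parameter lambda is comparable across sample
sizes:

    gaussian : (1/(2n)) * sum (y - b0 - x.beta)^2
    binomial : (1/n) * sum [ log(1 + e^eta) - y * eta ],  eta = b0 + x.beta
    cox      : (1/n) * negative Breslow partial log-likelihood, no intercept

The gradient helpers are also the basis of the KKT certificates used in
the test suite and of lambda_max.
"""

from __future__ import annotations

import numpy as np

from .data import Outcome

_P_EPS = 1e-8
_W_FLOOR = 1e-5


def _sigmoid(eta):
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# Breslow partial-likelihood machinery (ties handled by Breslow's method)


class BreslowIndex:
    """Precomputed ordering and event-time grouping for one survival sample."""

    def __init__(self, time, status):
        self.time = np.asarray(time, dtype=float)
        self.status = np.asarray(status, dtype=float)
        order = np.argsort(self.time, kind="stable")
        self.order = order
        t = self.time[order]
        d = self.status[order]
        # unique event times with multiplicities
        ev_mask = d == 1
        self.event_times, self.event_counts = np.unique(t[ev_mask], return_counts=True)
        # first index (in sorted order) at risk at each event time: time >= t_e
        self.risk_start = np.searchsorted(t, self.event_times, side="left")
        self.t_sorted = t
        self.d_sorted = d
        self.n = self.time.size

    def loglik(self, eta):
        """Breslow partial log-likelihood at linear predictor eta (length n)."""
        eta = np.asarray(eta, dtype=float)
        es = eta[self.order]
        # stabilise exp
        c = es.max() if es.size else 0.0
        ex = np.exp(es - c)
        # reverse cumulative sum -> risk-set sums
        rc = np.cumsum(ex[::-1])[::-1]
        S = rc[self.risk_start]  # scaled by e^{-c}
        ev = self.d_sorted == 1
        ll = es[ev].sum() - np.sum(self.event_counts * (np.log(S) + c))
        return ll

    def _risk_terms(self, eta):
        es = eta[self.order]
        c = es.max() if es.size else 0.0
        ex = np.exp(es - c)
        rc = np.cumsum(ex[::-1])[::-1]
        S = rc[self.risk_start] * np.exp(c)
        ex = ex * np.exp(c)
        return es, ex, S

    def grad_eta(self, eta):
        """Gradient of the NEGATIVE partial log-likelihood wrt eta (unsorted order)."""
        es, ex, S = self._risk_terms(eta)
        d_over_S = self.event_counts / S
        # C_k = sum over event times t_e <= t_k of d_e / S_e
        C = self._cum_event_sum(d_over_S)
        g_sorted = -(self.d_sorted - ex * C)
        g = np.empty_like(g_sorted)
        g[self.order] = g_sorted
        return g

    def working(self, eta):
        """IRLS working weights and response for the 1/n-scaled negative pll.

        Returns (w, z) in the original subject order;  w uses the diagonal
        of the Hessian wrt eta.
        """
        es, ex, S = self._risk_terms(eta)
        d_over_S = self.event_counts / S
        d_over_S2 = self.event_counts / S ** 2
        C = self._cum_event_sum(d_over_S)
        C2 = self._cum_event_sum(d_over_S2)
        w_sorted = ex * C - (ex ** 2) * C2
        w_sorted = np.maximum(w_sorted, _W_FLOOR)
        g_sorted = -(self.d_sorted - ex * C)  # n * d(nll/n)/d eta
        z_sorted = es - g_sorted / w_sorted
        w = np.empty_like(w_sorted)
        z = np.empty_like(z_sorted)
        w[self.order] = w_sorted
        z[self.order] = z_sorted
        return w, z

    def _cum_event_sum(self, per_event):
        """For each sorted subject k: sum of per_event over event times <= t_k."""
        cs = np.concatenate([[0.0], np.cumsum(per_event)])
        pos = np.searchsorted(self.event_times, self.t_sorted, side="right")
        return cs[pos]

    def baseline_cumhaz(self, eta):
        """Breslow baseline cumulative hazard: times and H0 at each event time."""
        _, _, S = self._risk_terms(eta)
        return self.event_times, np.cumsum(self.event_counts / S)


# ---------------------------------------------------------------------------


def loss(family, X, out: Outcome, beta, b0, bindex: BreslowIndex = None):
    """Value of the smooth (unpenalized) loss at (b0, beta)."""
    n = X.shape[0]
    eta = X @ beta + b0
    if family == "gaussian":
        return 0.5 * np.sum((out.y - eta) ** 2) / n
    if family == "binomial":
        # log(1+e^eta) - y*eta, computed stably
        return np.sum(np.logaddexp(0.0, eta) - out.y * eta) / n
    if family == "cox":
        if bindex is None:
            bindex = BreslowIndex(out.time, out.status)
        return -bindex.loglik(X @ beta) / n
    raise ValueError(family)


def gradient(family, X, out: Outcome, beta, b0, bindex: BreslowIndex = None):
    """Gradient of the smooth loss wrt beta (and b0) -> (g_beta, g_b0)."""
    n = X.shape[0]
    if family == "cox":
        if bindex is None:
            bindex = BreslowIndex(out.time, out.status)
        ge = bindex.grad_eta(X @ beta) / n
        return X.T @ ge, 0.0
    eta = X @ beta + b0
    if family == "gaussian":
        r = eta - out.y
    elif family == "binomial":
        r = _sigmoid(eta) - out.y
    else:
        raise ValueError(family)
    r = r / n
    return X.T @ r, r.sum()


def null_intercept(family, out: Outcome):
    """Intercept of the null (coefficient-free) model."""
    if family == "gaussian":
        return float(np.mean(out.y))
    if family == "binomial":
        pbar = float(np.mean(out.y))
        pbar = min(max(pbar, _P_EPS), 1 - _P_EPS)
        return float(np.log(pbar / (1 - pbar)))
    return 0.0


def binomial_working(y, eta):
    """Working weights/response for one IRLS step of the logistic loss."""
    p = _sigmoid(eta)
    p = np.clip(p, _P_EPS, 1 - _P_EPS)
    w = np.maximum(p * (1 - p), _W_FLOOR)
    z = eta + (y - p) / w
    return w, z
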