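import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ipflasso as ipf
from ipflasso.objectives import gradient, loss

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def random_instance(family, n, p, rng, signal=2):
    """Small random regression instance with a few true effects."""
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    k = min(signal, p)
    beta[rng.choice(p, size=k, replace=False)] = rng.normal(0, 1.2, size=k)
    eta = X @ beta
    if family == "gaussian":
        out = ipf.Outcome.gaussian(eta + rng.standard_normal(n))
    elif family == "binomial":
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        if y.min() == y.max():  # force both classes
            y[0], y[1] = 0.0, 1.0
        out = ipf.Outcome.binomial(y)
    else:
        time = rng.exponential(np.exp(-eta / 3)) + 1e-3
        status = (rng.random(n) < 0.7).astype(float)
        if status.sum() == 0:
            status[0] = 1.0
        out = ipf.Outcome.cox(time, status)
    return X, out


def proximal_weighted_lasso(X, out, pen, lam, n_iter=50_000, tol=1e-12):
    """Independent proximal-gradient (ISTA) minimizer of
    loss(b0, beta) + lam * sum_j pen_j |beta_j| on the given (raw) matrix.

    Deliberately naive: fixed backtracked step, no screening, no warm
    start; used as an oracle for the coordinate-descent solver.
    """
    n, p = X.shape
    beta = np.zeros(p)
    fit_intercept = out.family != "cox"
    b0 = 0.0
    t = 1.0
    prev = np.inf
    for _ in range(n_iter):
        g, g0 = gradient(out.family, X, out, beta, b0)
        f0 = loss(out.family, X, out, beta, b0)
        while True:
            step = beta - t * g
            cand = np.sign(step) * np.maximum(np.abs(step) - t * lam * pen, 0.0)
            cand0 = b0 - t * g0 if fit_intercept else 0.0
            d, d0 = cand - beta, cand0 - b0
            if loss(out.family, X, out, cand, cand0) <= (
                f0 + g @ d + g0 * d0 + (d @ d + d0 * d0) / (2 * t) + 1e-15
            ):
                break
            t *= 0.5
        beta, b0 = cand, cand0
        obj = loss(out.family, X, out, beta, b0) + lam * np.sum(pen * np.abs(beta))
        if prev - obj < tol:
            break
        prev = obj
        t = min(t * 1.5, 1e3)
    return beta, b0


def kkt_violation(X, out, beta, b0, lam, pen):
    """Max violation of the weighted-L1 subgradient conditions at (b0, beta)."""
    g, g0 = gradient(out.family, X, out, beta, b0)
    viol = abs(g0) if out.family != "cox" else 0.0
    nz = beta != 0
    if nz.any():
        viol = max(viol, float(np.max(np.abs(g[nz] + lam * pen[nz] * np.sign(beta[nz])))))
    z = (~nz) & np.isfinite(pen)
    if z.any():
        viol = max(viol, float(np.max(np.abs(g[z]) - lam * pen[z])))
    return viol


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
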