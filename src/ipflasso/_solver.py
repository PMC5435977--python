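"""Coordinate-descent kernel for penalized weighted least squares.

This is the inner engine shared by all three families: the gaussian loss
is solved directly, while logistic and Cox fits wrap it in an outer
iteratively-reweighted least-squares loop that supplies working weights
and a working response.

The kernel minimises, over (b0, beta),

    (1/(2n)) * sum_i w_i (z_i - b0 - x_i . beta)^2  +  lam * sum_j v_j |beta_j|

for a fixed per-feature penalty-weight vector v, restricted to the
candidate feature set ``feat_idx`` (the path driver screens features with
the sequential strong rule and verifies the full KKT conditions
afterwards).  Columns with v_j = inf or zero weighted variance are held
at beta_j = 0.  Convergence is declared when the largest single-
coefficient change in a sweep drops below ``tol``; full sweeps over the
candidate set alternate with cheap sweeps over the currently nonzero set.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def soft_threshold_kernel(z, gamma):
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


@njit(cache=True)
def _sweep(X, w, r, beta, denom, pen, lam, n, idx):
    """One coordinate sweep over the columns listed in idx; returns max change."""
    maxd = 0.0
    for k in range(idx.size):
        j = idx[k]
        d = denom[j]
        if d <= 0.0:
            continue
        pj = pen[j]
        if pj == np.inf:
            continue
        bj = beta[j]
        rho = 0.0
        for i in range(X.shape[0]):
            rho += w[i] * X[i, j] * r[i]
        rho = rho / n + d * bj
        new = soft_threshold_kernel(rho, lam * pj) / d
        if new != bj:
            delta = new - bj
            for i in range(X.shape[0]):
                r[i] -= delta * X[i, j]
            beta[j] = new
            ad = abs(delta)
            if ad > maxd:
                maxd = ad
    return maxd


@njit(cache=True)
def _intercept_step(w, r, wsum):
    db0 = 0.0
    for i in range(r.size):
        db0 += w[i] * r[i]
    db0 /= wsum
    if db0 != 0.0:
        for i in range(r.size):
            r[i] -= db0
    return db0


@njit(cache=True)
def cd_wls(X, w, r, beta, pen, lam, fit_intercept, tol, max_cycles, feat_idx):
    """Solve the penalized WLS problem on the candidate set.

    ``r`` must equal z - b0 - X @ beta on entry and is updated in place;
    ``beta`` is updated in place.  Returns (db0, n_cycles, converged)
    where db0 is the accumulated intercept shift.
    """
    n = X.shape[0]
    nf = float(n)
    wsum = 0.0
    for i in range(n):
        wsum += w[i]

    denom = np.zeros(X.shape[1])
    for k in range(feat_idx.size):
        j = feat_idx[k]
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        denom[j] = s / nf

    db0_total = 0.0
    cycles = 0
    converged = False
    while cycles < max_cycles:
        maxd = _sweep(X, w, r, beta, denom, pen, lam, nf, feat_idx)
        if fit_intercept and wsum > 0.0:
            db0 = _intercept_step(w, r, wsum)
            db0_total += db0
            if abs(db0) > maxd:
                maxd = abs(db0)
        cycles += 1
        # tolerance is relative to the largest coefficient once that
        # exceeds 1 (keeps the criterion meaningful near saturation)
        bmax = 1.0
        for k in range(feat_idx.size):
            ab = abs(beta[feat_idx[k]])
            if ab > bmax:
                bmax = ab
        if maxd < tol * bmax:
            converged = True
            break
        # sweeps over the nonzero subset only
        nact = 0
        for k in range(feat_idx.size):
            if beta[feat_idx[k]] != 0.0:
                nact += 1
        active = np.empty(nact, dtype=np.int64)
        a = 0
        for k in range(feat_idx.size):
            j = feat_idx[k]
            if beta[j] != 0.0:
                active[a] = j
                a += 1
        while cycles < max_cycles:
            maxd = _sweep(X, w, r, beta, denom, pen, lam, nf, active)
            if fit_intercept and wsum > 0.0:
                db0 = _intercept_step(w, r, wsum)
                db0_total += db0
                if abs(db0) > maxd:
                    maxd = abs(db0)
            cycles += 1
            bmax = 1.0
            for k in range(active.size):
                ab = abs(beta[active[k]])
                if ab > bmax:
                    bmax = ab
            if maxd < tol * bmax:
                break
    return db0_total, cycles, converged


@njit(cache=True)
def _grad_full(X, resid, g):
    n, p = X.shape
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * resid[i]
        g[j] = s / n


@njit(cache=True)
def lasso_path_glm(X, y, pen, grid, tol, max_cycles, binomial):
    """Full gaussian/logistic path with strong-rule screening, in one pass.

    Per lambda: screen features with the sequential strong rule at the
    warm start, solve (IRLS +) coordinate descent on the candidate set,
    then verify the KKT conditions over all features and re-solve with
    any violators added.  Returns (betas, b0s, bad_lambda, irls_capped)
    where bad_lambda is the first lambda index at which coordinate
    descent failed to converge (-1 if none).
    """
    n, p = X.shape
    L = grid.size
    betas = np.zeros((L, p))
    b0s = np.zeros(L)
    beta = np.zeros(p)
    if binomial:
        pbar = 0.0
        for i in range(n):
            pbar += y[i]
        pbar /= n
        if pbar < 1e-8:
            pbar = 1e-8
        if pbar > 1 - 1e-8:
            pbar = 1 - 1e-8
        b0 = np.log(pbar / (1 - pbar))
    else:
        b0 = y.mean()
    eta = np.full(n, b0)
    g = np.empty(p)
    resid = np.empty(n)
    w = np.ones(n)
    z = y.copy()
    cand_mask = np.zeros(p, dtype=np.bool_)
    bad_lambda = -1
    irls_capped = 0
    lam_prev = grid[0]

    # null deviance, for the saturation stop (freeze the path once the fit
    # explains >99.9% of it -- the quasi-separated / interpolating regime)
    nulldev = 0.0
    if binomial:
        for i in range(n):
            nulldev += np.logaddexp(0.0, b0) - y[i] * b0
    else:
        ybar = y.mean()
        for i in range(n):
            nulldev += 0.5 * (y[i] - ybar) ** 2
    nulldev = max(nulldev, 1e-300)

    for li in range(L):
        lam = grid[li]
        if binomial:
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                resid[i] = pi - y[i]
        else:
            for i in range(n):
                resid[i] = eta[i] - y[i]
        _grad_full(X, resid, g)
        thr = (2.0 * lam - lam_prev) * (1.0 - 1e-9)
        for j in range(p):
            cand_mask[j] = (pen[j] != np.inf) and (
                (beta[j] != 0.0) or (abs(g[j]) >= pen[j] * thr)
            )
        for _pass in range(p + 1):
            cand = np.flatnonzero(cand_mask)
            if binomial:
                for it in range(100):
                    for i in range(n):
                        pi = 1.0 / (1.0 + np.exp(-eta[i]))
                        if pi < 1e-8:
                            pi = 1e-8
                        if pi > 1 - 1e-8:
                            pi = 1 - 1e-8
                        wi = pi * (1 - pi)
                        if wi < 1e-5:
                            wi = 1e-5
                        w[i] = wi
                        z[i] = eta[i] + (y[i] - pi) / wi
                        resid[i] = z[i] - eta[i]
                    old_b0 = b0
                    old = np.empty(cand.size)
                    for k in range(cand.size):
                        old[k] = beta[cand[k]]
                    db0, cycles, ok = cd_wls(
                        X, w, resid, beta, pen, lam, True, tol, max_cycles, cand
                    )
                    b0 += db0
                    for i in range(n):
                        eta[i] = z[i] - resid[i]
                    if not ok:
                        bad_lambda = li
                        break
                    maxd = abs(b0 - old_b0)
                    bmax = 1.0
                    for k in range(cand.size):
                        d = abs(beta[cand[k]] - old[k])
                        if d > maxd:
                            maxd = d
                        ab = abs(beta[cand[k]])
                        if ab > bmax:
                            bmax = ab
                    if maxd < 10.0 * tol * bmax:
                        break
                else:
                    irls_capped += 1
                for i in range(n):
                    pi = 1.0 / (1.0 + np.exp(-eta[i]))
                    resid[i] = pi - y[i]
            else:
                for i in range(n):
                    resid[i] = y[i] - eta[i]
                db0, cycles, ok = cd_wls(
                    X, w, resid, beta, pen, lam, True, tol, max_cycles, cand
                )
                b0 += db0
                for i in range(n):
                    eta[i] = y[i] - resid[i]
                if not ok:
                    bad_lambda = li
                for i in range(n):
                    resid[i] = eta[i] - y[i]
            if bad_lambda >= 0:
                break
            _grad_full(X, resid, g)
            newviol = False
            kkt_lim = lam * (1.0 + 1e-9)
            for j in range(p):
                if (not cand_mask[j]) and pen[j] != np.inf:
                    if abs(g[j]) > kkt_lim * pen[j] + 1e-12:
                        cand_mask[j] = True
                        newviol = True
            if not newviol:
                break
        if bad_lambda >= 0:
            break
        for j in range(p):
            betas[li, j] = beta[j]
        b0s[li] = b0
        lam_prev = lam
        dev = 0.0
        if binomial:
            for i in range(n):
                dev += np.logaddexp(0.0, eta[i]) - y[i] * eta[i]
        else:
            for i in range(n):
                dev += 0.5 * (y[i] - eta[i]) ** 2
        if dev < 1e-3 * nulldev:
            for lj in range(li + 1, L):
                for j in range(p):
                    betas[lj, j] = beta[j]
                b0s[lj] = b0
            break
    return betas, b0s, bad_lambda, irls_capped
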