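"""Weighted-L1 penalized estimation for linear, logistic and Cox models.

The central objective, for a predictor matrix partitioned into M
modalities (blocks) with penalty parameters lam_m = lam1 * pf_m, is

    loss(b0, beta) + sum_m lam_m * ||beta^(m)||_1

which reduces to a single-lambda problem with per-feature penalty weights
w_j = pf_m for column j in block m.  Penalty factors are therefore applied
inside the coordinate-descent solver as per-feature weights; the
mathematically equivalent route of dividing each column by its factor,
fitting a uniform-penalty LASSO and dividing the estimates back
(:func:`rescale_design`) is retained as an independent cross-check.

Columns are internally centered and scaled to unit variance (divisor n)
before penalization; coefficients are reported back on the original
scale.  The intercept (gaussian/binomial) is never penalized; the Cox
model has none.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._solver import cd_wls, lasso_path_glm
from .blocks import BlockStructure, PenaltyFactors
from .data import DesignMatrix, Outcome, as_matrix
from .objectives import BreslowIndex, null_intercept, gradient, _sigmoid

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-7
DEFAULT_MAX_CYCLES = 100_000


class ConvergenceError(RuntimeError):
    """Raised when coordinate descent fails to converge.

    Carries the last iterate and the index of the offending lambda.
    """

    def __init__(self, msg, beta=None, lambda_index=None):
        super().__init__(msg)
        self.beta = beta
        self.lambda_index = lambda_index


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0); the scalar L1 proximal operator."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


# ---------------------------------------------------------------------------
# standardization


@dataclass(frozen=True)
class Standardization:
    mean: np.ndarray
    scale: np.ndarray          # population sd (divisor n); 0 for constant columns
    excluded: np.ndarray       # boolean mask of zero-variance columns

    @classmethod
    def identity(cls, p):
        return cls(np.zeros(p), np.ones(p), np.zeros(p, dtype=bool))


def standardize_columns(X: np.ndarray):
    """Center and scale to unit variance (divisor n); flag constant columns."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0)  # ddof=0 -> divisor n
    excluded = scale == 0
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} zero-variance column(s) excluded from penalized fit",
            stacklevel=2,
        )
        logger.warning("%d zero-variance column(s) excluded", int(excluded.sum()))
    safe = np.where(excluded, 1.0, scale)
    Xs = (X - mean) / safe
    Xs[:, excluded] = 0.0
    return np.asfortranarray(Xs), Standardization(mean, scale, excluded)


# ---------------------------------------------------------------------------
# path container


@dataclass
class PathFit:
    """Solution path of a weighted-L1 fit over a decreasing lambda grid.

    ``coef_`` holds coefficients on the ORIGINAL predictor scale
    (grid_length x p); ``intercept_`` is all zeros for the Cox family.
    """

    family: str
    lambdas: np.ndarray
    coef_: np.ndarray
    intercept_: np.ndarray
    penalty_weights: np.ndarray
    blocks: BlockStructure = None
    penalty_factors: PenaltyFactors = None
    feature_names: tuple = None
    baseline_times: np.ndarray = None      # cox only: unique event times
    baseline_cumhaz_: np.ndarray = None    # cox only: grid_length x n_event_times

    @property
    def n_lambdas(self) -> int:
        return self.lambdas.size

    @property
    def p(self) -> int:
        return self.coef_.shape[1]

    def df(self) -> np.ndarray:
        """Number of nonzero coefficients at each lambda."""
        return np.count_nonzero(self.coef_, axis=1)

    def df_by_block(self) -> np.ndarray:
        """grid_length x M matrix of per-block nonzero counts."""
        if self.blocks is None:
            raise ValueError("fit has no block structure")
        return np.stack(
            [np.count_nonzero(self.coef_[:, b], axis=1) for b in self.blocks.blocks], axis=1
        )

    def coef_at(self, lambda_index: int) -> np.ndarray:
        return self.coef_[lambda_index]


# ---------------------------------------------------------------------------
# lambda grid


def lambda_max(X, out: Outcome, penalty_weights, *, standardize: bool = True) -> float:
    """Smallest lambda at which every penalized coefficient is zero.

    Computed as max_j |g_j| / w_j with g the gradient of the unpenalized
    loss at the null model (intercept-only; eta = 0 for Cox).
    """
    X = as_matrix(X)
    out.check_fittable()
    w = np.asarray(penalty_weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("penalty weights must be positive")
    if standardize:
        Xs, st = standardize_columns(X)
    else:
        Xs, st = X, Standardization.identity(X.shape[1])
    b0 = null_intercept(out.family, out)
    g, _ = gradient(out.family, Xs, out, np.zeros(X.shape[1]), b0)
    keep = ~st.excluded
    if not keep.any():
        raise ValueError("all columns have zero variance")
    return float(np.max(np.abs(g[keep]) / w[keep]))


def default_grid(lmax: float, n: int, p: int, nlambda: int = 100, min_ratio: float = None):
    """Log-spaced grid from lambda_max down to min_ratio * lambda_max."""
    if min_ratio is None:
        min_ratio = 0.01 if p > n else 1e-4
    # nudge the anchor up so the all-zero solution holds exactly at the top
    # of the grid despite rounding in max_j |g_j| / w_j
    lmax = lmax * (1 + 1e-8)
    return np.geomspace(lmax, lmax * min_ratio, nlambda)


# ---------------------------------------------------------------------------
# fitting


def _fit_path_standardized(Xs, out, pen, grid, tol, max_cycles, family):
    """Solve the path on an already-standardized matrix; returns std-scale betas.

    Features are screened per lambda with the sequential strong rule
    |g_j| >= v_j * (2*lam - lam_prev) evaluated at the warm start; the
    full KKT conditions are then verified on the remaining features and
    any violators are added back and the problem re-solved.
    """
    n, p = Xs.shape
    if family in ("gaussian", "binomial"):
        betas, b0s, bad, irls_capped = lasso_path_glm(
            Xs, np.ascontiguousarray(out.y, dtype=float), pen, grid, tol,
            max_cycles, family == "binomial",
        )
        if bad >= 0:
            raise ConvergenceError(
                f"coordinate descent did not converge at lambda index {bad}",
                beta=betas[max(bad - 1, 0)].copy(), lambda_index=int(bad),
            )
        if irls_capped:
            # arises under quasi-separation at small lambda, where the
            # quadratic approximation stalls; the last iterate is kept
            warnings.warn(
                f"IRLS stopped at iteration cap for {irls_capped} lambda value(s)",
                stacklevel=2,
            )
        return betas, b0s

    betas = np.zeros((grid.size, p))
    b0s = np.zeros(grid.size)
    beta = np.zeros(p)
    fit_intercept = False
    b0 = 0.0
    bindex = BreslowIndex(out.time, out.status)
    finite_pen = np.isfinite(pen)

    def sparse_eta():
        nz = np.flatnonzero(beta)
        return Xs[:, nz] @ beta[nz] if nz.size else np.zeros(n)

    def full_gradient():
        return Xs.T @ (bindex.grad_eta(sparse_eta()) / n)

    def solve_on(lam, cand, li):
        # IRLS outer loop around the weighted-least-squares kernel
        for _ in range(100):
            w, z = bindex.working(sparse_eta())
            r = z - sparse_eta()
            old = beta[cand].copy()
            _, cycles, ok = cd_wls(Xs, w, r, beta, pen, lam, False,
                                   tol, max_cycles, cand)
            if not ok:
                raise ConvergenceError(
                    f"coordinate descent did not converge at lambda index {li}",
                    beta=beta.copy(), lambda_index=li,
                )
            bmax = max(1.0, np.max(np.abs(beta[cand]), initial=0.0))
            if np.max(np.abs(beta[cand] - old), initial=0.0) < 10 * tol * bmax:
                return
        warnings.warn(
            f"IRLS stopped at iteration cap (lambda index {li}); keeping last iterate",
            stacklevel=2,
        )

    null_nll = max(-bindex.loglik(np.zeros(n)), 1e-300)
    lam_prev = grid[0]
    for li, lam in enumerate(grid):
        g = full_gradient()
        strong = np.abs(g) >= pen * (2 * lam - lam_prev) * (1 - 1e-9)
        cand_mask = (strong | (beta != 0)) & finite_pen
        for _ in range(1 + p):
            cand = np.flatnonzero(cand_mask)
            solve_on(lam, cand, li)
            g = full_gradient()
            viol = (~cand_mask) & finite_pen & (np.abs(g) > lam * pen * (1 + 1e-9) + 1e-12)
            if not viol.any():
                break
            cand_mask |= viol
        betas[li] = beta
        lam_prev = lam
        # saturation stop, as for the other families
        if -bindex.loglik(sparse_eta()) < 1e-3 * null_nll:
            betas[li + 1 :] = beta
            break
    return betas, b0s


def fit_weighted_lasso_path(
    X,
    out: Outcome,
    penalty_weights,
    grid=None,
    *,
    nlambda: int = 100,
    lambda_min_ratio: float = None,
    standardize: bool = True,
    tol: float = DEFAULT_TOL,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    blocks: BlockStructure = None,
    penalty_factors: PenaltyFactors = None,
) -> PathFit:
    """Fit the per-feature weighted L1 path for any of the three families.

    ``penalty_weights`` is the length-p positive vector v with penalty
    lam * sum_j v_j |beta_j|; warm starts are used along the (strictly
    decreasing) grid.
    """
    names = X.feature_names if isinstance(X, DesignMatrix) else None
    X = as_matrix(X)
    out.check_fittable()
    n, p = X.shape
    pen = np.asarray(penalty_weights, dtype=float).copy()
    if pen.shape != (p,):
        raise ValueError("penalty_weights must have length p")
    if np.any(pen <= 0):
        raise ValueError("penalty weights must be positive")

    if standardize:
        Xs, st = standardize_columns(X)
    else:
        Xs, st = np.asfortranarray(X), Standardization.identity(p)
    pen = np.where(st.excluded, np.inf, pen)

    if grid is None:
        b0 = null_intercept(out.family, out)
        g, _ = gradient(out.family, Xs, out, np.zeros(p), b0)
        keep = ~st.excluded
        lmax = float(np.max(np.abs(g[keep]) / pen[keep]))
        grid = default_grid(lmax, n, p, nlambda, lambda_min_ratio)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("grid must be a non-empty vector")
        if grid.size > 1 and np.any(np.diff(grid) >= 0):
            raise ValueError("grid must be strictly decreasing")

    betas_std, b0_std = _fit_path_standardized(
        Xs, out, pen, grid, tol, max_cycles, out.family
    )

    # back-transform to the original scale
    safe = np.where(st.excluded, 1.0, st.scale)
    coef = betas_std / safe
    coef[:, st.excluded] = 0.0
    if out.family == "cox":
        intercept = np.zeros(grid.size)
    else:
        intercept = b0_std - coef @ st.mean

    fit = PathFit(
        family=out.family,
        lambdas=grid,
        coef_=coef,
        intercept_=intercept,
        penalty_weights=pen,
        blocks=blocks,
        penalty_factors=penalty_factors,
        feature_names=names,
    )
    if out.family == "cox":
        bindex = BreslowIndex(out.time, out.status)
        H = np.empty((grid.size, bindex.event_times.size))
        for li in range(grid.size):
            _, H[li] = bindex.baseline_cumhaz(X @ coef[li])
        fit.baseline_times = bindex.event_times
        fit.baseline_cumhaz_ = H
    return fit


def rescale_design(X, blocks: BlockStructure, pf: PenaltyFactors):
    """Divide each column by its modality's penalty factor (canonical form).

    Fitting the rescaled matrix with a uniform penalty and dividing the
    estimates back by the factors reproduces the weighted fit exactly.
    """
    X = as_matrix(X)
    w = pf.per_feature(blocks)
    return X / w


def fit_ipf_lasso(
    X,
    out: Outcome,
    blocks: BlockStructure,
    pf: PenaltyFactors,
    grid=None,
    **kwargs,
) -> PathFit:
    """Weighted-L1 fit with one penalty factor per modality.

    The factor vector is canonicalized first (divided by its first entry),
    so multiplying it by any positive scalar leaves the fit unchanged.
    """
    pfc = pf.canonical()
    pen = pfc.per_feature(blocks)
    return fit_weighted_lasso_path(
        X, out, pen, grid, blocks=blocks, penalty_factors=pfc, **kwargs
    )


def fit_standard_lasso(X, out: Outcome, grid=None, blocks: BlockStructure = None, **kwargs) -> PathFit:
    """Uniform-penalty LASSO: IPF with all penalty factors equal to 1."""
    X_arr = as_matrix(X)
    if blocks is None:
        blocks = BlockStructure.from_sizes([X_arr.shape[1]])
    pf = PenaltyFactors(np.ones(blocks.n_blocks))
    return fit_ipf_lasso(X, out, blocks, pf, grid, **kwargs)


# ---------------------------------------------------------------------------
# prediction


def predict(fit: PathFit, Xnew, lambda_index: int, kind: str = "response"):
    """Predict at one grid point.

    gaussian -> fitted mean; binomial -> probability (or linear predictor
    with kind="link"); cox -> linear predictor (log relative hazard).
    """
    Xnew = as_matrix(Xnew)
    if Xnew.shape[1] != fit.p:
        raise ValueError(f"Xnew has {Xnew.shape[1]} columns, fit expects {fit.p}")
    eta = Xnew @ fit.coef_[lambda_index] + fit.intercept_[lambda_index]
    if fit.family == "binomial" and kind == "response":
        return _sigmoid(eta)
    return eta


def predict_survival(fit: PathFit, Xnew, lambda_index: int, times):
    """Per-subject survival curves S_i(t) = exp(-H0(t) e^{eta_i}) (Breslow).

    Returns an n_new x len(times) matrix; H0 is the step-function baseline
    cumulative hazard from the training fit.
    """
    if fit.family != "cox":
        raise ValueError("survival curves are defined for the cox family only")
    Xnew = as_matrix(Xnew)
    times = np.asarray(times, dtype=float)
    eta = predict(fit, Xnew, lambda_index)
    H = fit.baseline_cumhaz_[lambda_index]
    cs = np.concatenate([[0.0], H])
    pos = np.searchsorted(fit.baseline_times, times, side="right")
    H_at = cs[pos]
    return np.exp(-np.outer(np.exp(eta), H_at))
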