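"""Two-modality Gaussian mixture simulator and the benchmark runner.

Data-generating model: a binary class y ~ Bernoulli(tau); given the
class, the p1 + p2 predictors are multivariate normal with common
covariance Sigma and class-1 mean shift

    mu = (beta1 x p1r, 0 ..., beta2 x p2r, 0 ...),

i.e. the first p1r columns of modality 1 and the first p2r columns of
modality 2 are the truly relevant variables.  Sigma is the identity in
the main settings; the correlated variants use a block covariance with b
correlation groups per modality (within-group correlation rho, plus
cross-modality correlation rho between paired groups), after which the
columns of each modality are randomly permuted so the relevant variables
scatter over the groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import BlockStructure, pow2_candidates
from .comparators import SglConfig, cv_sgl, cv_standard_lasso, fit_separate_S
from .cv import make_folds, select_penalty_factors
from .core import predict
from .data import Outcome
from .metrics import auc, misclassification_rate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationSetting:
    """One row of the benchmark design grid."""

    name: str
    p1: int
    p2: int
    p1r: int
    p2r: int
    beta1: float
    beta2: float
    n: int = 100
    tau: float = 0.5
    correlated: bool = False
    rho: float = 0.4
    b: int = 10
    n_test: int = 5000

    def __post_init__(self):
        if not (0 <= self.p1r <= self.p1 and 0 <= self.p2r <= self.p2):
            raise ValueError("relevant counts must not exceed modality sizes")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie strictly between 0 and 1")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.correlated and (self.p1 % self.b or self.p2 % self.b):
            raise ValueError("b must divide p1 and p2 in correlated settings")

    @property
    def p(self) -> int:
        return self.p1 + self.p2

    def mean_vector(self) -> np.ndarray:
        mu = np.zeros(self.p)
        mu[: self.p1r] = self.beta1
        mu[self.p1 : self.p1 + self.p2r] = self.beta2
        return mu


#: main design grid: (p1, p2, p1r, p2r, beta1, beta2)
_MAIN_SETTINGS = {
    "A": (1000, 1000, 10, 10, 0.5, 0.5),
    "B": (100, 1000, 3, 30, 0.5, 0.5),
    "C": (100, 1000, 10, 10, 0.5, 0.5),
    "D": (100, 1000, 20, 0, 0.3, 0.0),
    "E": (20, 1000, 3, 10, 1.0, 0.3),
    "F": (20, 1000, 15, 3, 0.5, 0.5),
}


def setting_params(name: str) -> SimulationSetting:
    """Look up a named setting; a prime/apostrophe suffix marks the
    correlated variant (rho = 0.4, b = 10 correlation groups)."""
    base = name.rstrip("'′")
    correlated = base != name
    if base not in _MAIN_SETTINGS:
        valid = sorted(_MAIN_SETTINGS) + [s + "'" for s in sorted(_MAIN_SETTINGS)]
        raise ValueError(f"unknown setting {name!r}; valid names: {valid}")
    p1, p2, p1r, p2r, b1, b2 = _MAIN_SETTINGS[base]
    return SimulationSetting(
        name=name, p1=p1, p2=p2, p1r=p1r, p2r=p2r, beta1=b1, beta2=b2,
        correlated=correlated,
    )


def build_covariance(p1: int, p2: int, b: int, rho: float) -> np.ndarray:
    """Block covariance: b within-modality correlation groups per modality,
    with the j-th groups of the two modalities mutually correlated.

    Within-modality group blocks have ones on the diagonal and rho off it;
    the paired cross-modality blocks are constant rho; everything else 0.
    """
    if p1 % b or p2 % b:
        raise ValueError("b must divide both modality sizes")
    q1, q2 = p1 // b, p2 // b
    p = p1 + p2
    S = np.zeros((p, p))
    for j in range(b):
        s1 = slice(j * q1, (j + 1) * q1)
        s2 = slice(p1 + j * q2, p1 + (j + 1) * q2)
        S[s1, s1] = rho
        S[s2, s2] = rho
        S[s1, s2] = rho
        S[s2, s1] = rho
    np.fill_diagonal(S, 1.0)
    evmin = float(np.linalg.eigvalsh(S).min())
    if evmin <= 0:
        raise ValueError(f"covariance not positive definite (min eigenvalue {evmin:.3e})")
    return S


@dataclass
class SimulatedDataset:
    X: np.ndarray
    y: np.ndarray
    blocks: BlockStructure
    truth_idx: np.ndarray     # column indices of the relevant variables
    truth_effects: np.ndarray
    setting: SimulationSetting


def generate_dataset(setting: SimulationSetting, seed, n: int = None) -> SimulatedDataset:
    """Draw one dataset; deterministic given the seed.

    In correlated settings the columns of each modality are permuted
    (freshly per dataset) after sampling, and the truth indices follow the
    permutation.
    """
    rng = np.random.default_rng(seed)
    n = n if n is not None else setting.n
    p1, p2, p = setting.p1, setting.p2, setting.p
    y = (rng.random(n) < setting.tau).astype(float)
    mu = setting.mean_vector()
    Z = rng.standard_normal((n, p))
    if setting.correlated:
        S = build_covariance(p1, p2, setting.b, setting.rho)
        L = np.linalg.cholesky(S)
        X = Z @ L.T
    else:
        X = Z
    X += np.outer(y, mu)
    truth_idx = np.flatnonzero(mu)
    truth_effects = mu[truth_idx]
    if setting.correlated:
        perm1 = rng.permutation(p1)
        perm2 = p1 + rng.permutation(p2)
        perm = np.concatenate([perm1, perm2])
        X = X[:, perm]
        inv = np.empty(p, dtype=np.intp)
        inv[perm] = np.arange(p)
        truth_idx = inv[truth_idx]
        order = np.argsort(truth_idx)
        truth_idx = truth_idx[order]
        truth_effects = truth_effects[order]
    return SimulatedDataset(
        X=X,
        y=y,
        blocks=BlockStructure.from_sizes([p1, p2]),
        truth_idx=truth_idx,
        truth_effects=truth_effects,
        setting=setting,
    )


# ---------------------------------------------------------------------------
# experiment runner


ALL_METHODS = ("ipf", "lasso", "separate", "sgl")


def run_experiment(
    setting: SimulationSetting,
    B: int = 20,
    methods=("ipf", "lasso", "separate", "sgl"),
    seed: int = 0,
    nlambda: int = 50,
    nfolds: int = 5,
    ncv: int = 10,
    metric: str = "misclassification",
    sgl_alpha: float = 0.95,
    n_test: int = None,
    tol: float = 1e-5,
):
    """Replicate the benchmark: B training draws, one test draw each.

    Per replicate every requested method is tuned with its protocol (IPF:
    7-candidate (1, 2^k) grid, repeated 5x10 CV on the misclassification
    rate; standard LASSO: the single (1,1) candidate, same CV; method S:
    per-modality CV'd LASSO + logistic combiner; SGL: alpha = 0.95,
    plain 5-fold CV) and evaluated on an independent test set.

    Returns (replicates, summary) DataFrames: per-replicate metric rows
    and per-method medians/quartiles.  Replicate r uses seed ``seed + r``
    with disjoint substreams for the training and test draws.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    n_test = n_test if n_test is not None else setting.n_test
    candidates = pow2_candidates()
    rows = []
    failures = 0
    for r in range(B):
        rep_seed = seed + r
        ss = np.random.SeedSequence(rep_seed)
        train_seed, test_seed, fold_seed = ss.spawn(3)
        data = generate_dataset(setting, train_seed)
        test = generate_dataset(setting, test_seed, n=n_test)
        out = Outcome.binomial(data.y)
        out_test = Outcome.binomial(test.y)
        fold_seed_int = int(fold_seed.generate_state(1)[0] % (2**31))
        try:
            rows.extend(
                _run_replicate(
                    r, data, out, test, out_test, methods, candidates,
                    nlambda, nfolds, ncv, metric, sgl_alpha, fold_seed_int, tol,
                )
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures += 1
            logger.warning("replicate %d failed: %s", r, exc)
            if failures > 0.2 * B:
                raise RuntimeError(
                    f"{failures} of {r + 1} replicates failed; aborting"
                ) from exc
    replicates = pd.DataFrame(rows)
    summary = (
        replicates.groupby(["method", "metric"])["value"]
        .agg(median="median", q1=lambda v: v.quantile(0.25), q3=lambda v: v.quantile(0.75))
        .reset_index()
    )
    return replicates, summary


def _run_replicate(r, data, out, test, out_test, methods, candidates,
                   nlambda, nfolds, ncv, metric, sgl_alpha, fold_seed, tol):
    rows = []
    X, blocks = data.X, data.blocks
    folds = make_folds(X.shape[0], nfolds, ncv, seed=fold_seed, strata=out.y)

    def record(method, prob, n_sel, extra=None):
        rows.append(dict(replicate=r, method=method, metric="misclassification",
                         value=misclassification_rate(prob, out_test.y)))
        rows.append(dict(replicate=r, method=method, metric="auc",
                         value=auc(prob, out_test.y)))
        rows.append(dict(replicate=r, method=method, metric="n_selected",
                         value=float(n_sel)))
        for k, v in (extra or {}).items():
            rows.append(dict(replicate=r, method=method, metric=k, value=float(v)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if "ipf" in methods:
            res = select_penalty_factors(
                X, out, blocks, candidates, folds, metric,
                grid_policy=dict(nlambda=nlambda, tol=tol),
            )
            prob = predict(res.fit, test.X, res.lambda_index)
            record("ipf", prob, res.n_selected,
                   {"pf2": res.pf.factors[1], "lambda_opt": res.lambda_opt})
        if "lasso" in methods:
            res = cv_standard_lasso(X, out, folds, metric, blocks=blocks, nlambda=nlambda, tol=tol)
            prob = predict(res.fit, test.X, res.lambda_index)
            record("lasso", prob, res.n_selected)
        if "separate" in methods:
            sfit = fit_separate_S(X, out, blocks, folds, metric, nlambda=nlambda, tol=tol)
            prob = sfit.predict(test.X)
            record("separate", prob, sfit.n_selected)
        if "sgl" in methods:
            res = cv_sgl(X, out, blocks, SglConfig(alpha=sgl_alpha), seed=fold_seed)
            prob = predict(res.fit, test.X, res.lambda_index)
            record("sgl", prob, res.n_selected)
    return rows
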