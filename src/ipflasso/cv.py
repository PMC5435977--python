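"""Repeated k-fold cross-validation for lambda and for penalty factors.

Tuning is two-dimensional: for each candidate penalty-factor vector, the
lambda path is tuned by repeated k-fold CV (default 5 folds x 10 repeats),
and the candidate whose optimal lambda achieves the best mean CV metric
wins.  The same fold plan is reused across candidates (paired design),
which removes between-candidate fold noise from the comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .blocks import BlockStructure, PenaltyFactors
from .core import PathFit, fit_ipf_lasso, predict
from .data import Outcome, as_matrix
from .metrics import MetricSpec, cox_cvpl, default_metric, evaluate_metric

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """Fold labels for repeated k-fold CV; deterministic given the seed."""

    k: int
    repeats: int
    assignments: np.ndarray  # repeats x n integer fold labels in 0..k-1
    seed: int


def make_folds(n, k, repeats=1, seed=0, strata=None) -> FoldPlan:
    """Build a repeated k-fold plan; fold sizes differ by at most one.

    With ``strata`` (e.g. binary class labels) the split is stratified so
    every fold receives its share of each stratum when possible.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=np.intp)
    for r in range(repeats):
        if strata is None:
            labels = np.resize(np.arange(k), n)
            assignments[r] = rng.permutation(labels)
        else:
            strata_arr = np.asarray(strata)
            fold = np.empty(n, dtype=np.intp)
            offset = rng.integers(k)  # rotate fold sizes across strata
            for s in np.unique(strata_arr):
                idx = np.flatnonzero(strata_arr == s)
                labels = (np.arange(idx.size) + offset) % k
                fold[rng.permutation(idx)] = labels
                offset += idx.size
            assignments[r] = fold
    return FoldPlan(k=k, repeats=repeats, assignments=assignments, seed=seed)


@dataclass
class CVResult:
    """Mean/sd CV curve(s) and the selected (penalty factors, lambda) pair."""

    metric: MetricSpec
    lambdas: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lambda_index: int
    pf: PenaltyFactors
    fit: PathFit                      # full-data path for the winning candidate
    n_folds_used: int = 1
    n_skipped_folds: int = 0
    candidate_results: list = field(default_factory=list)
    candidate_index: int = 0

    @property
    def lambda_opt(self) -> float:
        return float(self.lambdas[self.lambda_index])

    @property
    def best_value(self) -> float:
        return float(self.mean[self.lambda_index])

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.fit.coef_[self.lambda_index]))

    def coef_opt(self) -> np.ndarray:
        return self.fit.coef_[self.lambda_index]


def _train_degenerate(out: Outcome) -> bool:
    if out.family == "binomial":
        return np.unique(out.y).size < 2
    if out.family == "cox":
        return out.status.sum() < 1
    return np.ptp(out.y) == 0


def _fold_metric(metric, fold_fit, X, out, train_idx, test_idx):
    """Held-out metric values for every lambda of one fold fit."""
    vals = np.empty(fold_fit.n_lambdas)
    out_test = out.subset(test_idx)
    if metric.name == "cox_cvpl":
        for li in range(fold_fit.n_lambdas):
            vals[li] = cox_cvpl(fold_fit.coef_[li], X, out, train_idx)
        return vals
    X_test = X[test_idx]
    for li in range(fold_fit.n_lambdas):
        pred = predict(fold_fit, X_test, li)
        try:
            vals[li] = evaluate_metric(metric.name, out.family, pred, out_test)
        except ValueError:
            vals[li] = np.nan  # e.g. single-class test fold for AUC
    return vals


def _pick_lambda(metric: MetricSpec, mean, allowed=None) -> int:
    """Index of the best mean value; ties go to the smallest index (largest
    lambda, hence the sparser model)."""
    vals = mean.copy()
    if allowed is not None:
        vals[~allowed] = np.nan
    if np.all(np.isnan(vals)):
        raise ValueError("no admissible lambda")
    if metric.direction == "maximize":
        best = np.nanmax(vals)
    else:
        best = np.nanmin(vals)
    return int(np.flatnonzero(vals == best)[0])


def cv_curve(
    X,
    out: Outcome,
    blocks: BlockStructure,
    pf: PenaltyFactors,
    folds: FoldPlan,
    metric: str = None,
    grid=None,
    **fit_kwargs,
) -> CVResult:
    """Repeated-CV curve over lambda for one fixed penalty-factor vector.

    The grid is anchored at the full-data lambda_max for this pf (unless
    supplied); fold fits reuse it so curves are comparable across folds.
    Degenerate training folds (single class / no events) are skipped with
    a warning; means are over non-skipped folds.
    """
    X = as_matrix(X)
    metric = MetricSpec.for_family(metric or default_metric(out.family), out.family)
    full_fit = fit_ipf_lasso(X, out, blocks, pf, grid, **fit_kwargs)
    grid = full_fit.lambdas

    per_fold = []
    skipped = 0
    for r in range(folds.repeats):
        for f in range(folds.k):
            test_idx = np.flatnonzero(folds.assignments[r] == f)
            train_idx = np.flatnonzero(folds.assignments[r] != f)
            out_train = out.subset(train_idx)
            if _train_degenerate(out_train):
                warnings.warn(f"skipping degenerate training fold (repeat {r}, fold {f})")
                skipped += 1
                continue
            fold_fit = fit_ipf_lasso(X[train_idx], out_train, blocks, pf, grid, **fit_kwargs)
            per_fold.append(_fold_metric(metric, fold_fit, X, out, train_idx, test_idx))
    if not per_fold:
        raise ValueError("all CV folds were degenerate")
    arr = np.asarray(per_fold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
    li = _pick_lambda(metric, mean)
    return CVResult(
        metric=metric, lambdas=grid, mean=mean, sd=sd, lambda_index=li,
        pf=pf.canonical(), fit=full_fit, n_folds_used=len(per_fold),
        n_skipped_folds=skipped,
    )


def select_penalty_factors(
    X,
    out: Outcome,
    blocks: BlockStructure,
    candidates,
    folds: FoldPlan,
    metric: str = None,
    grid_policy: dict = None,
    max_vars: int = None,
    one_se: bool = False,
) -> CVResult:
    """Grid search over candidate penalty-factor vectors.

    Each candidate gets its own lambda grid (anchored at its own
    lambda_max) and a full repeated-CV curve on the shared fold plan; the
    candidate whose optimal lambda attains the best mean metric wins.
    ``max_vars`` restricts each candidate's lambda search to grid points
    whose full-data refit has at most that many nonzero coefficients.
    Ties across candidates are broken toward the lowest candidate index.
    """
    candidates = [c if isinstance(c, PenaltyFactors) else PenaltyFactors(c) for c in candidates]
    if not candidates:
        raise ValueError("need at least one candidate penalty-factor vector")
    fit_kwargs = dict(grid_policy or {})
    mspec = MetricSpec.for_family(metric or default_metric(out.family), out.family)

    results, scores = [], []
    for ci, cand in enumerate(candidates):
        res = cv_curve(X, out, blocks, cand, folds, mspec.name, **fit_kwargs)
        if max_vars is not None:
            allowed = res.fit.df() <= max_vars
            try:
                res.lambda_index = _pick_lambda(mspec, res.mean, allowed)
            except ValueError:
                logger.info("candidate %d: no lambda satisfies max_vars=%d", ci, max_vars)
                results.append(res)
                scores.append(np.nan)
                continue
        if one_se:
            res.lambda_index = _one_se_index(mspec, res)
        results.append(res)
        scores.append(res.mean[res.lambda_index])

    scores = np.asarray(scores, dtype=float)
    if np.all(np.isnan(scores)):
        raise ValueError(
            f"max_vars={max_vars} excludes every lambda for every candidate; "
            "increase the cap"
        )
    if mspec.direction == "maximize":
        best = np.nanmax(scores)
    else:
        best = np.nanmin(scores)
    winner = int(np.flatnonzero(scores == best)[0])
    out_res = results[winner]
    out_res.candidate_results = results
    out_res.candidate_index = winner
    return out_res


def _one_se_index(metric: MetricSpec, res: CVResult) -> int:
    """Largest lambda whose mean is within one SE of the optimum."""
    li = res.lambda_index
    se_opt = res.sd[li] / np.sqrt(max(1, res.n_folds_used))
    if metric.direction == "maximize":
        ok = res.mean >= res.mean[li] - se_opt
    else:
        ok = res.mean <= res.mean[li] + se_opt
    return int(np.flatnonzero(ok)[0])
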