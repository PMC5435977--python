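"""Comparator methods: standard LASSO, separate per-modality models, SGL tuning.

The standard LASSO is the uniform-penalty special case of the weighted
solver (penalty factors all 1).  The "separate models" method S fits one
CV-tuned LASSO per modality, then combines the resulting training linear
predictors in a small unpenalized regression (logistic for a binary
outcome, linear for a continuous one, Cox for survival).  SGL tuning uses
plain 5-fold CV without repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .blocks import BlockStructure, PenaltyFactors
from .core import fit_standard_lasso, predict
from .cv import CVResult, FoldPlan, _pick_lambda, make_folds, select_penalty_factors
from .data import Outcome, as_matrix
from .metrics import MetricSpec, cox_cvpl, evaluate_metric
from .objectives import _sigmoid
from .sgl import SglConfig, fit_sgl

__all__ = [
    "fit_standard_lasso",
    "cv_standard_lasso",
    "SeparateFit",
    "fit_separate_S",
    "cv_sgl",
    "SglConfig",
    "fit_sgl",
]


def cv_standard_lasso(X, out, folds: FoldPlan, metric=None, blocks=None, **kw) -> CVResult:
    """Repeated-CV-tuned uniform-penalty LASSO (single all-ones candidate)."""
    X = as_matrix(X)
    if blocks is None:
        blocks = BlockStructure.from_sizes([X.shape[1]])
    ones = PenaltyFactors(np.ones(blocks.n_blocks))
    return select_penalty_factors(X, out, blocks, [ones], folds, metric, grid_policy=kw)


# ---------------------------------------------------------------------------
# method S: separate per-modality models + combining regression


@dataclass
class SeparateFit:
    """Per-modality CV-tuned LASSO fits plus the combining regression.

    ``combiner_coef`` has one entry per modality (0 for modalities whose
    tuned model was empty and therefore contributed only a constant).
    """

    family: str
    blocks: BlockStructure
    modality_results: list
    combiner_coef: np.ndarray
    combiner_intercept: float
    active: np.ndarray  # modalities with a non-constant linear predictor

    @property
    def n_selected(self) -> int:
        return int(sum(r.n_selected for r in self.modality_results))

    def linear_predictors(self, Xnew) -> np.ndarray:
        """n x M matrix of per-modality linear predictors on new data."""
        Xnew = as_matrix(Xnew)
        cols = []
        for m, res in enumerate(self.modality_results):
            Xm = Xnew[:, self.blocks.blocks[m]]
            cols.append(predict(res.fit, Xm, res.lambda_index, kind="link"))
        return np.column_stack(cols)

    def predict(self, Xnew, kind: str = "response") -> np.ndarray:
        L = self.linear_predictors(Xnew)
        eta = L @ self.combiner_coef + self.combiner_intercept
        if self.family == "binomial" and kind == "response":
            return _sigmoid(eta)
        return eta


def _fit_combiner(family, L, out: Outcome):
    """Unpenalized low-dimensional combining model on the M linear predictors."""
    n, M = L.shape
    active = np.array([np.ptp(L[:, m]) > 0 for m in range(M)])
    coef = np.zeros(M)
    if not active.any():
        if family == "binomial":
            pbar = np.clip(out.y.mean(), 1e-12, 1 - 1e-12)
            return coef, float(np.log(pbar / (1 - pbar))), active
        if family == "gaussian":
            return coef, float(out.y.mean()), active
        return coef, 0.0, active
    La = L[:, active]
    if family == "gaussian":
        from sklearn.linear_model import LinearRegression

        m = LinearRegression().fit(La, out.y)
        coef[active] = m.coef_
        return coef, float(m.intercept_), active
    if family == "binomial":
        from sklearn.linear_model import LogisticRegression

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = LogisticRegression(penalty=None, max_iter=1000).fit(La, out.y)
        coef[active] = m.coef_[0]
        return coef, float(m.intercept_[0]), active
    # cox: unpenalized proportional-hazards fit on the modality predictors
    import pandas as pd
    from lifelines import CoxPHFitter

    df = pd.DataFrame(La, columns=[f"lp{m}" for m in np.flatnonzero(active)])
    df["time"] = out.time
    df["status"] = out.status
    try:
        cph = CoxPHFitter(penalizer=0.0)
        cph.fit(df, duration_col="time", event_col="status")
    except Exception:
        cph = CoxPHFitter(penalizer=1e-6)
        cph.fit(df, duration_col="time", event_col="status")
    coef[active] = cph.params_.to_numpy()
    return coef, 0.0, active


def fit_separate_S(
    X,
    out: Outcome,
    blocks: BlockStructure,
    folds: FoldPlan = None,
    metric=None,
    **fit_kwargs,
) -> SeparateFit:
    """Method S: one CV-tuned standard LASSO per modality, then a combiner.

    The combining regression uses the in-sample (training) linear
    predictors, a known source of optimism that matches the method's
    original formulation.  A modality whose tuned model is empty
    contributes a constant and is dropped from the combiner; if all are
    empty the combiner is the intercept-only null model.
    """
    X = as_matrix(X)
    if folds is None:
        strata = out.y if out.family == "binomial" else None
        folds = make_folds(X.shape[0], 5, 10, seed=0, strata=strata)
    results = []
    lps = []
    for m, cols in enumerate(blocks.blocks):
        Xm = X[:, cols]
        sub_blocks = BlockStructure.from_sizes([cols.size])
        res = select_penalty_factors(
            Xm, out, sub_blocks, [PenaltyFactors([1.0])], folds, metric,
            grid_policy=fit_kwargs,
        )
        results.append(res)
        lps.append(predict(res.fit, Xm, res.lambda_index, kind="link"))
    L = np.column_stack(lps)
    coef, intercept, active = _fit_combiner(out.family, L, out)
    return SeparateFit(
        family=out.family,
        blocks=blocks,
        modality_results=results,
        combiner_coef=coef,
        combiner_intercept=intercept,
        active=active,
    )


# ---------------------------------------------------------------------------
# SGL tuning


def cv_sgl(
    X,
    out: Outcome,
    blocks: BlockStructure,
    cfg: SglConfig = None,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """5-fold (no repeats) CV for the SGL lambda at fixed alpha.

    The criterion is the family's default loss: deviance for binomial,
    MSE for gaussian, cross-validated partial likelihood for Cox.
    """
    cfg = cfg or SglConfig()
    X = as_matrix(X)
    out.check_fittable()
    full = fit_sgl(X, out, blocks, cfg)
    grid = full.lambdas
    cfg_fold = SglConfig(
        alpha=cfg.alpha, lambdas=grid, tol=cfg.tol, max_iter=cfg.max_iter,
        standardize=cfg.standardize,
    )
    strata = out.y if out.family == "binomial" else None
    folds = make_folds(X.shape[0], k, 1, seed=seed, strata=strata)

    name = {"gaussian": "mse", "binomial": "deviance", "cox": "cox_cvpl"}[out.family]
    direction = "maximize" if name == "cox_cvpl" else "minimize"
    mspec = MetricSpec(name, direction)

    per_fold = []
    skipped = 0
    for f in range(k):
        test_idx = np.flatnonzero(folds.assignments[0] == f)
        train_idx = np.flatnonzero(folds.assignments[0] != f)
        out_train = out.subset(train_idx)
        try:
            out_train.check_fittable()
        except ValueError:
            warnings.warn(f"skipping degenerate SGL training fold {f}")
            skipped += 1
            continue
        ffit = fit_sgl(X[train_idx], out_train, blocks, cfg_fold)
        vals = np.empty(grid.size)
        for li in range(grid.size):
            if name == "cox_cvpl":
                vals[li] = cox_cvpl(ffit.coef_[li], X, out, train_idx)
            else:
                pred = predict(ffit, X[test_idx], li)
                vals[li] = evaluate_metric(name, out.family, pred, out.subset(test_idx))
        per_fold.append(vals)
    if not per_fold:
        raise ValueError("all SGL CV folds were degenerate")
    arr = np.asarray(per_fold)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(grid.size)
    li = _pick_lambda(mspec, mean)
    return CVResult(
        metric=mspec, lambdas=grid, mean=mean, sd=sd, lambda_index=li,
        pf=None, fit=full, n_folds_used=len(per_fold), n_skipped_folds=skipped,
    )
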