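# Methods

## Model

`ipflasso` fits L1-penalized regression models in which each *modality*
(block) of predictors — clinical covariates, gene expression, methylation,
copy number, … — receives its own penalty.  For a design with M modalities,
block m holding p_m standardized columns x^(m), the estimate minimizes

    loss(b0, beta) + sum_m lam_m * || beta^(m) ||_1 ,

where the loss is (1/(2n))·RSS for a continuous outcome, (1/n)·negative
log-likelihood with an unpenalized intercept for a binary outcome, and
(1/n)·negative Breslow partial log-likelihood (no intercept) for a
right-censored outcome.  Writing lam_m = lam1 · pf_m, the vector of
*penalty factors* pf = (1, lam2/lam1, …, lamM/lam1) is invariant under
multiplication by a positive scalar and is stored canonically with first
entry 1.  The weighted problem reduces to a single-lambda problem with
per-feature penalty weights w_j = pf_m for j in block m; equivalently one
may divide each column by its factor, fit a uniform-penalty LASSO and
divide the estimates back.  The solver uses the per-feature-weight form;
the rescaling route is retained as an independent test oracle (the two
agree to < 1e-6 on random instances across all three families).

The loss carries an explicit 1/n (1/(2n) for RSS) so lambda is comparable
across sample sizes; this matches the convention of the mainstream
penalized-GLM solvers and is cross-checked against R glmnet in the test
suite (after accounting for glmnet's internal rescaling of its
`penalty.factor` argument to sum to nvars).

## Tuning

Both lam1 and the penalty-factor vector are chosen by repeated k-fold
cross-validation (default 5 folds × 10 repeats, stratified by class for
binary outcomes).  A candidate set of factor vectors is supplied — for two
modalities the default grid is (1, 2^k), k = −3…3, seven candidates
including the uniform (1, 1) — and each candidate receives its own
lambda grid anchored at its own lambda_max, a full CV curve on a fold
plan shared across candidates (paired comparison), and an optimal lambda.
The candidate whose optimum achieves the best mean metric wins; ties go
to the lower candidate index, and ties along the lambda curve go to the
larger lambda (the sparser model).  Metrics: MSE (continuous),
misclassification rate at the 0.5 threshold or AUC (binary), and for
survival the Verweij–van Houwelingen cross-validated partial likelihood
pl_full(beta_train) − pl_train(beta_train), summed over folds.  The
optimum is the minimum (or maximum) of the mean curve; a one-standard-error
rule is available but not the default.  An optional `max_vars` cap
restricts each candidate's lambda search to grid points whose full-data
refit has at most that many nonzero coefficients.  Degenerate training
folds (single class, no events) are skipped with a warning and means are
taken over the remaining folds.

## Solver

Coordinate descent on standardized columns (centered, scaled by the
population standard deviation, divisor n); coefficients are reported on
the original scale.  Standardization happens first, then penalty weights
are applied — the order matters in principle and we make no bit-equality
claim against implementations that interleave the two differently.
Zero-variance columns are excluded (coefficient 0) with a warning.

Logistic and Cox fits wrap the weighted-least-squares kernel in an IRLS
loop (working weights floored at 1e-5, probabilities clipped at 1e-8; for
Cox the diagonal of the Hessian of the Breslow partial likelihood
provides the weights; ties are handled by Breslow's method throughout).
The path runs over a log-spaced grid of (default) 100 lambdas from
lambda_max = max_j |g_j|/w_j (null-model gradient g) down to
0.01·lambda_max when p > n (1e-4·lambda_max otherwise), with warm starts.
Features are screened per lambda with the sequential strong rule
|g_j| ≥ w_j(2·lam − lam_prev); the KKT conditions are then verified over
all features and violators re-enter the active problem, so screening
never changes the solution.  Convergence: the largest coefficient change
in a sweep must fall below tol × max(1, max|beta|) with tol = 1e-7; the
relative scaling keeps the criterion meaningful in quasi-separated
logistic fits whose coefficients grow without bound.  In that regime the
path is additionally frozen once the fit explains 99.9% of the null
deviance (the interpolation threshold), the same guard mainstream
penalized-GLM software applies.  Every returned solution passes a
subgradient (KKT) certificate at 1e-4 in the test suite.

## Comparators

*Standard LASSO* is the uniform-penalty special case (pf = (1, …, 1)) and
shares the code path bit-for-bit.

*Separate models (S)*: one CV-tuned standard LASSO per modality; the M
training-set linear predictors are then combined by a small unpenalized
regression — logistic for binary, linear for continuous, and for survival
an unpenalized Cox fit on the M predictors (the survival combiner is this
package's choice; the original description covers the binary case only).
The combiner uses in-sample linear predictors, a deliberate and
documented optimism source.  Empty per-modality models contribute a
constant and are dropped from the combiner; if all are empty the
prediction is the null model.

*Sparse group LASSO (SGL)*: penalty
(1−α)·lam·Σ_m √p_m‖beta^(m)‖₂ + α·lam·‖beta‖₁ with a single lambda for
all blocks, solved by FISTA with backtracking and momentum restarts; the
proximal operator composes soft-thresholding with blockwise group
shrinkage.  lambda_max is found per block by bisection on the zero-block
condition ‖soft(g_m, α·lam)‖₂ ≤ (1−α)·lam·√p_m.  Defaults follow the R
SGL package as run in the original benchmark: α = 0.95 (not tuned),
20 lambdas down to 0.1·lambda_max, loose relative tolerance 1e-2
(speed over polish — tests that certify block optimality use a strict
tolerance instead), and plain 5-fold CV without repeats scored by the
family deviance.  Block optimality is certified at 1e-3 in the suite.

## Synthetic data

The generator reproduces the two-modality benchmark design: y ~
Bernoulli(τ = 0.5); given the class, the p1 + p2 predictors are
multivariate normal with common covariance Σ and class-1 mean
μ = (β1×p1r, 0…, β2×p2r, 0…).  The six named settings A–F vary
(p1, p2, p1r, p2r, β1, β2) with n = 100 training samples and identity Σ;
primed variants (A′–F′) use a block covariance with b = 10 correlation
groups per modality: within-group correlation ρ = 0.4 and correlation ρ
between the j-th groups of the two modalities, after which the columns of
each modality are permuted (freshly per dataset, from the dataset seed)
so the relevant variables scatter across groups.  Sample moments are
verified against μ and Σ at n = 10000 within 4 standard errors.

What the generator does *not* emulate: heavy-tailed or discrete omics
distributions, batch effects, missingness, measurement error, or
outcome-dependent censoring — passing benchmarks here demonstrate correct
implementation of the design above, not performance on real multi-omics
data.

The experiment runner draws B training sets (replicate r uses seed
base + r, with train/test/fold substreams spawned from it), tunes every
requested method with its protocol (IPF: 7-candidate grid, 5×10 CV,
misclassification; standard LASSO: single (1,1) candidate; S: per-modality
CV'd LASSO + combiner; SGL: α = 0.95, 5-fold CV), evaluates
misclassification and AUC on an independent test set of n_test = 5000,
and records model sizes and the selected penalty factors.  Desk-scale
defaults are B = 20 replicates and 50-point lambda grids; the runner
solves at tol 1e-5 (selection decisions were identical to 1e-7 on probe
instances at half the cost — the same speed/polish trade the original
benchmark made when it relaxed the SGL tolerance).  B = 100 and finer
grids are a flag away.

## Numerical choices and edge cases

- Classification threshold fixed at 0.5 (equal-loss convention).
- Brier score: BS(t) weights by inverse probability of censoring
  (Kaplan–Meier Ĝ on the training sample; weight 1/Ĝ(T_i−) for events
  before t, 1/Ĝ(t) for subjects still at risk, 0 for earlier censorings);
  evaluation grid defaults to the unique event times up to the 95th
  percentile of follow-up; the integrated score is the trapezoidal
  integral over [0, horizon] divided by the horizon, anchored at
  BS(0) = 0.  If Ĝ hits 0 the horizon is truncated with a warning.
- Cox prediction exposes per-subject survival curves through the Breslow
  baseline cumulative hazard of the training fit.
- Fold plans are pure functions of (n, k, repeats, seed, strata); every
  pipeline output is a pure function of (data, config, seed).
- Fits serialize to versioned JSON with full float round-trip precision;
  saving a loaded fit reproduces the file byte-for-byte.

## Known limitations

- Full candidate-grid CV scales exponentially with the number of
  modalities; practical up to M ≈ 4.
- No elastic-net/L2 option, no adaptive per-feature weights, no
  stability selection.
- The S-method survival combiner and the within/between-group
  standardization of SGL are interpretation points where reference
  descriptions are silent; both choices are documented above.
- IRLS may stall under quasi-separation; the saturated tail of the path
  is then frozen rather than polished, which is immaterial for CV-selected
  models but visible if the extreme low-lambda end is inspected directly.
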