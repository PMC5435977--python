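# ipflasso

L1-penalized regression for predictor matrices built from several data
*modalities* — e.g. a handful of clinical covariates next to thousands of
gene-expression probes — where a single shared penalty would either drown
the small informative modality or over-select the large noisy one.  Each
modality m gets its own penalty, and the fit minimizes

    loss(β) + Σ_m λ_m ‖β^(m)‖₁ ,        λ_m = λ₁ · pf_m ,

for linear, logistic, or Cox regression.  The *penalty factors*
pf = (1, λ₂/λ₁, …, λ_M/λ₁) are tuned together with λ₁ by repeated
cross-validation over a candidate grid (default (1, 2^k), k = −3…3, with
5-fold CV × 10 repeats), or fixed from prior knowledge.  The package also
ships the comparison methods used to benchmark this approach — the
standard LASSO, separate per-modality models combined by a small
regression, and the sparse group LASSO — plus the evaluation metrics
(misclassification, AUC, cross-validated Cox partial likelihood,
IPCW Brier score / integrated Brier score) and a seeded two-modality
simulation benchmark.

Audience: biostatisticians and computational biologists building sparse
prediction models from multi-omics or clinical+omics data who care about
model size as much as accuracy.

## Worked example

Two modalities — 15 "clinical" columns (4 with true effects) and 300 noise
"expression" columns — binary outcome, full data-driven tuning:

```python
import numpy as np
import ipflasso as ipf

rng = np.random.default_rng(7)
n, p1, p2 = 120, 15, 300
X = rng.standard_normal((n, p1 + p2))
beta = np.zeros(p1 + p2)
beta[:4] = 1.0
y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)

blocks = ipf.BlockStructure.from_sizes([p1, p2], names=["clinical", "expression"])
out = ipf.Outcome.binomial(y)
folds = ipf.make_folds(n, k=5, repeats=10, seed=1, strata=y)
res = ipf.select_penalty_factors(
    X, out, blocks, ipf.pow2_candidates(), folds,
    metric="misclassification", grid_policy=dict(nlambda=50),
)
print("selected penalty factors:", res.pf.factors)
print("lambda_opt: %.4f" % res.lambda_opt)
print("variables selected:", res.n_selected)
```

Output:

```
selected penalty factors: [1. 2.]
lambda_opt: 0.0665
variables selected: 6
```

Cross-validation penalizes the noise modality twice as hard as the
clinical one and keeps a 6-variable model — all 6 from the clinical block
(`res.fit.df_by_block()[res.lambda_index]` → clinical 6, expression 0).
On an independent test draw of 1000 samples this model attains
misclassification 0.243 and AUC 0.842.  A standard LASSO
(`ipf.cv_standard_lasso`) on the same folds must use one penalty for all
315 columns and typically drags expression noise into the model.

## Command line

```bash
ipflasso cv   --data data.csv --blocks blocks.txt --family binomial \
              --outcome-column y --pf-candidates pow2:-3..3 --seed 1 --out-dir run/
ipflasso fit  --data data.csv --blocks blocks.txt --family cox \
              --time-column t --status-column s --method sgl --alpha 0.95
ipflasso simulate --setting A --b 20 --methods ipf,sgl --seed 1 --out-dir sim/
ipflasso evaluate --data test.csv --blocks blocks.txt --family binomial \
              --outcome-column y --fit-file run/fit.json
```

Block configs are plain text, 1-based inclusive ranges:

```
clinical   = 1-15
expression = 16-315
```

Every run writes a `*.meta.json` sidecar (arguments + seed + version)
sufficient to reproduce it exactly.

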