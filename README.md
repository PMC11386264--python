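# fourierreg

Nonparametric regression with a cosine-series basis. Each predictor `x_j`
contributes an additive curve

```
g(x_j) = mu_j/2 + beta_j * x_j + sum_{t=1..T_j} delta_tj * cos(t * x_j)
```

so the design matrix stacks, per predictor, a constant half-column, the raw
trend, and `T_j` cosine harmonics. The package provides:

- **basis** — `FourierSpec` / `assemble_design`: design-matrix construction
  with per-predictor column-block bookkeeping. For two or more predictors the
  half-columns are identical, so the design is rank-deficient by `p - 1` by
  construction; this is kept as-is and resolved by minimum-norm least squares.
- **estimation** — `fit_ols` (minimum-norm OLS via the Moore–Penrose
  pseudoinverse of `X'X`), `hat_matrix`, and fit metrics (R², MSE, MAE, RMSE,
  MAPE).
- **selection** — GCV scoring and two oscillation-count searches:
  `search_uniform` (one shared `T`) and `search_combinations` (full Cartesian
  enumeration of `{1..T_max}^p`), with CSV-serializable reports.
- **inference** — the simultaneous F-test of all coefficients
  (`simultaneous_test`), the Lagrange-multiplier constrained estimator
  (`constrained_fit`), per-coefficient t-tests (`partial_test`,
  `partial_test_all`, optional Bonferroni/BH adjustment), the likelihood
  ratio, and `quadratic_form_check` for the projector identities behind the
  t reference distribution.
- **diagnostics** — Glejser heteroscedasticity test (auxiliary regression of
  absolute residuals on the same design) and actual/predicted/residual
  exports.
- **synthetic** — seeded generators for datasets with known true
  coefficients and noise variance, including null-coefficient designs for
  type-I-error studies.
- **io / cli** — CSV ingestion with validation and a `fourierreg` command
  tying search → refit → tests → diagnostics into one reproducible run.

## CLI

```bash
# generate a synthetic dataset with known truth
fourierreg simulate --n 120 --p 2 --t 2 --sigma2 0.1 --seed 7 --out data.csv

# full pipeline: GCV search, refit at the best T, F/t tests, Glejser
fourierreg select --data data.csv --response y --t-max 3 --mode uniform --outdir run/

# fixed-T fit and tests
fourierreg fit  --data data.csv --response y --t 2 --out coef.csv
fourierreg test --data data.csv --response y --t 2,2 --alpha 0.05

# Monte-Carlo type-I-error check of the partial t-test
fourierreg calibrate --replicates 500 --n 40 --t 2,2 --seed 1
```

`select` writes `search.csv` (one row per candidate T-vector with GCV and
fit metrics), `coefficients.csv` (estimate, |Z|, p-value, decision per
coefficient), `metrics.csv`, `diagnostics.csv`, and `run.log`.

## Notes

- All occurrences of `(X'X)^{-1}` use the shared pseudoinverse, so the
  collinear half-columns receive equal (minimum-norm) intercept shares and
  degrees of freedom are rank-based: `r = n - rank(X)`.
- The simultaneous statistic's numerator `(X delta_hat)' y` includes the
  intercept contribution; its null calibration is exact only for zero-mean
  responses. The Glejser diagnostic therefore defaults to a mean-corrected
  F-test (`center=True`), since absolute residuals always have positive mean.
- `FourierSpec(rescale=True)` linearly maps each predictor to `[0, pi]`
  for data whose raw scale makes the cosine basis degenerate; the default
  applies cosines to raw values.
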