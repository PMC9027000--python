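# sterolkin

Predictive modelling of phytosterol degradation in bulk-stored seeds as a
function of water activity (a_w), temperature (T) and storage time (tau).

The package provides four modelling stages plus an orchestration layer:

- **`sterolkin.synthetic_data`** — generate storage-experiment datasets with a
  factorial (T x a_w) design, regular sampling times (72-day series for
  a_w <= 0.81, 48-day otherwise), replicate measurements and a quadratic
  degradation surface plus Gaussian noise; learning/test/validation role
  splitting (70:30 by default, replicate groups kept together).
- **`sterolkin.rsr`** — the full 10-term second-order response-surface
  regression (linear, quadratic and two-way interaction terms in a_w, T,
  tau), fitted by OLS on unscaled predictors via an orthogonal factorization,
  with coefficient standard errors and t-test p-values, plus the stored
  reference coefficient set (`REFERENCE_COEFFICIENTS`).
- **`sterolkin.ann`** — from-scratch MLP (3-H-1, BFGS-trained with an
  early-stopping test-error snapshot) and RBF (k-means centers + width
  heuristic + ridge output layer) regressors, the five-cases-per-parameter
  hidden-size rule of thumb, and a multi-restart topology grid search that
  selects the network with the lowest share-weighted
  learning/test/validation error.
- **`sterolkin.evaluation`** — the validation suite: R², MAE, RMSE, signed
  and absolute mean relative percentage errors (MRPE/MAPE), bias and
  accuracy factors (B_f/A_f, base-10 logs), and the elliptical joint
  confidence region (EJCR) test for the predicted-vs-observed regression
  against the ideal (intercept 0, slope 1).
- **`sterolkin.pipeline`** — end-to-end runs (generate → split → fit RSR →
  MLP/RBF searches → evaluate → report) that are bit-identical for a given
  master seed.

## CLI

```sh
# synthetic dataset (default 16-experiment design, triplicates, 70:30 split)
sterolkin generate --out data.csv --seed 1

# quadratic response-surface fit on the building rows
sterolkin fit-rsr --data data.csv --out rsr.json

# MLP topology search, hidden sizes 2..16, 25 restarts each
sterolkin search-ann --data data.csv --type mlp --hidden 2:16 \
    --activations log,tanh,exp --restarts 25 --seed 1 --out mlp.json

# metrics + EJCR per data-role subset (learning/test/building/validation)
sterolkin evaluate --data data.csv --model mlp.json --out report.json

# full pipeline into a run directory
sterolkin run --seed 1 --out runs/demo --restarts 25
```

`sterolkin run` accepts `--config config.yaml`; keys mirror
`sterolkin.pipeline.PipelineConfig` (temperatures, water_activities,
validation_conditions, sampling_interval, replicates, noise_sd, mlp_hidden,
rbf_hidden, restarts, max_iterations, seed, ...). Use `--restarts 1000` to
mirror the full-scale search.

## Notes

- Network "errors" are MSE on the min–max `[0, 1]`-scaled target, so they
  are comparable across topologies but not across differently scaled data.
- The exponential hidden activation is `e^x`; the RBF hidden unit is
  `exp(-d²/(2·width²))` with `d` the distance to the center.
- `MetricReport.r2` is the coefficient of determination `1 - SS_res/SS_tot`
  and may be negative for very poor models.
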