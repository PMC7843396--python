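# riskupdate

Updating published clinical risk prediction models on a new registry cohort,
with honest internal, temporal and cross-validation of the *whole updating
strategy* — not just of the final model.

## The problem

A published logistic risk score (for example, a 30-day mortality model for
transcatheter aortic valve implantation, TAVI) tends to miscalibrate when
carried to a new population or a later era: observed mortality drifts away
from the predictions even when discrimination survives. Rather than
discarding the model, one can *update* it on local data. Four updates of
increasing extensiveness are available for a logistic model with linear
predictor `lp = β₀ + βᵀx`:

| method | refit | free parameters |
|---|---|---|
| no update | — | 0 |
| intercept update (calibration-in-the-large) | `y ~ α + offset(lp)` | 1 |
| logistic recalibration | `y ~ α + γ·lp` | 2 |
| model revision | `y ~ β₀* + β*ᵀx` | p + 1 |

A **closed-testing procedure** — a nested sequence of likelihood-ratio tests
against the fixed published model — selects the least extensive update the
data support while approximately preserving the chosen type-I error rate
(here α = 0.05). Because the data also decide *which* update is fitted, the
selection itself must be validated: the package bootstraps the entire
strategy (imputation → closed testing → refit) in each of B resamples and
subtracts the resulting optimism from apparent performance.

The package provides:

- `registry_io` — typed cohort tables (CSV + JSON data dictionary), model
  specifications (JSON: intercept + named log-odds coefficients), and the
  missing-predictor policy (assume an unregistered predictor absent, or
  simulate it as Bernoulli(p) for sensitivity analysis);
- `synthetic` — a registry-like cohort generator with known ground truth:
  ~4.5% outcome prevalence, realistic predictor marginals, MAR missingness,
  a withheld predictor, and configurable miscalibration (intercept shift δ₀,
  slope factor γ, coefficient overrides, per-year drift);
- `imputation` — multiple imputation by chained equations (predictive mean
  matching / logistic / multinomial conditionals, outcome included), plus
  Rubin's rules pooling;
- `model_core` — linear predictors, Bernoulli likelihoods and the four
  update fits;
- `closed_testing` — the LR-test cascade, per-imputation, with
  majority-vote aggregation across imputed datasets;
- `performance` — AU-ROC (with DeLong and bootstrap CIs and the paired
  DeLong test), AU-PRC, Brier and Brier-skill scores, logistic calibration
  intercept/slope, calibration curves, Youden's J;
- `validation` — bootstrap-of-strategy internal validation with optimism
  correction, temporal validation (train early years / test the last), and
  outcome-stratified k-fold cross-validation;
- `descriptives` — the baseline-characteristics table with per-category
  mortality risks and univariable tests.

## Worked example

```sh
riskupdate simulate --n 6000 --seed 20260920 --intercept-shift -0.5 \
    --out cohort.csv --dictionary dictionary.json
python - <<'PY'
import riskupdate as ru
model = ru.synthetic_france2_like_spec()
ru.write_model_spec(model, "model.json")
PY
riskupdate update --cohort cohort.csv --dictionary dictionary.json \
    --model model.json --method auto --seed 1 --out updated.json \
    --report selection.json
```

Equivalently through the library (this is what `analysis/03_update_selection.py`
runs; output below is what it printed):

```
france2-like-synthetic: selected intercept; AU-ROC 0.662 -> 0.662,
    calibration intercept -0.441 -> +0.000
```

Reading: the cohort was generated with its true log-odds shifted −0.5 below
the published model, so the model overestimates mortality — a calibration
intercept of −0.44 (ideal 0) against an unchanged AU-ROC of 0.66
(discrimination is unaffected by a uniform shift). The closed test correctly
finds that re-estimating the intercept alone repairs it: after the update
the calibration intercept is 0.000 and the mean predicted risk equals the
observed event rate exactly (the logistic score equation).

The numbered drivers under `analysis/` run the full study on the synthetic
registry: `01` simulates the cohort, `02` writes the baseline table, `03`
selects updates by closed testing, `04` bootstraps the whole strategy
(optimism-corrected performance and selection frequencies), `05` contrasts
temporal validation with year-blind cross-validation, and `06` probes the
sensitivity of the absence assumption for the unregistered predictor. Each
writes JSON/CSV under `results/`.

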