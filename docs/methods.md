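# Methods

## Model updating

A published risk model is treated as a fixed logistic linear predictor
`lp_i = β₀ + βᵀx_i` producing risks `expit(lp_i)` for a binary outcome
(here: death within 30 days of the procedure). Updating re-estimates part
of it on the new cohort by maximum likelihood:

- **intercept update**: `y ~ α + offset(lp)`; the published lp enters as a
  fixed offset, so only the overall risk level moves. The returned model is
  the original with intercept `β₀ + α`.
- **recalibration**: `y ~ α + γ·lp`; one common shrinkage/expansion factor
  γ on all coefficients plus a new intercept `α + γβ₀`.
- **revision**: a plain logistic refit on the original predictor set. No
  penalization; separation or collinearity is an error, not a silent fix.
  A predictor whose column is constant in the cohort — in practice a
  predictor the registry never recorded, filled as all-absent — has no
  estimable coefficient: it is excluded from the free parameters and keeps
  its published coefficient, and every degrees-of-freedom computation uses
  the effective count.

Fits use iteratively reweighted least squares (statsmodels GLM, binomial
family, gradient tolerance 1e-8, at most 100 iterations); non-convergence
raises. For likelihood evaluation of externally supplied models, predicted
probabilities are clipped at 1e-12 (a published model may assign ~0/1 to an
observed event); clipping emits a warning.

## Closed testing

The parameter spaces nest (each method's optimum lies inside the next), so
maximised log-likelihoods are monotone and likelihood-ratio statistics
`2Δℓ` against χ² references give a step-down cascade (p = effective number
of free revision coefficients):

1. revision vs original, df p+1 — not significant → **no update**;
2. revision vs recalibration, df p−1 (skipped when p = 1) — significant →
   **revision**;
3. recalibration vs intercept, df 1 — significant → **recalibration**;
4. intercept vs original, df 1 — significant → **intercept**, else no
   update.

The original model enters with zero free parameters (its likelihood is
evaluated at the published coefficients), so rejecting step 1 controls the
overall chance of updating a truly well-calibrated model at α. Simulation
under the null (500 cohorts of n = 2000 from a 6-predictor model) puts the
realised any-update rate at ~4–5%.

The published test order is cited rather than reprinted in the source
literature; the cascade above matches the description (a series of LR tests
against the original, extensiveness increasing from no-update to revision)
and is the package's documented choice.

With multiple imputation the cascade runs once per completed dataset and
the final selection is the majority vote, ties resolved toward the less
extensive method (parsimony). The per-imputation detail is retained.
Likelihood-based MI pooling (D1/D2/D3) is a documented alternative, not
implemented.

## Multiple imputation

Chained equations over the incomplete predictors, visited in increasing
order of missingness, 10 burn-in cycles by default, m = 10 completed
datasets from independent seed substreams. Every conditional model includes
all other predictors *and the outcome* — omitting the outcome biases
predictor-outcome associations toward the null. Conditionals by type:

- continuous: predictive mean matching, type-1 — Bayesian posterior draw of
  the linear-regression parameters, then the observed value of one of the 5
  donors whose predicted means are nearest;
- binary and categorical: logistic / multinomial logistic refitted on a
  bootstrap resample of the observed rows (the resample supplies parameter
  uncertainty), then a Bernoulli/multinomial draw. The bootstrap device is
  used instead of Wald-covariance draws because the Wald covariance
  degenerates for the rare binaries in this setting (prevalences well below
  2%).

Observed cells are never altered (asserted in tests). Coefficients are
pooled by Rubin's rules; performance metrics are computed per completed
dataset and averaged arithmetically — the prevalent convention in the
validation literature, since the source does not state its pooling for
metrics. Categorical predictors are stored natively (string levels) and
expanded to reference-coded indicators on demand for model evaluation; this
keeps imputation on the categorical scale while model code sees the
indicator design.

## Validation of the strategy

**Internal.** The unit validated is the whole strategy. For each of B
bootstrap resamples (row indices only, redrawn if the outcome is
single-class): impute the resample (m_boot copies, default 5; the analysis
drivers use 2–3 for tractability), run the closed test, refit the chosen
update, and score it on the resample (train) and on the imputations of the
original cohort (test). Optimism per metric is `mean_b(train − test)`;
corrected performance is the apparent full-cohort result minus optimism.
Selection frequencies across replicates are tallied — on a cohort whose
truth differs from the published model only by sampling noise, replicates
still select revision far more often than the whole-cohort test does,
because the resampling truth is the cohort's empirical law rather than the
model; the per-selection optimism accessor lets one verify that
fixed-ranking selections (no-update, intercept) carry essentially zero
discrimination optimism (|ΔAUC| < 0.01 at B = 200).

**Temporal.** Update on years before the split (default: everything before
the final year), evaluate once on the later years, reusing the update
method selected on the whole cohort (a flag allows re-selection on the
training years). Under injected per-year drift in the generating log-odds,
the temporal calibration intercept is negative (overestimation) while
year-blind cross-validation straddles zero — the contrast that identifies
performance drift.

**Cross-validation.** k-fold (default 4), stratified by outcome so every
fold holds events at ~4.5% prevalence; the source does not state
stratification, but without it folds can be event-free and metrics
undefined. Fold metrics are averaged.

Seeding: one master `SeedSequence` spawns independent substreams per
replicate/fold/imputation; identical seeds give bit-identical reports.

## Performance measures

AU-ROC is the Mann–Whitney probability of concordance with ties counted ½
(midranks); the DeLong structural-components variance gives fixed-sample
CIs and the paired two-model test; bootstrap-percentile CIs are available
(single-class resamples redrawn and counted). AU-PRC uses the step-wise
average-precision convention (no linear interpolation between PR points).
Brier is the mean squared error of the risks; the Brier-skill score
references the climatology forecast at the observed event rate,
`BSS = 1 − Brier/(ȳ(1−ȳ))`. Calibration follows the logistic-recalibration
framework: the slope is the coefficient of `logit(p)` in a logistic refit
(ideal 1), calibration-in-the-large the intercept of the same refit with
slope fixed at 1 via an offset (ideal 0), both with Wald CIs. Calibration
curves use equal-count groups (default deciles, degenerate groups merged)
with Wilson binomial CIs and a lowess overlay. Youden's J scans observed
prediction values (positive when `p ≥ t`), ties to the lowest optimal
threshold.

## The synthetic registry

The default scenario emulates a national TAVI registry: n = 6000 over
2013–2017; age ~ N(80, 6.9), 51% female, NYHA class distribution
(12.5/23.8/56.1/7.6)%, 18.8% non-transfemoral access, (90.8/9.0/0.3)%
elective/urgent/emergency acuity, dialysis 1.5%, critical preoperative
state 0.6%, plus BMI, eGFR and systolic pulmonary pressure (both clipped at
0). Outcomes are Bernoulli with log-odds
`δ₀ + drift·(year − 2013) + γ·(β₀ + βᵀx)`; the generating intercept is
root-found once (fixed internal probe sample) so the marginal event rate is
4.5% at δ₀ = 0, γ = 1. Missingness: MAR via a logistic function of age
root-found to hit 35.6% on the pulmonary-pressure predictor and 13.7% on
NYHA, MCAR below 2% elsewhere; applied after outcome generation. One binary
predictor (the acute-pulmonary-oedema analogue, prevalence 5%, log-odds
0.9) influences outcomes but is withheld from the emitted table, exercising
the missing-predictor policy. A compact 6-predictor benchmark scenario
(3 standard-normal, 3 binary predictors) serves the calibration
simulations where the full registry scenario would add nothing.

Predictors are generated independently (no copula structure): none of the
validated procedures exploits predictor correlation. Consequently the
synthetic data do not probe collinearity between predictors, center
effects, or non-logistic true risk surfaces — passing tests demonstrate
correctness of the procedures under their stated assumptions, not
robustness to their violation on real registries.

The headline analysis scenario shifts the generating intercept by −0.5, so
the "published" model overestimates mortality — the situation that
motivates updating — and the correct selection is intercept-update, which
the closed test makes on the full cohort.

## Numerical and problem-size choices

- Probability clipping 1e-12; IRLS tolerance 1e-8; score-equation and
  calibration identities asserted to 1e-6 in tests.
- Type-I error simulation: 500 replicates of n = 2000; selection recovery:
  200 replicates of n = 5000; parameter recovery: n = 20000 with 3-SE
  bands; strategy bootstrap check: B = 200, m_boot = 3 on a fully observed
  n = 2000 cohort.
- The Fisher-exact oracle (two-sided hypergeometric enumeration) is checked
  exhaustively over all 2×2 tables with total ≤ 25 and on a seeded random
  sweep of sparser tables up to total 60.
- Analysis drivers default to B = 200 with m_boot = 2 inside replicates;
  B and m are parameters, and B = 1000 / m = 10 reproduce the full-scale
  design.

## Known limitations

- Model extension (adding predictors beyond the original set) is out of
  scope by design.
- MI selection aggregation is majority-vote, not pooled-likelihood testing.
- The MAR mechanism conditions on a single fully observed predictor; more
  complex realistic missingness (e.g. outcome-dependent) is not generated.
- Points-based published scores must be supplied already mapped to the
  logit scale.
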