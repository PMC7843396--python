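"""Internal, temporal and cross-validation of the whole updating strategy.

The unit being validated is not a fitted model but the *strategy*:
impute -> select an update method by closed testing -> refit.  Internal
validation therefore repeats all of it inside every bootstrap replicate;
optimism per metric is the mean excess of bootstrap-sample (training)
performance over original-cohort (test) performance, and the corrected
estimate subtracts that optimism from the apparent full-cohort performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import performance
from .closed_testing import UpdateSelection, closed_test_mi
from .imputation import ImputationSet, impute_mice
from .model_core import fit_update, predicted_risk
from .registry_io import AnalysisConfig, CohortTable, ModelSpec, RegistryError

#: metrics tracked through bootstrap optimism correction
TRACKED_METRICS = (
    "auroc",
    "auprc",
    "brier",
    "brier_skill",
    "calibration_intercept",
    "calibration_slope",
)


@dataclass
class StrategyResult:
    """One full run of the strategy on one cohort."""

    selection: UpdateSelection
    updated_spec: ModelSpec
    imputations: ImputationSet
    metrics: dict[str, float]  # averaged over the m completed datasets


@dataclass
class BootstrapReport:
    B: int
    selected_methods: list[str]
    selection_frequencies: dict[str, int]
    apparent: dict[str, float]
    train_mean: dict[str, float]
    test_mean: dict[str, float]
    optimism: dict[str, float]
    corrected: dict[str, float]
    percentile_ci: dict[str, tuple[float, float]]
    redraws: int
    apparent_selection: str
    train_per_replicate: list[dict] = field(default_factory=list)
    test_per_replicate: list[dict] = field(default_factory=list)

    def optimism_by_selection(self, methods: tuple[str, ...]) -> dict[str, float]:
        """Mean (train - test) per metric over replicates whose selected
        update is in ``methods`` (e.g. the fixed-ranking no_update/intercept
        selections, which cannot overfit discrimination)."""
        idx = [i for i, m_ in enumerate(self.selected_methods) if m_ in methods]
        if not idx:
            return {}
        return {
            k: float(
                np.mean(
                    [
                        self.train_per_replicate[i][k] - self.test_per_replicate[i][k]
                        for i in idx
                    ]
                )
            )
            for k in self.apparent
        }


@dataclass
class SplitReport:
    label: str
    n_train: int
    n_test: int
    train_event_rate: float
    test_event_rate: float
    method: str
    updated_spec: ModelSpec
    test_metrics: dict[str, float]
    test_report: performance.PerformanceReport | None = None


def _metric_suite(predictions, outcomes) -> dict[str, float]:
    a, b, _, _ = performance.calibration_cox(predictions, outcomes)
    return {
        "auroc": performance.auroc(predictions, outcomes),
        "auprc": performance.auprc(predictions, outcomes),
        "brier": performance.brier(predictions, outcomes),
        "brier_skill": performance.brier_skill(predictions, outcomes),
        "calibration_intercept": a,
        "calibration_slope": b,
    }


def evaluate_spec_on_imputations(spec: ModelSpec, imputations: ImputationSet) -> dict[str, float]:
    """Metric suite per completed dataset, averaged arithmetically."""
    per = [
        _metric_suite(predicted_risk(spec, completed), completed.outcome)
        for completed in imputations
    ]
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


def _pool_updated_spec(original: ModelSpec, method: str, imputations: ImputationSet) -> ModelSpec:
    """Fit the chosen update on each completed dataset; pool coefficients by
    Rubin's rules (the point estimate is the across-imputation mean)."""
    fits = [fit_update(method, original, completed) for completed in imputations]
    if method == "no_update":
        return original
    intercept = float(np.mean([f.spec.intercept for f in fits]))
    names = fits[0].spec.predictors
    coefs = {nm: float(np.mean([f.spec.coefficients[nm] for f in fits])) for nm in names}
    return ModelSpec(name=fits[0].spec.name, intercept=intercept, coefficients=coefs)


def run_strategy(
    cohort: CohortTable,
    original: ModelSpec,
    config: AnalysisConfig,
    seed: int | np.random.SeedSequence | None = None,
    m: int | None = None,
    method: str | None = None,
) -> StrategyResult:
    """Impute, select (unless ``method`` pins it), refit, and evaluate apparently."""
    ss = seed if seed is not None else config.seed
    imputations = impute_mice(cohort, m=m or config.m, iterations=config.mice_iterations, seed=ss)
    if method is None:
        selection = closed_test_mi(original, imputations, config.alpha)
    else:
        # method pinned by the caller: no selection step, just record the fit
        fit = fit_update(method, original, imputations.completed[0])
        selection = UpdateSelection(
            selected=method,
            log_likelihoods={method: fit.log_likelihood},
            free_dfs={method: fit.free_df},
            tests=[],
            alpha=config.alpha,
            fits={method: fit},
        )
    spec = _pool_updated_spec(original, selection.selected, imputations)
    metrics = evaluate_spec_on_imputations(spec, imputations)
    return StrategyResult(selection, spec, imputations, metrics)


def optimism_correct(apparent: dict, train_perf: list[dict], test_perf: list[dict]) -> dict:
    """corrected_m = apparent_m - mean_b(train_mb - test_mb)."""
    if not train_perf or len(train_perf) != len(test_perf):
        raise RegistryError("need equal, nonzero replicate counts")
    out = {}
    for k, a in apparent.items():
        diffs = [tr[k] - te[k] for tr, te in zip(train_perf, test_perf)]
        out[k] = a - float(np.mean(diffs))
    return out


def bootstrap_validate_strategy(
    cohort: CohortTable,
    original: ModelSpec,
    config: AnalysisConfig,
    progress=None,
) -> BootstrapReport:
    """Bootstrap the entire strategy B times and correct apparent performance.

    Each replicate resamples n rows with replacement, reruns imputation and
    closed testing on the resample, refits the chosen update, and scores the
    result both on the resample (train) and on the original cohort's
    imputations (test).  Replicates whose outcome is single-class are
    redrawn and counted.
    """
    master = np.random.SeedSequence(config.seed)
    apparent_seed, *rep_seeds = master.spawn(config.B + 1)

    apparent_run = run_strategy(cohort, original, config, seed=apparent_seed, m=config.m)
    apparent = apparent_run.metrics
    original_imps = apparent_run.imputations

    n = cohort.n
    selected: list[str] = []
    train_perf: list[dict] = []
    test_perf: list[dict] = []
    redraws = 0
    for b, rep_ss in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_ss)
        while True:
            idx = rng.integers(0, n, size=n)
            boot = cohort.resample(idx)
            if 0 < boot.outcome.sum() < n:
                break
            redraws += 1
        boot_imps = impute_mice(
            boot, m=config.m_boot, iterations=config.mice_iterations, seed=rep_ss.spawn(1)[0]
        )
        sel = closed_test_mi(original, boot_imps, config.alpha)
        spec = _pool_updated_spec(original, sel.selected, boot_imps)
        selected.append(sel.selected)
        train_perf.append(evaluate_spec_on_imputations(spec, boot_imps))
        test_perf.append(evaluate_spec_on_imputations(spec, original_imps))
        if progress is not None:
            progress(b)

    corrected = optimism_correct(apparent, train_perf, test_perf)
    optimism = {k: apparent[k] - corrected[k] for k in apparent}
    freqs = {m_: selected.count(m_) for m_ in ("no_update", "intercept", "recalibration", "revision")}
    test_arrays = {k: np.array([d[k] for d in test_perf]) for k in apparent}
    ci = {
        k: tuple(float(v) for v in np.percentile(test_arrays[k], [2.5, 97.5]))
        for k in apparent
    }
    return BootstrapReport(
        B=config.B,
        selected_methods=selected,
        selection_frequencies=freqs,
        apparent=apparent,
        train_mean={k: float(np.mean([d[k] for d in train_perf])) for k in apparent},
        test_mean={k: float(np.mean([d[k] for d in test_perf])) for k in apparent},
        optimism=optimism,
        corrected=corrected,
        percentile_ci=ci,
        redraws=redraws,
        apparent_selection=apparent_run.selection.selected,
        train_per_replicate=train_perf,
        test_per_replicate=test_perf,
    )


def temporal_validate(
    cohort: CohortTable,
    original: ModelSpec,
    split_year: int,
    config: AnalysisConfig,
    method: str | None = None,
) -> SplitReport:
    """Update on years before ``split_year``; evaluate once on the later years.

    ``method`` pins the update method (the default workflow reuses the
    selection made on the whole cohort); ``config.reselect_on_train`` reruns
    closed testing on the training years instead.
    """
    years = cohort.year
    train = cohort.subset(years < split_year)
    test = cohort.subset(years >= split_year)
    if train.n == 0 or test.n == 0:
        raise RegistryError("temporal split leaves an empty side")
    if test.outcome.sum() == 0:
        raise RegistryError("no events in the test years")

    ss = np.random.SeedSequence(config.seed).spawn(3)
    if method is None and not config.reselect_on_train:
        full = run_strategy(cohort, original, config, seed=ss[0])
        method = full.selection.selected
    train_run = run_strategy(train, original, config, seed=ss[1], method=method)
    method = train_run.selection.selected

    test_imps = impute_mice(test, m=config.m, iterations=config.mice_iterations, seed=ss[2])
    metrics = evaluate_spec_on_imputations(train_run.updated_spec, test_imps)
    rep = performance.performance_report(
        predicted_risk(train_run.updated_spec, test_imps.completed[0]),
        test_imps.completed[0].outcome,
    )
    return SplitReport(
        label=f"train<{split_year}|test>={split_year}",
        n_train=train.n,
        n_test=test.n,
        train_event_rate=float(train.outcome.mean()),
        test_event_rate=float(test.outcome.mean()),
        method=method,
        updated_spec=train_run.updated_spec,
        test_metrics=metrics,
        test_report=rep,
    )


def cross_validate(
    cohort: CohortTable,
    original: ModelSpec,
    k: int,
    config: AnalysisConfig,
    seed: int | None = None,
    method: str | None = None,
) -> tuple[list[SplitReport], dict[str, float]]:
    """Outcome-stratified k-fold cross-validation of the strategy.

    Stratification guarantees events in every fold at rare prevalence.
    Fold metrics are pooled by averaging.
    """
    if k < 2:
        raise RegistryError("k must be >= 2")
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(master.generate_state(1)[0] % 2**31))
    y = cohort.outcome
    reports: list[SplitReport] = []
    fold_seeds = master.spawn(k)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros_like(y), y)):
        train = cohort.resample(train_idx)
        test = cohort.resample(test_idx)
        ss = fold_seeds[fold].spawn(2)
        train_run = run_strategy(train, original, config, seed=ss[0], method=method)
        test_imps = impute_mice(test, m=config.m, iterations=config.mice_iterations, seed=ss[1])
        metrics = evaluate_spec_on_imputations(train_run.updated_spec, test_imps)
        reports.append(
            SplitReport(
                label=f"fold{fold}",
                n_train=train.n,
                n_test=test.n,
                train_event_rate=float(train.outcome.mean()),
                test_event_rate=float(test.outcome.mean()),
                method=train_run.selection.selected,
                updated_spec=train_run.updated_spec,
                test_metrics=metrics,
            )
        )
    pooled = {
        key: float(np.mean([r.test_metrics[key] for r in reports]))
        for key in reports[0].test_metrics
    }
    return reports, pooled
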