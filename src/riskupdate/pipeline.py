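"""End-to-end orchestration: the full updating-and-validation workflow.

Stages, in order: missing-predictor policy -> descriptive table -> multiple
imputation + closed-testing update selection per model -> internal bootstrap
validation of the whole strategy -> temporal validation -> stratified k-fold
cross-validation -> sensitivity analysis (rerun with the unregistered
predictor simulated as Bernoulli(0.5)).  Everything stochastic derives from
the single configured seed, and the run log records enough to replay it.
"""

from __future__ import annotations

import json
import hashlib
import time
from pathlib import Path

import numpy as np

from . import descriptives, performance, validation
from .model_core import predicted_risk
from .registry_io import (
    AnalysisConfig,
    CohortTable,
    ModelSpec,
    apply_missing_predictor_policy,
    write_model_spec,
)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_full_pipeline(
    cohort: CohortTable,
    models: list[ModelSpec],
    config: AnalysisConfig,
    out_dir,
    make_figures: bool = True,
) -> dict:
    """Run every stage and write the report bundle under ``out_dir``.

    Returns the summary dictionary that is also written as summary.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": _jsonable(config.__dict__), "stages": {}, "warnings": []}
    summary: dict = {"models": {}}
    t0 = time.time()

    def stage(name):
        log["stages"][name] = round(time.time() - t0, 2)

    # stage: descriptives (on the raw cohort, complete-case per variable)
    table1 = descriptives.baseline_table(cohort)
    table1.to_csv(out / "baseline_table.csv", index=False)
    summary["n"] = cohort.n
    summary["events"] = int(cohort.outcome.sum())
    summary["event_rate"] = float(cohort.outcome.mean())
    stage("descriptives")

    master = np.random.SeedSequence(config.seed)
    per_model_seeds = master.spawn(len(models))

    split_year = config.split_year or int(cohort.year.max())

    for model, mseed in zip(models, per_model_seeds):
        mname = model.name
        msum: dict = {}
        seeds = mseed.spawn(6)

        # missing-predictor policy (primary analysis: assume absent)
        working = apply_missing_predictor_policy(
            cohort, model, policy="absent", seed=seeds[0]
        )

        # closed testing + update on the whole cohort
        apparent = validation.run_strategy(working, model, config, seed=seeds[1])
        msum["selected_method"] = apparent.selection.selected
        msum["apparent"] = apparent.metrics
        msum["lr_tests"] = _jsonable(apparent.selection.tests)
        write_model_spec(apparent.updated_spec, out / f"{mname}.updated.json")
        stage(f"{mname}:update")

        # internal validation of the whole strategy
        boot_cfg = config
        boot = validation.bootstrap_validate_strategy(working, model, boot_cfg)
        msum["internal_validation"] = {
            "B": boot.B,
            "selection_frequencies": boot.selection_frequencies,
            "optimism": boot.optimism,
            "corrected": boot.corrected,
            "percentile_ci": _jsonable(boot.percentile_ci),
            "redraws": boot.redraws,
        }
        stage(f"{mname}:internal")

        # temporal validation: train on earlier years, test on the last
        temporal = validation.temporal_validate(
            working, model, split_year, config, method=apparent.selection.selected
        )
        msum["temporal_validation"] = {
            "split_year": split_year,
            "n_train": temporal.n_train,
            "n_test": temporal.n_test,
            "train_event_rate": temporal.train_event_rate,
            "test_event_rate": temporal.test_event_rate,
            "metrics": temporal.test_metrics,
            "auroc_ci": list(temporal.test_report.auroc_ci) if temporal.test_report else None,
        }
        stage(f"{mname}:temporal")

        # stratified k-fold cross-validation
        folds, pooled = validation.cross_validate(
            working, model, config.k, config, method=apparent.selection.selected
        )
        msum["cross_validation"] = {
            "k": config.k,
            "fold_sizes": [f.n_test for f in folds],
            "pooled": pooled,
            "per_fold": [
                {"label": f.label, "n_test": f.n_test, "metrics": f.test_metrics} for f in folds
            ],
        }
        stage(f"{mname}:cv")

        # sensitivity analysis: simulate the unregistered predictor at p=0.5
        present = set(cohort.expanded().columns)
        unregistered = [name for name in model.predictors if name not in present]
        if unregistered:
            simulated = apply_missing_predictor_policy(
                cohort, model, policy="simulate", p=config.missing_predictor_p, seed=seeds[2]
            )
            sens = validation.run_strategy(
                simulated, model, config, seed=seeds[3], method=apparent.selection.selected
            )
            msum["sensitivity_simulated_predictor"] = {
                "metrics": sens.metrics,
                "delta": {
                    k: sens.metrics[k] - apparent.metrics[k] for k in apparent.metrics
                },
            }
        stage(f"{mname}:sensitivity")

        # calibration figure on the first completed dataset
        if make_figures:
            completed = apparent.imputations.completed[0]
            preds = predicted_risk(apparent.updated_spec, completed)
            performance.plot_calibration(
                preds,
                completed.outcome,
                path=out / f"{mname}.calibration.png",
                title=f"{mname} (updated, apparent)",
            )
        summary["models"][mname] = msum

    # paired discrimination contrast when two or more models are supplied
    if len(models) >= 2:
        working = [
            apply_missing_predictor_policy(cohort, m, policy="absent") for m in models[:2]
        ]
        runs = [
            validation.run_strategy(w, m, config, seed=s)
            for w, m, s in zip(working, models[:2], per_model_seeds[:2])
        ]
        c0 = runs[0].imputations.completed[0]
        c1 = runs[1].imputations.completed[0]
        delta, p = performance.compare_auroc(
            predicted_risk(runs[0].updated_spec, c0),
            predicted_risk(runs[1].updated_spec, c1),
            c0.outcome,
        )
        summary["paired_auroc_comparison"] = {
            "models": [m.name for m in models[:2]],
            "delta_auroc": delta,
            "p_value": p,
        }
    stage("total")

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), indent=2))
    manifest = {}
    for f in sorted(out.iterdir()):
        if f.is_file():
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
    log["manifest"] = manifest
    (out / "run_log.json").write_text(json.dumps(_jsonable(log), indent=2))
    return summary
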