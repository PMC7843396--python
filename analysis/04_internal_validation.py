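"""Internal validation: bootstrap the whole updating strategy.

Repeats imputation + closed testing + refitting in each of B bootstrap
samples of the cohort, tallies how often each update method is selected,
and reports optimism-corrected performance (apparent minus the mean excess
of bootstrap-sample over original-cohort performance).  B defaults to 200
here to keep the driver quick; pass B=1000 for a full-scale run.
"""

import json
import sys
from pathlib import Path

import riskupdate as ru
from riskupdate.pipeline import _jsonable

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 414


def main(B=200):
    dictionary = ru.DataDictionary.from_json((OUT / "dictionary.json").read_text())
    cohort, _ = ru.read_cohort(OUT / "cohort.csv", dictionary)
    config = ru.AnalysisConfig(B=B, m=5, m_boot=2, mice_iterations=3, seed=SEED)
    report = {}
    for spec_file in ("model_full.json", "model_reduced.json"):
        model = ru.read_model_spec(OUT / spec_file)
        working = ru.apply_missing_predictor_policy(cohort, model, policy="absent")
        boot = ru.bootstrap_validate_strategy(working, model, config)
        report[model.name] = {
            "B": boot.B,
            "selection_frequencies": boot.selection_frequencies,
            "apparent": boot.apparent,
            "optimism": boot.optimism,
            "corrected": boot.corrected,
            "percentile_ci": boot.percentile_ci,
            "whole_cohort_selection": boot.apparent_selection,
        }
        print(f"{model.name}: selections {boot.selection_frequencies}; "
              f"AU-ROC apparent {boot.apparent['auroc']:.3f}, "
              f"optimism {boot.optimism['auroc']:+.3f}, "
              f"corrected {boot.corrected['auroc']:.3f}")
    (OUT / "internal_validation.json").write_text(json.dumps(_jsonable(report), indent=2))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 200)
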