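"""Generate the synthetic registry cohort used by the downstream analyses.

Draws the default TAVI-like scenario — ~6000 patients over 2013-2017, ~4.5%
30-day mortality declining if drift is requested, MAR missingness on the
pulmonary-pressure and NYHA predictors — with the generating model's
intercept shifted by -0.5 so that the "published" model overestimates
mortality on this cohort (the situation that motivates updating).  Writes
the cohort CSV, data dictionary, truth record, and the two synthetic
original-model specifications.
"""

from pathlib import Path

import riskupdate as ru

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260920


def main():
    OUT.mkdir(exist_ok=True)
    scenario = ru.make_default_tavi_scenario(n=6000, seed=SEED, intercept_shift=-0.5)
    cohort, truth = ru.generate_cohort(scenario)
    ru.write_cohort(cohort, OUT / "cohort.csv")
    (OUT / "dictionary.json").write_text(cohort.dictionary.to_json())
    (OUT / "truth.json").write_text(truth.to_json())
    ru.write_model_spec(ru.synthetic_france2_like_spec(), OUT / "model_full.json")
    ru.write_model_spec(ru.synthetic_acctavi_like_spec(), OUT / "model_reduced.json")
    print(f"cohort: n={cohort.n}, events={int(cohort.outcome.sum())}, "
          f"rate={cohort.outcome.mean():.4f}")
    print("missingness:", cohort.missingness().round(3).to_dict())


if __name__ == "__main__":
    main()
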