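"""Baseline characteristics of the simulated registry cohort.

Reads the cohort written by 01_simulate_cohort.py and produces the
descriptive table: counts, per-category risk of early mortality, and
univariable tests, stratified by the 30-day outcome.  The withheld
acute-pulmonary-oedema predictor appears as an N.A. row, as it would for a
variable the registry never recorded.
"""

from pathlib import Path

import riskupdate as ru

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    dictionary = ru.DataDictionary.from_json((OUT / "dictionary.json").read_text())
    cohort, miss = ru.read_cohort(OUT / "cohort.csv", dictionary)
    variables = cohort.predictor_names + ["acute_pulmonary_oedema"]
    table = ru.baseline_table(cohort, variables)
    table.to_csv(OUT / "baseline_table.csv", index=False)
    shown = table[["variable", "category", "total", "dead", "risk", "p_value", "test"]]
    print(shown.to_string(index=False))


if __name__ == "__main__":
    main()
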