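import json

import numpy as np
import pandas as pd
import pytest

import riskupdate as ru
from riskupdate.registry_io import RegistryError, VariableDef, DataDictionary


@pytest.fixture
def toy_dictionary():
    return DataDictionary(
        (
            VariableDef("age", "continuous"),
            VariableDef("dialysis", "binary"),
            VariableDef("nyha", "categorical", ("I", "II", "III")),
        )
    )


def _write(tmp_path, text, name="cohort.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCohort:
    def test_direct_parse(self, tmp_path, toy_dictionary):
        p = _write(tmp_path, "age,dialysis,outcome,year\n70,0,0,2015\n82,1,1,2016\n75,0,0,2017\n")
        cohort, miss = ru.read_cohort(p, toy_dictionary)
        assert cohort.n == 3
        assert (miss == 0).all()
        assert list(cohort.outcome) == [0, 1, 0]

    def test_empty_cell_is_missing(self, tmp_path, toy_dictionary):
        p = _write(tmp_path, "age,outcome,year\n,0,2015\n82,1,2016\n75,0,2017\n")
        cohort, miss = ru.read_cohort(p, toy_dictionary)
        assert np.isnan(cohort.data["age"].iloc[0])
        assert miss["age"] == pytest.approx(1 / 3)

    def test_missing_outcome_column_fatal(self, tmp_path, toy_dictionary):
        p = _write(tmp_path, "age,year\n70,2015\n")
        with pytest.raises(RegistryError, match="outcome"):
            ru.read_cohort(p, toy_dictionary)

    def test_unknown_column_warned_and_dropped(self, tmp_path, toy_dictionary):
        p = _write(tmp_path, "age,mystery,outcome,year\n70,5,0,2015\n")
        with pytest.warns(UserWarning, match="mystery"):
            cohort, _ = ru.read_cohort(p, toy_dictionary)
        assert "mystery" not in cohort.data.columns

    def test_round_trip(self, tmp_path, toy_dictionary):
        p = _write(tmp_path, "age,dialysis,nyha,outcome,year\n70,0,II,0,2015\n,1,,1,2016\n")
        cohort, _ = ru.read_cohort(p, toy_dictionary)
        out = tmp_path / "roundtrip.csv"
        ru.write_cohort(cohort, out)
        again, _ = ru.read_cohort(out, toy_dictionary)
        pd.testing.assert_frame_equal(cohort.data, again.data)


class TestModelSpec:
    def test_direct_parse(self, tmp_path):
        p = _write(tmp_path, json.dumps({"intercept": -3.0, "coefficients": {"dialysis": 0.7}}), "m.json")
        spec = ru.read_model_spec(p)
        assert spec.intercept == -3.0
        assert spec.predictors == ["dialysis"]

    def test_round_trip_identity(self, tmp_path):
        spec = ru.ModelSpec("m", -2.5, {"age": 0.03, "nyha_III": 0.4})
        ru.write_model_spec(spec, tmp_path / "m.json")
        assert ru.read_model_spec(tmp_path / "m.json") == spec

    def test_non_numeric_coefficient_fatal(self, tmp_path):
        p = _write(tmp_path, json.dumps({"intercept": -3.0, "coefficients": {"dialysis": "high"}}), "m.json")
        with pytest.raises(RegistryError, match="non-numeric"):
            ru.read_model_spec(p)

    def test_undeclared_predictor_fatal(self, tmp_path, toy_dictionary):
        p = _write(tmp_path, json.dumps({"intercept": -3.0, "coefficients": {"ghost": 0.7}}), "m.json")
        with pytest.raises(RegistryError, match="ghost"):
            ru.read_model_spec(p, toy_dictionary)

    def test_indicator_names_validate(self, tmp_path, toy_dictionary):
        p = _write(tmp_path, json.dumps({"intercept": -3.0, "coefficients": {"nyha_III": 0.4}}), "m.json")
        assert ru.read_model_spec(p, toy_dictionary).predictors == ["nyha_III"]


class TestMissingPredictorPolicy:
    def _cohort(self, n=100):
        data = pd.DataFrame(
            {"age": np.linspace(60, 90, n), "outcome": [0, 1] * (n // 2), "year": 2015}
        )
        return ru.CohortTable(data, DataDictionary((VariableDef("age", "continuous"),)))

    def test_absent_policy_all_zero(self):
        cohort = self._cohort(100)
        model = ru.ModelSpec("m", -3.0, {"age": 0.02, "oedema": 0.9})
        out = ru.apply_missing_predictor_policy(cohort, model, "absent")
        assert (out.data["oedema"] == 0).all()

    def test_simulate_half_proportion(self):
        cohort = self._cohort(10000)
        model = ru.ModelSpec("m", -3.0, {"oedema": 0.9})
        out = ru.apply_missing_predictor_policy(cohort, model, "simulate", p=0.5, seed=3)
        assert abs(out.data["oedema"].mean() - 0.5) < 3 * np.sqrt(0.25 / 10000)

    def test_simulate_zero_equals_absent(self):
        cohort = self._cohort(100)
        model = ru.ModelSpec("m", -3.0, {"oedema": 0.9})
        out = ru.apply_missing_predictor_policy(cohort, model, "simulate", p=0.0, seed=3)
        assert (out.data["oedema"] == 0).all()

    def test_simulate_reproducible(self):
        cohort = self._cohort(200)
        model = ru.ModelSpec("m", -3.0, {"oedema": 0.9})
        a = ru.apply_missing_predictor_policy(cohort, model, "simulate", p=0.3, seed=9)
        b = ru.apply_missing_predictor_policy(cohort, model, "simulate", p=0.3, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_invalid_probability_fatal(self):
        cohort = self._cohort(10)
        model = ru.ModelSpec("m", -3.0, {"oedema": 0.9})
        with pytest.raises(RegistryError):
            ru.apply_missing_predictor_policy(cohort, model, "simulate", p=1.5)


class TestCohortInvariants:
    def test_outcome_never_missing(self, toy_dictionary):
        data = pd.DataFrame({"age": [70.0], "outcome": [np.nan], "year": [2015]})
        with pytest.raises(RegistryError):
            ru.CohortTable(data, toy_dictionary)

    def test_outcome_binary(self, toy_dictionary):
        data = pd.DataFrame({"age": [70.0], "outcome": [2], "year": [2015]})
        with pytest.raises(RegistryError):
            ru.CohortTable(data, toy_dictionary)

    def test_expanded_propagates_missing_categorical(self, toy_dictionary):
        data = pd.DataFrame(
            {"nyha": ["II", None, "III"], "outcome": [0, 1, 0], "year": 2015}
        )
        cohort = ru.CohortTable(data, toy_dictionary)
        X = cohort.expanded()
        assert np.isnan(X["nyha_II"].iloc[1]) and np.isnan(X["nyha_III"].iloc[1])
        assert X["nyha_II"].iloc[0] == 1 and X["nyha_III"].iloc[2] == 1
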