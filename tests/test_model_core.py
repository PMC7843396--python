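import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import riskupdate as ru
from riskupdate.model_core import FitError, evaluate_original, log_likelihood
from riskupdate.registry_io import DataDictionary, RegistryError, VariableDef
from riskupdate.synthetic import make_benchmark_scenario


def _toy_cohort(x, y):
    data = pd.DataFrame({"x": np.asarray(x, float), "outcome": y, "year": 2015})
    return ru.CohortTable(data, DataDictionary((VariableDef("x", "continuous"),)))


class TestLinearPredictor:
    def test_intercept_only(self):
        cohort = _toy_cohort([1, 2, 3], [0, 0, 1])
        lp = ru.linear_predictor(ru.ModelSpec("m", -3.0), cohort)
        assert np.allclose(lp, -3.0)
        assert np.allclose(expit(lp), 0.0474, atol=1e-4)

    def test_single_binary(self):
        cohort = _toy_cohort([1.0], [1])
        lp = ru.linear_predictor(ru.ModelSpec("m", 0.0, {"x": 1.0}), cohort)
        assert lp[0] == pytest.approx(1.0)
        assert expit(lp[0]) == pytest.approx(0.7311, abs=1e-4)

    def test_all_zero_gives_half(self):
        cohort = _toy_cohort([5, -5], [0, 1])
        p = ru.predicted_risk(ru.ModelSpec("m", 0.0, {"x": 0.0}), cohort)
        assert np.allclose(p, 0.5)

    def test_missing_value_fatal(self):
        cohort = _toy_cohort([1.0, np.nan], [0, 1])
        with pytest.raises(RegistryError, match="impute"):
            ru.linear_predictor(ru.ModelSpec("m", 0.0, {"x": 1.0}), cohort)


class TestLogLikelihood:
    def test_half_probabilities(self):
        assert log_likelihood([0.5] * 4, [0, 1, 1, 0]) == pytest.approx(4 * np.log(0.5))

    def test_hand_arithmetic(self):
        assert log_likelihood([0.9, 0.1], [1, 0]) == pytest.approx(2 * np.log(0.9))

    def test_empty_sum(self):
        assert log_likelihood([], []) == 0.0

    def test_discordant_boundary_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            ll = log_likelihood([1.0], [0])
        assert np.isfinite(ll)


class TestUpdateMethods:
    def test_intercept_update_closed_form(self):
        # constant offset c: MLE solves expit(alpha + c) = ybar
        cohort = _toy_cohort([0.0] * 100, [0, 1] * 50)
        fit = ru.update_intercept(ru.ModelSpec("m", -1.0), cohort)
        assert fit.params["alpha"] == pytest.approx(1.0, abs=1e-6)
        assert fit.spec.intercept == pytest.approx(0.0, abs=1e-6)

    def test_intercept_matches_event_rate(self, bench_cohort, bench_model):
        cohort, _ = bench_cohort
        fit = ru.update_intercept(bench_model, cohort)
        p = ru.predicted_risk(fit.spec, cohort)
        assert p.mean() == pytest.approx(cohort.outcome.mean(), abs=1e-8)

    def test_intercept_near_zero_under_null(self, bench_cohort, bench_model):
        cohort, _ = bench_cohort
        fit = ru.update_intercept(bench_model, cohort)
        assert abs(fit.params["alpha"]) < 3 * fit.param_se["alpha"] + 1e-9

    def test_recalibration_recovers_damped_slope(self, bench_model):
        cohort, _ = ru.generate_cohort(
            make_benchmark_scenario(n=20000, seed=17, slope_factor=0.5)
        )
        fit = ru.update_recalibrate(bench_model, cohort)
        assert abs(fit.params["gamma"] - 0.5) < 3 * fit.param_se["gamma"]

    def test_recalibrating_a_revised_model_is_identity(self, bench_cohort, bench_model):
        cohort, _ = bench_cohort
        revised = ru.update_revise(bench_model, cohort)
        recal = ru.update_recalibrate(revised.spec, cohort)
        assert recal.params["alpha"] == pytest.approx(0.0, abs=1e-5)
        assert recal.params["gamma"] == pytest.approx(1.0, abs=1e-5)

    def test_revision_matches_two_by_two_odds_ratio(self):
        # single binary predictor: logistic MLE equals the contingency fit
        y = np.array([0] * 40 + [1] * 10 + [0] * 35 + [1] * 15)
        x = np.array([0.0] * 50 + [1.0] * 50)
        cohort = _toy_cohort(x, y)
        fit = ru.update_revise(ru.ModelSpec("m", 0.0, {"x": 0.3}), cohort)
        assert fit.spec.intercept == pytest.approx(np.log(10 / 40), abs=1e-6)
        assert fit.spec.coefficients["x"] == pytest.approx(
            np.log((15 / 35) / (10 / 40)), abs=1e-6
        )

    def test_constant_lp_recalibration_fatal(self):
        cohort = _toy_cohort([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        with pytest.raises(FitError, match="intercept"):
            ru.update_recalibrate(ru.ModelSpec("m", -1.0), cohort)

    def test_single_class_outcome_fatal(self):
        cohort = _toy_cohort([1.0, 2.0], [1, 1])
        with pytest.raises(FitError):
            ru.update_intercept(ru.ModelSpec("m", -1.0, {"x": 0.1}), cohort)

    def test_absent_predictor_keeps_published_coefficient(self, bench_model):
        cohort, _ = ru.generate_cohort(make_benchmark_scenario(n=1000, seed=3))
        spec = ru.ModelSpec(
            "m", bench_model.intercept, {**bench_model.coefficients, "ghost": 0.9}
        )
        cohort = ru.apply_missing_predictor_policy(cohort, spec, "absent")
        fit = ru.update_revise(spec, cohort)
        assert fit.spec.coefficients["ghost"] == 0.9
        assert fit.free_df == len(bench_model.coefficients) + 1


class TestInvariants:
    def test_nesting_chain(self, bench_cohort, bench_model):
        cohort, _ = bench_cohort
        lls = [
            evaluate_original(bench_model, cohort).log_likelihood,
            ru.update_intercept(bench_model, cohort).log_likelihood,
            ru.update_recalibrate(bench_model, cohort).log_likelihood,
            ru.update_revise(bench_model, cohort).log_likelihood,
        ]
        assert all(a <= b + 1e-8 for a, b in zip(lls, lls[1:]))

    def test_score_equation_for_free_intercept(self, bench_cohort, bench_model):
        cohort, _ = bench_cohort
        for fit in (
            ru.update_intercept(bench_model, cohort),
            ru.update_recalibrate(bench_model, cohort),
            ru.update_revise(bench_model, cohort),
        ):
            p = ru.predicted_risk(fit.spec, cohort)
            assert p.sum() == pytest.approx(cohort.outcome.sum(), abs=1e-6)

    def test_composed_spec_reproduces_fitted_probabilities(self, bench_cohort, bench_model):
        cohort, _ = bench_cohort
        fit = ru.update_recalibrate(bench_model, cohort)
        lp0 = ru.linear_predictor(bench_model, cohort)
        direct = expit(fit.params["alpha"] + fit.params["gamma"] * lp0)
        composed = ru.predicted_risk(fit.spec, cohort)
        assert np.allclose(direct, composed, atol=1e-10)
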