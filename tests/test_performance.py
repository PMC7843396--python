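import numpy as np
import pytest
from scipy.special import expit, logit

import riskupdate as ru
from riskupdate import performance as perf
from riskupdate.registry_io import RegistryError
from riskupdate.synthetic import make_benchmark_scenario


def auroc_pair_count(p, y):
    """Brute-force oracle: concordant pairs with ties counted half."""
    p, y = np.asarray(p, float), np.asarray(y, int)
    pos, neg = p[y == 1], p[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_worked_example(self):
        assert perf.auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert perf.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_predictions_half(self):
        assert perf.auroc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(4, 200)
            y = rng.binomial(1, 0.3, n)
            if y.min() == y.max():
                continue
            p = np.round(rng.random(n), 2)  # rounding forces ties
            assert perf.auroc(p, y) == pytest.approx(auroc_pair_count(p, y))

    def test_permutation_invariant(self, rng):
        y = rng.binomial(1, 0.3, 100)
        y[0], y[1] = 0, 1
        p = rng.random(100)
        perm = rng.permutation(100)
        assert perf.auroc(p[perm], y[perm]) == pytest.approx(perf.auroc(p, y))

    def test_single_class_fatal(self):
        with pytest.raises(RegistryError):
            perf.auroc([0.1, 0.9], [1, 1])


class TestAurocCI:
    def test_delong_contains_point(self, rng):
        y = rng.binomial(1, 0.3, 400)
        p = np.clip(rng.normal(0.3 + 0.2 * y, 0.2), 0.01, 0.99)
        lo, hi = perf.auroc_ci(p, y, method="delong")
        assert lo <= perf.auroc(p, y) <= hi

    def test_perfect_separation_upper_bound_one(self):
        y = np.repeat([0, 1], 50)
        p = np.concatenate([np.linspace(0.0, 0.4, 50), np.linspace(0.6, 1.0, 50)])
        assert perf.auroc_ci(p, y, method="delong")[1] == 1.0

    def test_bootstrap_deterministic(self, rng):
        y = rng.binomial(1, 0.3, 200)
        p = rng.random(200)
        a = perf.auroc_ci(p, y, method="bootstrap", B=200, seed=5)
        b = perf.auroc_ci(p, y, method="bootstrap", B=200, seed=5)
        assert a == b

    def test_delong_coverage(self):
        """~95% of DeLong intervals cover the large-sample AUC."""
        from riskupdate.synthetic import benchmark_true_model

        big, _ = ru.generate_cohort(make_benchmark_scenario(n=100000, seed=1, prevalence=0.2))
        spec = benchmark_true_model(0.2)
        true_auc = perf.auroc(ru.predicted_risk(spec, big), big.outcome)
        covered = 0
        n_sim = 150
        for r in range(n_sim):
            cohort, _ = ru.generate_cohort(
                make_benchmark_scenario(n=500, seed=10000 + r, prevalence=0.2)
            )
            p = ru.predicted_risk(spec, cohort)
            lo, hi = perf.auroc_ci(p, cohort.outcome, method="delong")
            covered += lo <= true_auc <= hi
        # binomial band around 0.95 at 150 replicates
        assert covered / n_sim > 0.95 - 3 * np.sqrt(0.95 * 0.05 / n_sim)


class TestCompareAuroc:
    def test_identical_predictors(self):
        y = [0, 1, 0, 1]
        p = [0.1, 0.6, 0.3, 0.8]
        delta, pval = perf.compare_auroc(p, p, y)
        assert delta == 0 and pval == 1

    def test_type_one_error(self, rng):
        rejections = 0
        n_sim = 150
        for _ in range(n_sim):
            y = rng.binomial(1, 0.3, 300)
            if y.min() == y.max():
                continue
            pa, pb = rng.random(300), rng.random(300)
            _, pval = perf.compare_auroc(pa, pb, y)
            rejections += pval < 0.05
        assert rejections / n_sim < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_power_against_informative_predictor(self, rng):
        wins = 0
        for _ in range(20):
            y = rng.binomial(1, 0.3, 5000)
            pa = np.clip(0.3 + 0.25 * (y - 0.3) + rng.normal(0, 0.15, y.size), 0.01, 0.99)
            pb = rng.random(y.size)
            _, pval = perf.compare_auroc(pa, pb, y)
            wins += pval < 0.05
        assert wins > 10

    def test_length_mismatch_fatal(self):
        with pytest.raises(RegistryError):
            perf.compare_auroc([0.1, 0.2], [0.1], [0, 1])


class TestAuprcBrier:
    def test_constant_predictions_give_prevalence(self):
        y = [0, 0, 1, 0, 1]
        assert perf.auprc([0.4] * 5, y) == pytest.approx(0.4)

    def test_perfect_ranking(self):
        assert perf.auprc([0.9, 0.1], [1, 0]) == 1.0

    def test_hand_stepped_curve(self):
        assert perf.auprc([0.9, 0.8, 0.7], [0, 1, 1]) == pytest.approx(0.5833, abs=1e-4)

    def test_zero_events_fatal(self):
        with pytest.raises(RegistryError):
            perf.auprc([0.2, 0.3], [0, 0])

    def test_brier_hand_arithmetic(self):
        assert perf.brier([0.2, 0.8], [0, 1]) == pytest.approx(0.04)

    def test_climatology_has_zero_skill(self):
        y = [0, 0, 0, 1]
        assert perf.brier_skill([0.25] * 4, y) == pytest.approx(0.0)

    def test_perfect_predictions(self):
        y = [0, 1, 0]
        assert perf.brier([0, 1, 0], y) == 0.0
        assert perf.brier_skill([0, 1, 0], y) == 1.0


class TestCalibration:
    def test_revised_model_is_perfectly_calibrated(self, bench_cohort, bench_model):
        cohort, _ = bench_cohort
        revised = ru.update_revise(bench_model, cohort)
        p = ru.predicted_risk(revised.spec, cohort)
        a, b, _, _ = perf.calibration_cox(p, cohort.outcome)
        assert a == pytest.approx(0.0, abs=1e-6)
        assert b == pytest.approx(1.0, abs=1e-6)

    def test_halved_logit_needs_slope_two(self, bench_model):
        cohort, _ = ru.generate_cohort(make_benchmark_scenario(n=40000, seed=23))
        lp = ru.linear_predictor(bench_model, cohort)
        p_att = expit(lp / 2)  # attenuated predictions
        _, b, _, b_ci = perf.calibration_cox(p_att, cohort.outcome)
        se = (b_ci[1] - b_ci[0]) / (2 * 1.96)
        assert abs(b - 2.0) < 3 * se

    def test_overestimation_gives_negative_intercept(self, bench_model):
        cohort, _ = ru.generate_cohort(
            make_benchmark_scenario(n=40000, seed=29, intercept_shift=-1.0)
        )
        p = ru.predicted_risk(bench_model, cohort)  # too high vs shifted truth
        a, _, a_ci, _ = perf.calibration_cox(p, cohort.outcome)
        half = (a_ci[1] - a_ci[0]) / 2
        assert abs(a - (-1.0)) < 3 * half

    def test_constant_predictions_slope_fatal(self):
        with pytest.raises(RegistryError, match="slope"):
            perf.calibration_cox([0.3] * 10, [0, 1] * 5)


class TestCalibrationCurve:
    def test_well_calibrated_deciles_track_diagonal(self, bench_model):
        cohort, _ = ru.generate_cohort(make_benchmark_scenario(n=10000, seed=31))
        p = ru.predicted_risk(bench_model, cohort)
        table = perf.calibration_curve(p, cohort.outcome, groups=10)
        gap = (table["observed_rate"] - table["mean_predicted"]).abs().max()
        assert gap < 0.03

    def test_two_group_hand_computation(self):
        p = [0.1, 0.2, 0.7, 0.8]
        y = [0, 0, 1, 1]
        table = perf.calibration_curve(p, y, groups=2)
        assert len(table) == 2
        assert table["mean_predicted"].tolist() == pytest.approx([0.15, 0.75])
        assert table["observed_rate"].tolist() == pytest.approx([0.0, 1.0])


class TestYouden:
    def test_perfect_separation(self):
        cutoff, j, sens, spec = perf.youden_cutoff([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
        assert (cutoff, j) == (0.7, 1.0)

    def test_constant_predictions_zero_j(self):
        _, j, _, _ = perf.youden_cutoff([0.5] * 4, [0, 1, 0, 1])
        assert j == pytest.approx(0.0)

    def test_exhaustive_scan(self):
        cutoff, j, _, _ = perf.youden_cutoff([0.1, 0.3, 0.4, 0.6, 0.8], [0, 1, 0, 1, 1])
        assert cutoff == pytest.approx(0.6)
        assert j == pytest.approx(2 / 3)


class TestAverageReports:
    def test_identical_tables_average_to_single_metric(self, bench_cohort, bench_model):
        cohort, _ = bench_cohort
        p = ru.predicted_risk(bench_model, cohort)
        reps = [perf.performance_report(p, cohort.outcome) for _ in range(3)]
        avg = perf.average_reports(reps)
        assert avg["auroc"] == pytest.approx(reps[0].auroc)
        assert avg["brier"] == pytest.approx(reps[0].brier)
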