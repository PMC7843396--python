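import numpy as np
import pytest

import riskupdate as ru
from riskupdate.synthetic import benchmark_true_model, make_benchmark_scenario


@pytest.fixture(scope="session")
def bench_model():
    return benchmark_true_model()


@pytest.fixture(scope="session")
def bench_cohort(bench_model):
    """Fully observed null cohort generated from the benchmark model."""
    cohort, truth = ru.generate_cohort(make_benchmark_scenario(n=4000, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def tavi_cohort():
    """Default registry-like cohort with missingness and a withheld predictor."""
    scenario = ru.make_default_tavi_scenario(n=4000, seed=7)
    return ru.generate_cohort(scenario)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
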