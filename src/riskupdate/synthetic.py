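"""Synthetic TAVI-registry cohorts with known ground truth.

Emulates a national registry of transcatheter aortic valve implantation
(TAVI) patients: ~6000 patients over five calendar years, a binary 30-day
mortality outcome with ~4.5% prevalence, a mix of continuous, binary and
categorical predictors with realistic marginals, missing-at-random values
concentrated on two predictors, and one predictor that the registry never
records at all.  Outcomes are drawn from a known logistic model whose
calibration can be perturbed (intercept shift, slope damping, coefficient
overrides, per-year drift), so every downstream stage can be tested for
parameter and selection recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .registry_io import (
    OUTCOME,
    YEAR,
    CohortTable,
    DataDictionary,
    ModelSpec,
    RegistryError,
    VariableDef,
)


@dataclass(frozen=True)
class Generator:
    """Marginal distribution of one predictor."""

    kind: str  # "normal" | "bernoulli" | "categorical"
    params: tuple = ()
    levels: tuple[str, ...] = ()
    clip_at_zero: bool = False


@dataclass(frozen=True)
class Missingness:
    """MCAR(rate) or MAR(rate | conditioning predictor, slope on its z-score)."""

    mechanism: str  # "mcar" | "mar"
    rate: float
    conditioning: str | None = None
    slope: float = 1.0

    def __post_init__(self):
        if not 0 <= self.rate <= 1:
            raise RegistryError("missingness rate must lie in [0, 1]")


@dataclass
class SimulationScenario:
    n: int
    years: tuple[int, int]
    true_model: ModelSpec
    generators: dict[str, Generator]
    dictionary: DataDictionary
    intercept_shift: float = 0.0  # delta0, added to the true lp
    slope_factor: float = 1.0  # gamma, multiplies the true lp
    coefficient_overrides: dict[str, float] = field(default_factory=dict)
    drift_per_year: float = 0.0  # added to the log-odds per year past the first
    missingness: dict[str, Missingness] = field(default_factory=dict)
    withheld: tuple[str, ...] = ()  # generated, used for outcomes, not emitted
    seed: int = 0


@dataclass
class TruthRecord:
    """Everything the generator knew: enables exact parameter-recovery checks."""

    intercept_shift: float
    slope_factor: float
    drift_per_year: float
    true_model: ModelSpec
    coefficient_overrides: dict[str, float]
    effective_coefficients: dict[str, float]
    withheld_columns: pd.DataFrame
    seed: int

    def to_json(self) -> str:
        d = {
            "intercept_shift": self.intercept_shift,
            "slope_factor": self.slope_factor,
            "drift_per_year": self.drift_per_year,
            "true_model": json.loads(self.true_model.to_json()),
            "coefficient_overrides": self.coefficient_overrides,
            "effective_coefficients": self.effective_coefficients,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)


def split_truth(truth: TruthRecord) -> tuple[float, float, dict[str, float]]:
    """(true intercept shift, true slope factor, effective coefficient map)."""
    return truth.intercept_shift, truth.slope_factor, dict(truth.effective_coefficients)


def _draw_predictors(
    scenario: SimulationScenario, rng: np.random.Generator
) -> pd.DataFrame:
    n = scenario.n
    cols: dict[str, object] = {}
    for name, gen in scenario.generators.items():
        if gen.kind == "normal":
            mu, sd = gen.params
            x = rng.normal(mu, sd, size=n)
            if gen.clip_at_zero:
                x = np.clip(x, 0.0, None)
            cols[name] = x
        elif gen.kind == "bernoulli":
            (q,) = gen.params
            cols[name] = rng.binomial(1, q, size=n).astype(float)
        elif gen.kind == "categorical":
            probs = np.asarray(gen.params, dtype=float)
            idx = rng.choice(len(gen.levels), size=n, p=probs / probs.sum())
            cols[name] = pd.Categorical.from_codes(idx, categories=list(gen.levels)).astype(str)
        else:
            raise RegistryError(f"unknown generator kind {gen.kind!r}")
    y0, y1 = scenario.years
    cols[YEAR] = rng.integers(y0, y1 + 1, size=n)
    return pd.DataFrame(cols)


def _expanded_lp(
    frame: pd.DataFrame, dictionary: DataDictionary, model: ModelSpec, overrides: dict[str, float]
) -> tuple[np.ndarray, dict[str, float]]:
    coefs = dict(model.coefficients)
    coefs.update(overrides)
    lp = np.full(len(frame), model.intercept)
    for name, beta in coefs.items():
        base = name
        for var in dictionary.variables:
            if var.type == "categorical" and name in var.indicator_columns():
                base = var.name
                level = name[len(var.name) + 1 :]
                lp += beta * (frame[base] == level).to_numpy(dtype=float)
                break
        else:
            lp += beta * frame[name].to_numpy(dtype=float)
    return lp, coefs


def _mar_probabilities(z: np.ndarray, rate: float, slope: float) -> np.ndarray:
    """Logistic MAR: P(miss) = expit(a + slope * z), a solved for the target rate."""
    if rate <= 0:
        return np.zeros_like(z)
    if rate >= 1:
        return np.ones_like(z)

    def mean_rate(a):
        return expit(a + slope * z).mean() - rate

    a = brentq(mean_rate, -30, 30)
    return expit(a + slope * z)


def generate_cohort(scenario: SimulationScenario) -> tuple[CohortTable, TruthRecord]:
    """Draw a cohort; outcome ~ Bernoulli(expit(delta0 + drift*(year-year0) + gamma*lp))."""
    rng = np.random.default_rng(scenario.seed)
    frame = _draw_predictors(scenario, rng)

    lp, effective = _expanded_lp(
        frame, scenario.dictionary, scenario.true_model, scenario.coefficient_overrides
    )
    year_offset = (frame[YEAR].to_numpy() - scenario.years[0]).astype(float)
    eta = (
        scenario.intercept_shift
        + scenario.drift_per_year * year_offset
        + scenario.slope_factor * lp
    )
    p = expit(eta)
    mean_p = float(p.mean())
    if mean_p <= 0.0 or mean_p >= 1.0:
        raise RegistryError("scenario implies degenerate outcome prevalence")
    frame[OUTCOME] = rng.binomial(1, p)

    # missingness applied after outcome generation, never to outcome/year
    for name, mech in scenario.missingness.items():
        if mech.mechanism == "mcar":
            miss = rng.random(scenario.n) < mech.rate
        elif mech.mechanism == "mar":
            cond = frame[mech.conditioning].to_numpy(dtype=float)
            z = (cond - cond.mean()) / (cond.std() or 1.0)
            miss = rng.random(scenario.n) < _mar_probabilities(z, mech.rate, mech.slope)
        else:
            raise RegistryError(f"unknown missingness mechanism {mech.mechanism!r}")
        frame.loc[miss, name] = np.nan

    withheld = frame[list(scenario.withheld)].copy()
    emitted = frame.drop(columns=list(scenario.withheld))
    emitted_vars = tuple(
        v for v in scenario.dictionary.variables if v.name not in scenario.withheld
    )
    cohort = CohortTable(emitted, DataDictionary(emitted_vars))
    truth = TruthRecord(
        intercept_shift=scenario.intercept_shift,
        slope_factor=scenario.slope_factor,
        drift_per_year=scenario.drift_per_year,
        true_model=scenario.true_model,
        coefficient_overrides=dict(scenario.coefficient_overrides),
        effective_coefficients=effective,
        withheld_columns=withheld,
        seed=scenario.seed,
    )
    return cohort, truth


# --- the default TAVI scenario -------------------------------------------------

#: log-odds effects of the generating model for the default registry scenario
_TAVI_COEFFICIENTS = {
    "age": 0.025,  # per year
    "female": 0.05,
    "bmi": -0.035,  # per kg/m^2
    "egfr": -0.010,  # per mL/min
    "spap": 0.015,  # per mmHg
    "chronic_lung_disease": 0.25,
    "critical_state": 1.6,
    "dialysis": 0.8,
    "nyha_II": -0.40,
    "nyha_III": 0.10,
    "nyha_IV": 0.70,
    "access_nontransfemoral": 0.75,
    "acuity_urgent": 0.55,
    "acuity_emergency": 1.0,
    "acute_pulmonary_oedema": 0.9,
}

_TAVI_GENERATORS = {
    "age": Generator("normal", (80.0, 6.9)),
    "female": Generator("bernoulli", (0.51,)),
    "bmi": Generator("normal", (27.2, 4.88)),
    "egfr": Generator("normal", (59.1, 21.31), clip_at_zero=True),
    "spap": Generator("normal", (31.1, 10.93), clip_at_zero=True),
    "chronic_lung_disease": Generator("bernoulli", (0.224,)),
    "critical_state": Generator("bernoulli", (0.006,)),
    "dialysis": Generator("bernoulli", (0.015,)),
    "nyha": Generator(
        "categorical", (0.125, 0.238, 0.561, 0.076), levels=("I", "II", "III", "IV")
    ),
    "access": Generator("categorical", (0.812, 0.188), levels=("transfemoral", "nontransfemoral")),
    "acuity": Generator(
        "categorical", (0.907, 0.090, 0.003), levels=("elective", "urgent", "emergency")
    ),
    "acute_pulmonary_oedema": Generator("bernoulli", (0.05,)),
}

_TAVI_DICTIONARY = DataDictionary(
    (
        VariableDef("age", "continuous"),
        VariableDef("female", "binary"),
        VariableDef("bmi", "continuous"),
        VariableDef("egfr", "continuous"),
        VariableDef("spap", "continuous"),
        VariableDef("chronic_lung_disease", "binary"),
        VariableDef("critical_state", "binary"),
        VariableDef("dialysis", "binary"),
        VariableDef("nyha", "categorical", ("I", "II", "III", "IV")),
        VariableDef("access", "categorical", ("transfemoral", "nontransfemoral")),
        VariableDef("acuity", "categorical", ("elective", "urgent", "emergency")),
        VariableDef("acute_pulmonary_oedema", "binary"),
    )
)

#: target marginal event rate of the default scenario
TAVI_PREVALENCE = 0.045

#: MAR rates of the two heavily incomplete predictors
SPAP_MISSING_RATE = 0.356
NYHA_MISSING_RATE = 0.137


def tavi_dictionary() -> DataDictionary:
    return _TAVI_DICTIONARY


def _calibrate_intercept(target_rate: float = TAVI_PREVALENCE, n_probe: int = 100_000) -> float:
    """Intercept making the marginal event rate equal target_rate in expectation.

    Solved by root-finding over a large fixed probe sample of predictors
    (internal constant seed, so the returned value does not depend on the
    user's scenario seed).
    """
    probe = SimulationScenario(
        n=n_probe,
        years=(2013, 2017),
        true_model=ModelSpec("probe", 0.0, dict(_TAVI_COEFFICIENTS)),
        generators=dict(_TAVI_GENERATORS),
        dictionary=_TAVI_DICTIONARY,
        seed=1_234_567,
    )
    rng = np.random.default_rng(probe.seed)
    frame = _draw_predictors(probe, rng)
    lp, _ = _expanded_lp(frame, _TAVI_DICTIONARY, probe.true_model, {})

    def mean_rate(b0):
        return expit(b0 + lp).mean() - target_rate

    return float(brentq(mean_rate, -30, 10))


_CALIBRATED_INTERCEPT: float | None = None


def tavi_true_model() -> ModelSpec:
    """The generating logistic model of the default scenario (~4.5% prevalence)."""
    global _CALIBRATED_INTERCEPT
    if _CALIBRATED_INTERCEPT is None:
        _CALIBRATED_INTERCEPT = _calibrate_intercept()
    return ModelSpec("tavi-truth", _CALIBRATED_INTERCEPT, dict(_TAVI_COEFFICIENTS))


def make_default_tavi_scenario(
    n: int = 6000,
    seed: int = 0,
    intercept_shift: float = 0.0,
    slope_factor: float = 1.0,
    coefficient_overrides: dict[str, float] | None = None,
    drift_per_year: float = 0.0,
    with_missingness: bool = True,
) -> SimulationScenario:
    """The registry-like default: five years, ~4.5% mortality, MAR missingness
    on the pulmonary-pressure and NYHA-class predictors, and the
    acute-pulmonary-oedema predictor generated but never emitted."""
    if n < 100:
        raise RegistryError("default scenario needs n >= 100")
    missingness = {}
    if with_missingness:
        missingness = {
            "spap": Missingness("mar", SPAP_MISSING_RATE, conditioning="age", slope=0.5),
            "nyha": Missingness("mar", NYHA_MISSING_RATE, conditioning="age", slope=0.5),
            "egfr": Missingness("mcar", 0.015),
            "bmi": Missingness("mcar", 0.010),
        }
    return SimulationScenario(
        n=n,
        years=(2013, 2017),
        true_model=tavi_true_model(),
        generators=dict(_TAVI_GENERATORS),
        dictionary=_TAVI_DICTIONARY,
        intercept_shift=intercept_shift,
        slope_factor=slope_factor,
        coefficient_overrides=dict(coefficient_overrides or {}),
        drift_per_year=drift_per_year,
        missingness=missingness,
        withheld=("acute_pulmonary_oedema",),
        seed=seed,
    )


_BENCH_COEFFICIENTS = {
    "x1": 0.30,
    "x2": -0.25,
    "x3": 0.20,
    "b1": 0.45,
    "b2": -0.30,
    "b3": 0.55,
}

_BENCH_GENERATORS = {
    "x1": Generator("normal", (0.0, 1.0)),
    "x2": Generator("normal", (0.0, 1.0)),
    "x3": Generator("normal", (0.0, 1.0)),
    "b1": Generator("bernoulli", (0.3,)),
    "b2": Generator("bernoulli", (0.2,)),
    "b3": Generator("bernoulli", (0.1,)),
}

_BENCH_DICTIONARY = DataDictionary(
    tuple(
        VariableDef(nm, "continuous" if nm.startswith("x") else "binary")
        for nm in _BENCH_COEFFICIENTS
    )
)

_BENCH_INTERCEPT_CACHE: dict[float, float] = {}


def benchmark_true_model(prevalence: float = TAVI_PREVALENCE) -> ModelSpec:
    """A compact 6-predictor generating model (3 standard-normal continuous,
    3 binary) with the intercept root-found so the marginal event rate is
    ``prevalence`` in expectation."""
    if prevalence not in _BENCH_INTERCEPT_CACHE:
        rng = np.random.default_rng(7_654_321)
        n_probe = 200_000
        lp = np.zeros(n_probe)
        for nm, gen in _BENCH_GENERATORS.items():
            if gen.kind == "normal":
                x = rng.normal(*gen.params, size=n_probe)
            else:
                x = rng.binomial(1, gen.params[0], size=n_probe).astype(float)
            lp += _BENCH_COEFFICIENTS[nm] * x
        _BENCH_INTERCEPT_CACHE[prevalence] = float(
            brentq(lambda b0: expit(b0 + lp).mean() - prevalence, -30, 10)
        )
    return ModelSpec(
        "benchmark-truth", _BENCH_INTERCEPT_CACHE[prevalence], dict(_BENCH_COEFFICIENTS)
    )


def make_benchmark_scenario(
    n: int,
    seed: int = 0,
    prevalence: float = TAVI_PREVALENCE,
    intercept_shift: float = 0.0,
    slope_factor: float = 1.0,
    coefficient_overrides: dict[str, float] | None = None,
    drift_per_year: float = 0.0,
) -> SimulationScenario:
    """Small fully observed scenario for calibration/selection simulations."""
    return SimulationScenario(
        n=n,
        years=(2013, 2017),
        true_model=benchmark_true_model(prevalence),
        generators=dict(_BENCH_GENERATORS),
        dictionary=_BENCH_DICTIONARY,
        intercept_shift=intercept_shift,
        slope_factor=slope_factor,
        coefficient_overrides=dict(coefficient_overrides or {}),
        drift_per_year=drift_per_year,
        seed=seed,
    )


def synthetic_france2_like_spec() -> ModelSpec:
    """A stand-in for a published points-style score, expressed on the logit
    scale; includes the never-registered acute-pulmonary-oedema predictor.
    Synthetic: placeholder coefficients, not the published values."""
    m = tavi_true_model()
    return ModelSpec("france2-like-synthetic", m.intercept, dict(m.coefficients))


def synthetic_acctavi_like_spec() -> ModelSpec:
    """A stand-in for a registry-derived score on a reduced predictor set.
    Synthetic: placeholder coefficients, not the published values."""
    m = tavi_true_model()
    keep = ("age", "egfr", "dialysis", "nyha_IV", "access_nontransfemoral", "acuity_urgent", "acuity_emergency")
    coefs = {k: m.coefficients[k] for k in keep}
    # crude intercept compensation for the dropped predictors keeps the mean
    # predicted risk near the cohort event rate
    dropped_mean_lp = (
        m.coefficients["female"] * 0.51
        + m.coefficients["bmi"] * 27.2
        + m.coefficients["spap"] * 31.1
        + m.coefficients["chronic_lung_disease"] * 0.224
        + m.coefficients["critical_state"] * 0.006
        + m.coefficients["nyha_II"] * 0.238
        + m.coefficients["nyha_III"] * 0.561
        + m.coefficients["acute_pulmonary_oedema"] * 0.05
    )
    return ModelSpec("acctavi-like-synthetic", m.intercept + dropped_mean_lp, coefs)
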