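"""Data model and I/O for registry cohorts, model specifications and run configuration.

A cohort is a patient-level table with typed predictor columns, a complete
binary 30-day mortality outcome, and the calendar year of the procedure.
A published risk model is represented as a logistic linear predictor:
an intercept plus named coefficients on the log-odds scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OUTCOME = "outcome"
YEAR = "year"

VALID_TYPES = ("continuous", "binary", "categorical")


class RegistryError(ValueError):
    """Fatal problem with a cohort, dictionary or model specification."""


@dataclass(frozen=True)
class VariableDef:
    """One entry of the data dictionary."""

    name: str
    type: str  # continuous | binary | categorical
    levels: tuple[str, ...] = ()  # categorical only, reference first
    label: str | None = None

    def __post_init__(self):
        if self.type not in VALID_TYPES:
            raise RegistryError(f"unknown variable type {self.type!r} for {self.name!r}")
        if self.type == "categorical" and len(self.levels) < 2:
            raise RegistryError(f"categorical variable {self.name!r} needs >= 2 levels")

    @property
    def reference(self) -> str | None:
        return self.levels[0] if self.type == "categorical" else None

    def indicator_columns(self) -> list[str]:
        """Names of the reference-coded indicator columns this variable expands to."""
        if self.type == "categorical":
            return [f"{self.name}_{lv}" for lv in self.levels[1:]]
        return [self.name]


@dataclass(frozen=True)
class DataDictionary:
    variables: tuple[VariableDef, ...]

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise RegistryError("duplicate variable names in dictionary")

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __getitem__(self, name: str) -> VariableDef:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def indicator_names(self) -> list[str]:
        out: list[str] = []
        for v in self.variables:
            out.extend(v.indicator_columns())
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                v.name: {"type": v.type, **({"levels": list(v.levels)} if v.levels else {})}
                for v in self.variables
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DataDictionary":
        raw = json.loads(text)
        return cls(
            tuple(
                VariableDef(name, spec["type"], tuple(spec.get("levels", ())))
                for name, spec in raw.items()
            )
        )


@dataclass
class CohortTable:
    """Patient-level cohort: predictors + binary outcome + procedure year.

    ``data`` keeps predictors in their natural representation (continuous
    floats, binary 0/1 floats, categoricals as string labels); missing
    values are NaN/NA, never zero.  ``expanded()`` produces the
    reference-coded numeric design view used for model evaluation.
    """

    data: pd.DataFrame
    dictionary: DataDictionary

    def __post_init__(self):
        if OUTCOME not in self.data.columns:
            raise RegistryError("cohort lacks the outcome column")
        y = self.data[OUTCOME]
        if y.isna().any():
            raise RegistryError("outcome must never be missing")
        if not set(np.unique(y)).issubset({0, 1}):
            raise RegistryError("outcome must be coded 0/1")
        if len(self.data) < 1:
            raise RegistryError("cohort must contain at least one row")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data[OUTCOME].to_numpy(dtype=float)

    @property
    def year(self) -> np.ndarray:
        return self.data[YEAR].to_numpy(dtype=int)

    @property
    def predictor_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in (OUTCOME, YEAR)]

    def missingness(self) -> pd.Series:
        """Fraction of missing values per predictor column."""
        cols = self.predictor_names
        return self.data[cols].isna().mean()

    def expanded(self) -> pd.DataFrame:
        """Reference-coded numeric view: categoricals become 0/1 indicators.

        Missing categorical labels propagate to NaN in every indicator.
        """
        out: dict[str, np.ndarray] = {}
        for name in self.predictor_names:
            col = self.data[name]
            if name in self.dictionary and self.dictionary[name].type == "categorical":
                var = self.dictionary[name]
                miss = col.isna().to_numpy()
                for lv in var.levels[1:]:
                    ind = (col == lv).to_numpy(dtype=float)
                    ind[miss] = np.nan
                    out[f"{name}_{lv}"] = ind
            else:
                out[name] = col.to_numpy(dtype=float)
        out[OUTCOME] = self.outcome
        if YEAR in self.data.columns:
            out[YEAR] = self.data[YEAR].to_numpy(dtype=float)
        return pd.DataFrame(out, index=self.data.index)

    def subset(self, mask_or_index) -> "CohortTable":
        sel = np.asarray(mask_or_index)
        sub = self.data.loc[sel] if sel.dtype == bool else self.data.iloc[sel]
        return CohortTable(sub.reset_index(drop=True), self.dictionary)

    def resample(self, indices: np.ndarray) -> "CohortTable":
        """Row resample by integer position (bootstrap); records never altered."""
        return CohortTable(self.data.iloc[indices].reset_index(drop=True), self.dictionary)

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return CohortTable(data, self.dictionary)


@dataclass(frozen=True)
class ModelSpec:
    """A published logistic risk model: intercept + named coefficients (log-odds).

    Coefficient keys refer to columns of the cohort's expanded (indicator)
    view, e.g. ``nyha_IV`` for the class-IV indicator of a NYHA categorical.
    """

    name: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.intercept):
            raise RegistryError("model intercept must be finite")
        for k, v in self.coefficients.items():
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not np.isfinite(v):
                raise RegistryError(f"non-numeric or non-finite coefficient for {k!r}")

    @property
    def predictors(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "intercept": self.intercept, "coefficients": self.coefficients},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        raw = json.loads(text)
        coefs = raw.get("coefficients", {})
        bad = [k for k, v in coefs.items() if not isinstance(v, (int, float)) or isinstance(v, bool)]
        if bad:
            raise RegistryError(f"non-numeric coefficient(s) for {bad}")
        return cls(
            name=raw.get("name", "model"),
            intercept=float(raw["intercept"]),
            coefficients={k: float(v) for k, v in coefs.items()},
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Run configuration; defaults follow the study design this pipeline mirrors."""

    alpha: float = 0.05
    m: int = 10  # imputed datasets
    m_boot: int = 5  # imputations inside each bootstrap replicate
    B: int = 1000  # bootstrap replicates
    k: int = 4  # cross-validation folds
    split_year: int | None = None  # first test year of temporal validation
    mice_iterations: int = 10
    seed: int = 0
    missing_predictor_policy: str = "absent"  # "absent" | "simulate"
    missing_predictor_p: float = 0.5
    reselect_on_train: bool = False  # temporal validation: rerun closed test on train years

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise RegistryError("alpha must lie in (0, 1)")
        if self.m < 1 or self.B < 1 or self.k < 2 or self.m_boot < 1:
            raise RegistryError("m >= 1, m_boot >= 1, B >= 1 and k >= 2 required")
        if self.missing_predictor_policy not in ("absent", "simulate"):
            raise RegistryError("missing_predictor_policy must be 'absent' or 'simulate'")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)


def read_cohort(path, dictionary: DataDictionary) -> tuple[CohortTable, pd.Series]:
    """Read a CSV cohort; empty cells become missing values.

    Returns the typed cohort and the per-column missingness fractions.
    Unknown columns are dropped with a warning; a missing outcome column
    is fatal.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if OUTCOME not in df.columns:
        raise RegistryError(f"{path}: no '{OUTCOME}' column")
    keep = {}
    for col in df.columns:
        raw = df[col].replace("", np.nan)
        if col == OUTCOME:
            keep[col] = pd.to_numeric(raw).astype(int)
        elif col == YEAR:
            keep[col] = pd.to_numeric(raw).astype(int)
        elif col in dictionary:
            var = dictionary[col]
            if var.type == "categorical":
                keep[col] = raw
            else:
                keep[col] = pd.to_numeric(raw, errors="coerce")
        else:
            warnings.warn(f"ignoring undeclared column {col!r}", stacklevel=2)
    cohort = CohortTable(pd.DataFrame(keep), dictionary)
    return cohort, cohort.missingness()


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, index=False, na_rep="")


def read_model_spec(path, dictionary: DataDictionary | None = None) -> ModelSpec:
    """Read and validate a JSON model specification.

    When a dictionary is supplied, every coefficient must refer to a
    declared variable or one of its indicator columns.
    """
    spec = ModelSpec.from_json(open(path).read())
    if dictionary is not None:
        known = set(dictionary.indicator_names()) | set(dictionary.names)
        unknown = [p for p in spec.predictors if p not in known]
        if unknown:
            raise RegistryError(f"model {spec.name!r} uses undeclared predictor(s): {unknown}")
    return spec


def write_model_spec(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(spec.to_json())


def apply_missing_predictor_policy(
    cohort: CohortTable,
    model: ModelSpec,
    policy: str = "absent",
    p: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
) -> CohortTable:
    """Fill in model predictors that the registry never recorded.

    ``absent`` assumes the condition is absent for every patient (all-zero
    column); ``simulate`` draws independent Bernoulli(p) values, the
    sensitivity-analysis counterpart.
    """
    if policy not in ("absent", "simulate"):
        raise RegistryError(f"unknown policy {policy!r}")
    if policy == "simulate" and not 0 <= p <= 1:
        raise RegistryError("simulation probability must lie in [0, 1]")
    present = set(cohort.expanded().columns)
    missing = [name for name in model.predictors if name not in present]
    if not missing:
        return cohort
    rng = np.random.default_rng(seed)
    data = cohort.data.copy()
    newdict = list(cohort.dictionary.variables)
    for name in missing:
        if policy == "absent":
            data[name] = 0.0
        else:
            data[name] = rng.binomial(1, p, size=len(data)).astype(float)
        if name not in cohort.dictionary:
            newdict.append(VariableDef(name, "binary"))
    return CohortTable(data, DataDictionary(tuple(newdict)))
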