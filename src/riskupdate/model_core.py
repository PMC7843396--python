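"""Evaluate a published logistic model on a cohort and fit the candidate updates.

The update ladder, in increasing number of free parameters:

    no_update       keep the published model as-is                       (0 df)
    intercept       y ~ alpha + offset(lp)        calibration-in-the-large (1 df)
    recalibration   y ~ alpha + gamma * lp        logistic calibration     (2 df)
    revision        y ~ beta0 + beta' x           full coefficient refit   (p+1 df)

where lp is the published model's linear predictor beta0 + beta'x.  Every
fitted update is re-expressed as a ModelSpec so downstream evaluation needs
no knowledge of how the model was obtained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .registry_io import CohortTable, ModelSpec, RegistryError

#: clipping bound for likelihood evaluation of externally supplied models,
#: which may assign probability ~0/1 to observed events
PROB_EPS = 1e-12

METHODS = ("no_update", "intercept", "recalibration", "revision")


class FitError(RuntimeError):
    """Logistic maximum likelihood failed (separation, rank deficiency, ...)."""


@dataclass(frozen=True)
class UpdatedModel:
    method: str
    spec: ModelSpec
    params: dict[str, float]
    log_likelihood: float
    free_df: int
    param_se: dict[str, float] | None = None


def linear_predictor(model: ModelSpec, cohort: CohortTable) -> np.ndarray:
    """lp_i = intercept + sum_j beta_j x_ij on the expanded (indicator) view."""
    X = cohort.expanded()
    lp = np.full(cohort.n, model.intercept, dtype=float)
    for name, beta in model.coefficients.items():
        if name not in X.columns:
            raise RegistryError(f"cohort lacks model predictor {name!r}")
        col = X[name].to_numpy()
        if np.isnan(col).any():
            raise RegistryError(
                f"predictor {name!r} has missing values; impute before evaluating the model"
            )
        lp += beta * col
    return lp


def predicted_risk(model: ModelSpec, cohort: CohortTable) -> np.ndarray:
    return expit(linear_predictor(model, cohort))


def log_likelihood(probabilities: np.ndarray, outcomes: np.ndarray) -> float:
    """Bernoulli log likelihood; probabilities clipped at PROB_EPS with a warning."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.size == 0:
        return 0.0
    if ((p <= 0) & (y == 1)).any() or ((p >= 1) & (y == 0)).any():
        warnings.warn("probability 0/1 discordant with outcome; clipping", stacklevel=2)
    p = np.clip(p, PROB_EPS, 1 - PROB_EPS)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _design(cohort: CohortTable, predictors: list[str]) -> np.ndarray:
    X = cohort.expanded()
    cols = []
    for name in predictors:
        if name not in X.columns:
            raise RegistryError(f"cohort lacks model predictor {name!r}")
        col = X[name].to_numpy()
        if np.isnan(col).any():
            raise RegistryError(f"predictor {name!r} has missing values; impute first")
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((cohort.n, 0))


def _check_outcome(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise FitError("outcome takes a single value; logistic MLE diverges")


def _fit_glm(y, X, offset=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
        try:
            res = model.fit(maxiter=100, tol=1e-8)
        except Exception as exc:  # perfect separation / singular information
            raise FitError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError("logistic fit produced non-finite estimates")
    return res


def evaluate_original(model: ModelSpec, cohort: CohortTable) -> UpdatedModel:
    """The published model with zero free parameters (the closed-test baseline)."""
    p = predicted_risk(model, cohort)
    return UpdatedModel(
        method="no_update",
        spec=model,
        params={},
        log_likelihood=log_likelihood(p, cohort.outcome),
        free_df=0,
    )


def update_intercept(original: ModelSpec, cohort: CohortTable) -> UpdatedModel:
    """Re-estimate only the intercept, keeping the published lp as a fixed offset."""
    y = cohort.outcome
    _check_outcome(y)
    lp = linear_predictor(original, cohort)
    res = _fit_glm(y, np.ones((cohort.n, 1)), offset=lp)
    alpha = float(res.params[0])
    spec = ModelSpec(
        name=f"{original.name}+intercept",
        intercept=original.intercept + alpha,
        coefficients=dict(original.coefficients),
    )
    return UpdatedModel(
        method="intercept",
        spec=spec,
        params={"alpha": alpha},
        log_likelihood=float(res.llf),
        free_df=1,
        param_se={"alpha": float(res.bse[0])},
    )


def update_recalibrate(original: ModelSpec, cohort: CohortTable) -> UpdatedModel:
    """Logistic calibration: refit intercept and common slope on the published lp."""
    y = cohort.outcome
    _check_outcome(y)
    lp = linear_predictor(original, cohort)
    if np.ptp(lp) < 1e-12:
        raise FitError("constant linear predictor: slope unidentifiable, use the intercept update")
    res = _fit_glm(y, sm.add_constant(lp))
    alpha, gamma = (float(v) for v in res.params)
    spec = ModelSpec(
        name=f"{original.name}+recalibrated",
        intercept=alpha + gamma * original.intercept,
        coefficients={k: gamma * v for k, v in original.coefficients.items()},
    )
    return UpdatedModel(
        method="recalibration",
        spec=spec,
        params={"alpha": alpha, "gamma": gamma},
        log_likelihood=float(res.llf),
        free_df=2,
        param_se={"alpha": float(res.bse[0]), "gamma": float(res.bse[1])},
    )


def update_revise(original: ModelSpec, cohort: CohortTable) -> UpdatedModel:
    """Full revision: refit every coefficient of the original predictor set."""
    y = cohort.outcome
    _check_outcome(y)
    X_all = _design(cohort, original.predictors)
    # constant columns (e.g. a never-registered predictor assumed absent for
    # everyone) are unidentifiable in a refit: keep the published coefficient,
    # estimate nothing for them
    variable = [j for j in range(X_all.shape[1]) if np.ptp(X_all[:, j]) > 0]
    predictors = [original.predictors[j] for j in variable]
    X = X_all[:, variable]
    Xd = np.column_stack([np.ones(cohort.n), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise FitError(f"design matrix rank deficient over predictors {predictors}")
    res = _fit_glm(y, Xd)
    params = {"intercept": float(res.params[0])}
    coefs = {
        name: original.coefficients[name]
        for name in original.predictors
        if name not in predictors
    }
    ses = {"intercept": float(res.bse[0])}
    for j, name in enumerate(predictors, start=1):
        coefs[name] = float(res.params[j])
        params[name] = float(res.params[j])
        ses[name] = float(res.bse[j])
    spec = ModelSpec(name=f"{original.name}+revised", intercept=params["intercept"], coefficients=coefs)
    return UpdatedModel(
        method="revision",
        spec=spec,
        params=params,
        log_likelihood=float(res.llf),
        free_df=len(predictors) + 1,
        param_se=ses,
    )


_UPDATERS = {
    "no_update": evaluate_original,
    "intercept": update_intercept,
    "recalibration": update_recalibrate,
    "revision": update_revise,
}


def fit_update(method: str, original: ModelSpec, cohort: CohortTable) -> UpdatedModel:
    """Dispatch a named update method."""
    if method not in _UPDATERS:
        raise ValueError(f"unknown update method {method!r}; choose from {METHODS}")
    return _UPDATERS[method](original, cohort)
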