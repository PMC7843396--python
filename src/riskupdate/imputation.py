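"""Multiple imputation by chained equations (MICE) for missing predictor values.

Each incomplete variable is imputed from a conditional model given all other
predictors *and the outcome* (including the outcome in the imputation models
is methodologically required to avoid biasing predictor-outcome associations
toward the null):

  * continuous   -> predictive mean matching (type-1: Bayesian parameter draw,
                    nearest-predicted-mean donors, default 5)
  * binary       -> logistic regression with a parameter draw, Bernoulli draw
  * categorical  -> multinomial logistic fitted on a bootstrap resample of the
                    observed rows (the resample supplies parameter
                    uncertainty), multinomial draw

Variables are visited in increasing order of missingness and cycled for a
fixed number of burn-in iterations, then the final completed table is
emitted; the whole procedure is repeated m times from independent substreams.

No installed package provides chained equations with these conditional
models, so the sampler is implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from .registry_io import YEAR, CohortTable, RegistryError


@dataclass
class ImputationSet:
    m: int
    completed: list[CohortTable]
    seed: object
    iterations: int
    methods: dict[str, str]

    def __iter__(self):
        return iter(self.completed)


def pool_scalar(estimates, variances) -> tuple[float, float]:
    """Rubin's rules: pooled estimate and total variance across m imputations."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise RegistryError("estimates and variances must have equal length")
    m = est.size
    if m < 1:
        raise RegistryError("need at least one estimate")
    qbar = float(est.mean())
    if m == 1:
        return qbar, float(var[0])
    within = float(var.mean())
    between = float(est.var(ddof=1))
    return qbar, within + (1 + 1 / m) * between


def _numeric_design(cohort: CohortTable, exclude: str) -> pd.DataFrame:
    """Expanded numeric view of all predictors except `exclude`, plus outcome."""
    X = cohort.expanded()
    drop = [c for c in X.columns if c == exclude or c.startswith(exclude + "_") or c == YEAR]
    # keep only columns not derived from the excluded variable
    var = cohort.dictionary[exclude] if exclude in cohort.dictionary else None
    if var is not None and var.type == "categorical":
        drop = [c for c in X.columns if c in var.indicator_columns() or c == YEAR]
    return X.drop(columns=[c for c in drop if c in X.columns])


def _bayes_linear_draw(Xo, yo, rng):
    """Posterior draw (beta*, sigma*) under the standard noninformative prior."""
    n, p = Xo.shape
    XtX = Xo.T @ Xo + 1e-8 * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    df = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / df
    sigma2_star = sigma2_hat * df / rng.chisquare(df)
    L = np.linalg.cholesky(0.5 * (XtX_inv + XtX_inv.T) * sigma2_star + 1e-12 * np.eye(p))
    beta_star = beta_hat + L @ rng.standard_normal(p)
    return beta_hat, beta_star


def _pmm_impute(Xo, yo, Xm, rng, donors=5):
    """Predictive mean matching: draw observed donor values whose predicted
    means (under beta_hat) are nearest the missing rows' predicted means
    (under a posterior draw beta_star)."""
    beta_hat, beta_star = _bayes_linear_draw(Xo, yo, rng)
    pred_obs = Xo @ beta_hat
    pred_mis = Xm @ beta_star
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = yo[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    k = min(donors, len(yo))
    out = np.empty(len(pred_mis))
    for i, (pm, ins) in enumerate(zip(pred_mis, pos)):
        lo = max(0, ins - k)
        hi = min(len(sorted_pred), ins + k)
        window = np.arange(lo, hi)
        dist = np.abs(sorted_pred[window] - pm)
        nearest = window[np.argsort(dist, kind="stable")[:k]]
        out[i] = sorted_y[nearest[rng.integers(0, len(nearest))]]
    return out


def _standardize(Xo, Xm):
    mu = Xo.mean(axis=0)
    sd = Xo.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xo - mu) / sd, (Xm - mu) / sd


def _fit_class_probs(Xo, labels, Xm, rng):
    """Bootstrap-refit multinomial/binary logistic; class probabilities for Xm.

    The bootstrap resample of the observed rows supplies parameter
    uncertainty (the device mice's boot-variants use) and stays well behaved
    for rare classes where the Wald covariance degenerates.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    boot = rng.integers(0, len(labels), size=len(labels))
    Xb, yb = Xo[boot], labels[boot]
    if len(np.unique(yb)) < 2:
        return None, yb[0]  # collapsed bootstrap: impute the single class
    Xb, Xs = _standardize(Xb, Xm)
    clf = LogisticRegression(max_iter=1000, C=100.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xb, yb)
    return clf.classes_, clf.predict_proba(Xs)


def _logistic_impute(Xo, yo, Xm, rng):
    classes, probs = _fit_class_probs(Xo, yo, Xm, rng)
    if classes is None:
        return np.full(len(Xm), probs, dtype=float)
    pm = probs[:, list(classes).index(1.0)]
    return (rng.random(len(pm)) < pm).astype(float)


def _multinomial_impute(Xo, labels, Xm, rng, levels):
    classes, probs = _fit_class_probs(Xo, labels, Xm, rng)
    if classes is None:
        return np.full(len(Xm), probs, dtype=object)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(Xm))[:, None]
    idx = (u > cum).sum(axis=1)
    return classes[idx]


def _impute_once(cohort: CohortTable, iterations: int, rng: np.random.Generator) -> CohortTable:
    data = cohort.data.copy()
    miss_masks = {
        name: data[name].isna().to_numpy()
        for name in cohort.predictor_names
        if data[name].isna().any()
    }
    order = sorted(miss_masks, key=lambda v: miss_masks[v].sum())

    # initial fill: random draws from the observed margin
    for name in order:
        mask = miss_masks[name]
        observed = data.loc[~mask, name].to_numpy()
        data.loc[mask, name] = observed[rng.integers(0, len(observed), size=mask.sum())]

    working = cohort.with_data(data)
    for _ in range(iterations):
        for name in order:
            mask = miss_masks[name]
            var = working.dictionary[name]
            design = _numeric_design(working, name)
            Z = design.to_numpy(dtype=float)
            Xo, Xm = Z[~mask], Z[mask]
            if var.type == "continuous":
                yo = working.data.loc[~mask, name].to_numpy(dtype=float)
                working.data.loc[mask, name] = _pmm_impute(Xo, yo, Xm, rng)
            elif var.type == "binary":
                yo = working.data.loc[~mask, name].to_numpy(dtype=float)
                working.data.loc[mask, name] = _logistic_impute(Xo, yo, Xm, rng)
            else:
                yo = working.data.loc[~mask, name].to_numpy()
                working.data.loc[mask, name] = _multinomial_impute(
                    Xo, yo, Xm, rng, var.levels
                )
    return working


def impute_mice(
    cohort: CohortTable,
    m: int = 10,
    iterations: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> ImputationSet:
    """Generate m completed cohorts; pass-through when nothing is missing."""
    if m < 1:
        raise RegistryError("m must be >= 1")
    fully_missing = [
        name for name in cohort.predictor_names if cohort.data[name].isna().all()
    ]
    if fully_missing:
        raise RegistryError(f"variable(s) 100% missing, cannot impute: {fully_missing}")

    methods = {}
    for name in cohort.predictor_names:
        if cohort.data[name].isna().any():
            methods[name] = {
                "continuous": "pmm",
                "binary": "logreg",
                "categorical": "polyreg",
            }[cohort.dictionary[name].type]

    if not methods:
        return ImputationSet(m, [cohort] * m, seed, iterations, {})

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    completed = [
        _impute_once(cohort, iterations, np.random.default_rng(child))
        for child in ss.spawn(m)
    ]
    return ImputationSet(m, completed, ss.entropy, iterations, methods)
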