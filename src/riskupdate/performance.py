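"""Discrimination, calibration and accuracy measures for binary risk predictions.

Discrimination: AU-ROC (Mann-Whitney; DeLong and bootstrap-percentile CIs,
paired DeLong comparison) and AU-PRC (step-wise average precision).
Accuracy: Brier score and Brier-skill score against the climatology forecast
(constant prediction at the observed event rate).
Calibration: the logistic-recalibration framework — the calibration slope is
the coefficient of logit(p) in a logistic refit of the outcome (ideal 1),
calibration-in-the-large is the intercept of the same refit with the slope
fixed at 1 via an offset (ideal 0) — plus grouped calibration curves.
Youden's J locates the cutoff balancing sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score

from .registry_io import RegistryError


@dataclass
class PerformanceReport:
    auroc: float
    auroc_ci: tuple[float, float]
    auprc: float
    brier: float
    brier_skill: float
    calibration_intercept: float
    calibration_intercept_ci: tuple[float, float]
    calibration_slope: float
    calibration_slope_ci: tuple[float, float]
    youden_cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    mean_predicted: float
    event_rate: float
    n: int
    events: int

    def to_dict(self) -> dict:
        return asdict(self)


def _validate(predictions, outcomes, need_both_classes=True):
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise RegistryError("predictions and outcomes must have equal length")
    if p.size == 0:
        raise RegistryError("empty input")
    if need_both_classes and (y.min() == y.max()):
        raise RegistryError("both outcome classes required")
    return p, y


def auroc(predictions, outcomes) -> float:
    """P(random event outranks random non-event), ties counted 1/2."""
    p, y = _validate(predictions, outcomes)
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = rankdata(p)  # midranks handle ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(predictions, outcomes):
    """DeLong structural components; returns (auc, var, v10, v01)."""
    p, y = _validate(predictions, outcomes)
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-event placement values
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-non-event
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n, v10, v01


def auroc_ci(
    predictions,
    outcomes,
    method: str = "delong",
    level: float = 0.95,
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Confidence interval for the AU-ROC.

    ``delong`` uses the asymptotic DeLong variance; ``bootstrap`` uses the
    percentile method over B resamples (single-class resamples are redrawn).
    Both are truncated to [0, 1].
    """
    p, y = _validate(predictions, outcomes)
    z = norm.ppf(0.5 + level / 2)
    if method == "delong":
        auc, var, _, _ = _delong_variance(p, y)
        half = z * np.sqrt(var)
        return (max(auc - half, 0.0), min(auc + half, 1.0))
    if method == "bootstrap":
        if B < 100:
            raise RegistryError("bootstrap CI needs B >= 100")
        rng = np.random.default_rng(seed)
        stats = np.empty(B)
        for b in range(B):
            while True:
                idx = rng.integers(0, y.size, size=y.size)
                if y[idx].min() != y[idx].max():
                    break
            stats[b] = auroc(p[idx], y[idx])
        lo, hi = np.percentile(stats, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
        return (float(lo), float(hi))
    raise RegistryError(f"unknown CI method {method!r}")


def compare_auroc(pred_a, pred_b, outcomes) -> tuple[float, float]:
    """Paired DeLong test: (AUC_a - AUC_b, two-sided p-value)."""
    pa, y = _validate(pred_a, outcomes)
    pb, y2 = _validate(pred_b, outcomes)
    if pa.shape != pb.shape:
        raise RegistryError("prediction vectors must cover the same patients")
    auc_a, _, v10a, v01a = _delong_variance(pa, y)
    auc_b, _, v10b, v01b = _delong_variance(pb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(v10a, v10b, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01a, v01b, ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    delta = auc_a - auc_b
    if var <= 0:
        return (float(delta), 1.0 if abs(delta) < 1e-12 else 0.0)
    zstat = delta / np.sqrt(var)
    return (float(delta), float(2 * norm.sf(abs(zstat))))


def auprc(predictions, outcomes) -> float:
    """Area under the precision-recall curve, step-wise (average precision)."""
    p, y = _validate(predictions, outcomes, need_both_classes=False)
    if y.sum() == 0:
        raise RegistryError("AU-PRC undefined without events")
    if y.min() == y.max():  # all events
        return 1.0
    return float(average_precision_score(y, p))


def brier(predictions, outcomes) -> float:
    p, y = _validate(predictions, outcomes, need_both_classes=False)
    if ((p < 0) | (p > 1)).any():
        raise RegistryError("predictions must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def brier_skill(predictions, outcomes) -> float:
    """1 - Brier / Brier_ref with the climatology reference ybar(1-ybar)."""
    p, y = _validate(predictions, outcomes, need_both_classes=False)
    ref = y.mean() * (1 - y.mean())
    if ref == 0:
        raise RegistryError("Brier-skill undefined for single-class outcomes")
    return float(1.0 - brier(p, y) / ref)


def calibration_cox(predictions, outcomes, level: float = 0.95):
    """Calibration intercept and slope with Wald CIs.

    slope: b from logistic y ~ a + b*logit(p)  (ideal 1)
    intercept: a from logistic y ~ a + offset(logit(p))  (ideal 0)
    """
    p, y = _validate(predictions, outcomes)
    if ((p <= 0) | (p >= 1)).any():
        p = np.clip(p, 1e-12, 1 - 1e-12)
    lp = logit(p)
    z = norm.ppf(0.5 + level / 2)

    res_int = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Binomial(), offset=lp).fit()
    a = float(res_int.params[0])
    a_se = float(res_int.bse[0])
    intercept_ci = (a - z * a_se, a + z * a_se)

    if np.ptp(lp) < 1e-12:
        raise RegistryError(
            "degenerate (constant) logit: calibration slope unidentifiable"
        )
    res_slope = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    b = float(res_slope.params[1])
    b_se = float(res_slope.bse[1])
    slope_ci = (b - z * b_se, b + z * b_se)
    return a, b, intercept_ci, slope_ci


def calibration_curve(predictions, outcomes, groups: int = 10):
    """Grouped observed-vs-predicted table (equal-count groups, binomial CIs).

    Returns a DataFrame with one row per (possibly merged) group.  Groups
    whose prediction quantiles collapse are merged with their neighbour.
    """
    import pandas as pd
    from statsmodels.stats.proportion import proportion_confint

    p, y = _validate(predictions, outcomes, need_both_classes=False)
    if groups < 2:
        raise RegistryError("need at least 2 groups")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, groups + 1)))
    if len(edges) < 3:  # nearly constant predictions: single group
        edges = np.array([p.min() - 1e-9, p.max() + 1e-9])
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for g in range(len(edges) - 1):
        mask = idx == g
        if mask.sum() == 0:
            continue
        ng = int(mask.sum())
        events = int(y[mask].sum())
        lo, hi = proportion_confint(events, ng, method="wilson")
        rows.append(
            {
                "group": g,
                "n": ng,
                "mean_predicted": float(p[mask].mean()),
                "observed_rate": float(events / ng),
                "events": events,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def plot_calibration(predictions, outcomes, groups: int = 10, path=None, title=None):
    """Calibration graph: grouped observed vs predicted with a lowess overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from statsmodels.nonparametric.smoothers_lowess import lowess

    table = calibration_curve(predictions, outcomes, groups)
    p, y = _validate(predictions, outcomes, need_both_classes=False)
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = max(table["mean_predicted"].max(), table["observed_rate"].max()) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="ideal")
    ax.errorbar(
        table["mean_predicted"],
        table["observed_rate"],
        yerr=[
            table["observed_rate"] - table["ci_low"],
            table["ci_high"] - table["observed_rate"],
        ],
        fmt="o",
        capsize=3,
        label="grouped",
    )
    smooth = lowess(y, p, frac=0.6, return_sorted=True)
    ax.plot(smooth[:, 0], smooth[:, 1], "-", color="C1", label="smoothed")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed early-mortality")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return table, fig


def youden_cutoff(predictions, outcomes) -> tuple[float, float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    The scan runs over observed prediction values (classify positive when
    p >= t); ties resolve to the lowest optimal threshold.
    """
    p, y = _validate(predictions, outcomes)
    n1 = y.sum()
    n0 = y.size - n1
    best = (-np.inf, np.inf, 0.0, 0.0)
    for t in np.unique(p):
        pred_pos = p >= t
        sens = float((y[pred_pos] == 1).sum() / n1)
        spec = float((y[~pred_pos] == 0).sum() / n0)
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    j, t, sens, spec = best
    return float(t), float(j), sens, spec


def performance_report(
    predictions,
    outcomes,
    ci_method: str = "delong",
    seed: int | np.random.SeedSequence = 0,
) -> PerformanceReport:
    """The full metric suite on one prediction vector."""
    p, y = _validate(predictions, outcomes)
    auc = auroc(p, y)
    ci = auroc_ci(p, y, method=ci_method, seed=seed)
    a, b, a_ci, b_ci = calibration_cox(p, y)
    cutoff, j, sens, spec = youden_cutoff(p, y)
    return PerformanceReport(
        auroc=auc,
        auroc_ci=ci,
        auprc=auprc(p, y),
        brier=brier(p, y),
        brier_skill=brier_skill(p, y),
        calibration_intercept=a,
        calibration_intercept_ci=a_ci,
        calibration_slope=b,
        calibration_slope_ci=b_ci,
        youden_cutoff=cutoff,
        youden_j=j,
        sensitivity=sens,
        specificity=spec,
        mean_predicted=float(p.mean()),
        event_rate=float(y.mean()),
        n=int(y.size),
        events=int(y.sum()),
    )


def average_reports(reports: list[PerformanceReport]) -> dict:
    """Arithmetic mean of each metric across imputed datasets (the pooled
    point estimate reported downstream)."""
    keys = [
        "auroc",
        "auprc",
        "brier",
        "brier_skill",
        "calibration_intercept",
        "calibration_slope",
        "youden_j",
        "mean_predicted",
        "event_rate",
    ]
    return {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
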