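"""Baseline characteristics stratified by 30-day mortality.

Produces the registry-style descriptive table: per variable (or category)
the total count, counts among survivors and deaths, the risk of early
mortality (deaths / total x 100, one decimal), and a univariable p-value —
t-test or Mann-Whitney for continuous variables depending on a normality
screen, chi-squared or Fisher exact for categorical ones depending on the
expected-count rule.  Computed on the unimputed cohort, complete-case per
variable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .registry_io import CohortTable, RegistryError


def risk_of_early_mortality(deaths: int, total: int) -> float:
    """100 * deaths / total, rounded to one decimal."""
    if total <= 0:
        raise RegistryError("risk undefined for an empty category")
    if not 0 <= deaths <= total:
        raise RegistryError("deaths must lie in [0, total]")
    return round(100.0 * deaths / total, 1)


def compare_continuous(
    values_by_group: tuple[np.ndarray, np.ndarray],
    normality_alpha: float = 0.05,
    force: str | None = None,
) -> tuple[float, float, str]:
    """Two-group comparison: t-test if both groups pass a Shapiro screen,
    otherwise Mann-Whitney.  Returns (statistic, p, test name)."""
    g0, g1 = (np.asarray(g, dtype=float) for g in values_by_group)
    g0, g1 = g0[~np.isnan(g0)], g1[~np.isnan(g1)]
    if len(g0) < 2 or len(g1) < 2:
        raise RegistryError("each group needs n >= 2")
    if np.ptp(g0) == 0 and np.ptp(g1) == 0:
        import warnings

        warnings.warn("zero variance in both groups; p = 1", stacklevel=2)
        return 0.0, 1.0, "degenerate"

    def _normal(g):
        if np.ptp(g) == 0:
            return False
        # shapiro caps at n=5000; a subsample keeps the screen usable
        sample = g if len(g) <= 5000 else np.sort(g)[:: len(g) // 5000 + 1]
        return stats.shapiro(sample).pvalue > normality_alpha

    use_t = force == "t" if force else (_normal(g0) and _normal(g1))
    if force == "mannwhitney":
        use_t = False
    if use_t:
        if np.array_equal(np.sort(g0), np.sort(g1)):
            return 0.0, 1.0, "t-test"
        res = stats.ttest_ind(g0, g1, equal_var=False)
        return float(res.statistic), float(res.pvalue), "t-test"
    res = stats.mannwhitneyu(g0, g1, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), "mann-whitney"


def compare_categorical(contingency: np.ndarray) -> tuple[float, float, str]:
    """Chi-squared (no continuity correction) when every expected count >= 5;
    otherwise Fisher exact for 2x2, chi-squared with a warning for wider
    tables.  Returns (statistic, p, test name)."""
    table = np.asarray(contingency, dtype=float)
    if table.size == 0 or table.sum() == 0:
        raise RegistryError("empty contingency table")
    if (table.sum(axis=1) == 0).any():
        raise RegistryError("both outcome margins must be positive")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected >= 5).all():
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p), "chi-squared"
    if table.shape == (2, 2):
        res = stats.fisher_exact(table)
        return float(res[0]), float(res[1]), "fisher"
    import warnings

    warnings.warn("low expected counts in a 2xc table; chi-squared approximate", stacklevel=2)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), "chi-squared (low counts)"


def baseline_table(cohort: CohortTable, variables: list[str] | None = None) -> pd.DataFrame:
    """One row per variable (or per category of a categorical variable).

    Variables absent from the cohort yield a row marked "N.A."; continuous
    rows carry mean (SD) per outcome group instead of counts.
    """
    y = cohort.outcome.astype(bool)
    n = cohort.n
    n_dead = int(y.sum())
    n_alive = n - n_dead
    variables = variables or cohort.predictor_names
    rows: list[dict] = []

    rows.append(
        {
            "variable": "overall",
            "category": "",
            "total": n,
            "alive": n_alive,
            "dead": n_dead,
            "risk": risk_of_early_mortality(n_dead, n),
            "p_value": np.nan,
            "test": "",
            "summary": f"n={n}",
        }
    )

    for name in variables:
        if name not in cohort.data.columns:
            rows.append(
                {"variable": name, "category": "N.A.", "total": np.nan, "alive": np.nan,
                 "dead": np.nan, "risk": np.nan, "p_value": np.nan, "test": "N.A.", "summary": "N.A."}
            )
            continue
        var = cohort.dictionary[name] if name in cohort.dictionary else None
        col = cohort.data[name]
        observed = ~col.isna().to_numpy()
        if var is not None and var.type == "continuous":
            vals = col.to_numpy(dtype=float)
            g_alive = vals[observed & ~y]
            g_dead = vals[observed & y]
            stat, p, test = compare_continuous((g_alive, g_dead))
            rows.append(
                {
                    "variable": name,
                    "category": "mean (SD)",
                    "total": int(observed.sum()),
                    "alive": len(g_alive),
                    "dead": len(g_dead),
                    "risk": np.nan,
                    "p_value": p,
                    "test": test,
                    "summary": (
                        f"{np.mean(vals[observed]):.1f} ({np.std(vals[observed], ddof=1):.2f}) | "
                        f"alive {g_alive.mean():.1f} | dead {g_dead.mean():.1f}"
                    ),
                }
            )
            continue

        if var is not None and var.type == "categorical":
            levels = list(var.levels)
        else:
            levels = [1.0]  # binary: report the "yes" row
        # contingency: outcome x category over complete cases
        if var is not None and var.type == "categorical":
            counts = np.array(
                [
                    [int(((col == lv).to_numpy() & observed & ~y).sum()) for lv in levels],
                    [int(((col == lv).to_numpy() & observed & y).sum()) for lv in levels],
                ]
            )
        else:
            vals = col.to_numpy(dtype=float)
            counts = np.array(
                [
                    [int(((vals == 0) & observed & ~y).sum()), int(((vals == 1) & observed & ~y).sum())],
                    [int(((vals == 0) & observed & y).sum()), int(((vals == 1) & observed & y).sum())],
                ]
            )
        try:
            stat, p, test = compare_categorical(counts)
        except RegistryError:
            stat, p, test = np.nan, np.nan, "n/a"

        if var is not None and var.type == "categorical":
            for j, lv in enumerate(levels):
                total = int(counts[:, j].sum())
                dead = int(counts[1, j])
                rows.append(
                    {
                        "variable": name,
                        "category": str(lv),
                        "total": total,
                        "alive": total - dead,
                        "dead": dead,
                        "risk": risk_of_early_mortality(dead, total) if total else np.nan,
                        "p_value": p if j == 0 else np.nan,
                        "test": test if j == 0 else "",
                        "summary": f"{total} ({100 * total / n:.1f})",
                    }
                )
        else:
            total = int(counts[:, 1].sum())
            dead = int(counts[1, 1])
            rows.append(
                {
                    "variable": name,
                    "category": "yes",
                    "total": total,
                    "alive": total - dead,
                    "dead": dead,
                    "risk": risk_of_early_mortality(dead, total) if total else np.nan,
                    "p_value": p,
                    "test": test,
                    "summary": f"{total} ({100 * total / n:.1f})",
                }
            )
    return pd.DataFrame(rows)
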