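"""Closed-testing selection of the update method.

A nested sequence of likelihood-ratio tests picks the least extensive update
supported by the data while approximately preserving the overall type-I
error rate.  The published model is the zero-free-parameter baseline; the
candidates add 1 (intercept), 2 (intercept+slope) or p+1 (full revision)
free parameters, so their maximised log-likelihoods are monotone:

    l(original) <= l(intercept) <= l(recalibration) <= l(revision)

Test sequence (all statistics 2*delta-l against chi-square):

    1. revision vs original      df p+1   not significant -> no_update
    2. revision vs recalibration df p-1   significant     -> revision
    3. recalibration vs intercept df 1    significant     -> recalibration
    4. intercept vs original      df 1    significant     -> intercept
                                          else            -> no_update
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import chi2

from . import model_core
from .imputation import ImputationSet
from .registry_io import CohortTable, ModelSpec

#: selection order from least to most extensive
EXTENSIVENESS = {"no_update": 0, "intercept": 1, "recalibration": 2, "revision": 3}


@dataclass
class UpdateSelection:
    selected: str
    log_likelihoods: dict[str, float]
    free_dfs: dict[str, int]
    tests: list[dict]  # each: {comparison, statistic, df, p_value}
    alpha: float
    fits: dict[str, model_core.UpdatedModel] = field(repr=False, default_factory=dict)
    per_imputation: list["UpdateSelection"] | None = None

    @property
    def model(self) -> model_core.UpdatedModel:
        return self.fits[self.selected]


def _lr_test(ll_big: float, ll_small: float, df: int) -> tuple[float, float]:
    stat = max(2.0 * (ll_big - ll_small), 0.0)
    return stat, float(chi2.sf(stat, df))


def closed_test(original: ModelSpec, cohort: CohortTable, alpha: float = 0.05) -> UpdateSelection:
    """Run the full closed-testing procedure on one complete cohort."""
    fits = {
        "no_update": model_core.evaluate_original(original, cohort),
        "intercept": model_core.update_intercept(original, cohort),
        "recalibration": model_core.update_recalibrate(original, cohort),
        "revision": model_core.update_revise(original, cohort),
    }
    ll = {k: v.log_likelihood for k, v in fits.items()}
    dfs = {k: v.free_df for k, v in fits.items()}
    # effective p: free coefficients of the revision fit (constant columns
    # such as an all-absent predictor carry no estimable coefficient)
    p = dfs["revision"] - 1
    tests: list[dict] = []

    def record(name, big, small, df):
        stat, pval = _lr_test(ll[big], ll[small], df)
        tests.append({"comparison": name, "statistic": stat, "df": df, "p_value": pval})
        return pval

    selected = "no_update"
    if record("revision_vs_original", "revision", "no_update", p + 1) < alpha:
        # evidence of some miscalibration; step down from the most extensive
        rev_vs_recal_df = p - 1
        if rev_vs_recal_df > 0:
            rev_sig = record(
                "revision_vs_recalibration", "revision", "recalibration", rev_vs_recal_df
            ) < alpha
        else:
            # p = 1: revision and recalibration coincide, step skipped
            rev_sig = False
        if rev_sig:
            selected = "revision"
        elif record("recalibration_vs_intercept", "recalibration", "intercept", 1) < alpha:
            selected = "recalibration"
        elif record("intercept_vs_original", "intercept", "no_update", 1) < alpha:
            selected = "intercept"
    return UpdateSelection(selected, ll, dfs, tests, alpha, fits)


def majority_vote(selections: list[str]) -> str:
    """Most frequent method; ties resolve toward the less extensive one."""
    votes: dict[str, int] = {}
    for s in selections:
        votes[s] = votes.get(s, 0) + 1
    return max(votes, key=lambda k: (votes[k], -EXTENSIVENESS[k]))


def closed_test_mi(
    original: ModelSpec, imputations: ImputationSet, alpha: float = 0.05
) -> UpdateSelection:
    """Closed test per completed dataset; majority vote across the m copies,
    ties broken toward the less extensive method."""
    per = [closed_test(original, completed, alpha) for completed in imputations]
    winner = majority_vote([sel.selected for sel in per])
    # representative fit detail: the first imputation that chose the winner
    representative = next(s for s in per if s.selected == winner)
    return UpdateSelection(
        selected=winner,
        log_likelihoods=representative.log_likelihoods,
        free_dfs=representative.free_dfs,
        tests=representative.tests,
        alpha=alpha,
        fits=representative.fits,
        per_imputation=per,
    )
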