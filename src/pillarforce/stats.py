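"""Thin wrappers around the group-comparison tests used across the assays.

All assays compare independent groups at alpha = 0.05: Welch two-sample
t-tests for pairwise strength/thrash contrasts, one-way ANOVA with Tukey HSD
for the multi-group OCR contrasts, two-way ANOVA for the temperature design,
and a split-plot (mixed-design) repeated-measures ANOVA for the paralysis
time-courses.  The split-plot decomposition is coded here directly because
the standard repeated-measures helpers do not handle a between-subject
factor; everything else delegates to scipy/statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

__all__ = [
    "ALPHA",
    "WelchResult",
    "welch_ttest",
    "OneWayAnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "MixedAnovaResult",
    "mixed_design_anova",
]


@dataclass(frozen=True)
class WelchResult:
    mean_a: float
    mean_b: float
    mean_diff: float
    percent_of_reference: float
    t_stat: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


def welch_ttest(a, b) -> WelchResult:
    """Welch (unequal-variance) two-sample t-test, two-sided.

    The effect is also reported as percent of the reference (first) group
    mean.  A zero-variance cohort at n=2 is degenerate; the p-value is
    reported as computed, with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs at least 2 samples")
    if (np.var(a) == 0 and len(a) == 2) or (np.var(b) == 0 and len(b) == 2):
        warnings.warn("zero-variance cohort with n=2; test is degenerate")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, equal_var=False)
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    diff = mean_b - mean_a
    pct = 100.0 * diff / mean_a if mean_a != 0 else np.nan
    return WelchResult(mean_a, mean_b, diff, pct, float(t), float(p), len(a), len(b))


@dataclass(frozen=True)
class OneWayAnovaResult:
    f_stat: float
    p_value: float
    group_means: dict
    tukey: pd.DataFrame | None

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


def one_way_anova(groups: dict, with_tukey: bool = False) -> OneWayAnovaResult:
    """One-way ANOVA over a ``{label: samples}`` mapping.

    ``with_tukey=True`` adds Tukey's multiple-comparison table for all
    pairwise contrasts.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    f, p = sps.f_oneway(*arrays)
    means = {k: float(np.mean(v)) for k, v in zip(labels, arrays)}
    tukey = tukey_hsd(groups) if with_tukey else None
    return OneWayAnovaResult(float(f), float(p), means, tukey)


def tukey_hsd(groups: dict) -> pd.DataFrame:
    """Tukey HSD pairwise table with columns group1, group2, meandiff,
    p_adj, reject."""
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in groups])
    labels = np.concatenate([[k] * len(groups[k]) for k in groups])
    res = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )


@dataclass(frozen=True)
class MixedAnovaResult:
    """Split-plot ANOVA: one between-subject factor, one within (time)."""

    f_between: float
    p_between: float
    f_within: float
    p_within: float
    f_interaction: float
    p_interaction: float
    df: dict


def mixed_design_anova(data_by_group: dict) -> MixedAnovaResult:
    """Mixed-design (split-plot) ANOVA on ``{group: (n_subjects, n_times)}``.

    Subjects are nested in groups; time is the repeated (within-subject)
    factor.  The between-group F uses the subjects-within-groups mean square
    as its error term; time and group-by-time use the within-subject
    residual.  Groups must be balanced (equal subject counts and a common
    time grid).
    """
    mats = [np.asarray(v, dtype=float) for v in data_by_group.values()]
    if len(mats) < 2:
        raise ValueError("need at least 2 groups")
    n = mats[0].shape[0]
    t = mats[0].shape[1]
    if any(m.shape != (n, t) for m in mats):
        raise ValueError("groups must be balanced with a common time grid")
    g = len(mats)
    y = np.stack(mats)  # (g, n, t)
    grand = y.mean()
    subj_means = y.mean(axis=2)  # (g, n)
    group_means = y.mean(axis=(1, 2))  # (g,)
    time_means = y.mean(axis=(0, 1))  # (t,)
    cell_means = y.mean(axis=1)  # (g, t)

    ss_total = ((y - grand) ** 2).sum()
    ss_group = n * t * ((group_means - grand) ** 2).sum()
    ss_subj = t * ((subj_means - group_means[:, None]) ** 2).sum()
    ss_time = g * n * ((time_means - grand) ** 2).sum()
    ss_inter = n * (
        (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
    ).sum()
    ss_error = ss_total - ss_group - ss_subj - ss_time - ss_inter

    df_group = g - 1
    df_subj = g * (n - 1)
    df_time = t - 1
    df_inter = (g - 1) * (t - 1)
    df_error = g * (n - 1) * (t - 1)

    ms = lambda ss, df: ss / df if df > 0 else np.nan
    ms_subj = ms(ss_subj, df_subj)
    ms_error = ms(ss_error, df_error)

    def ftest(ss, df, ms_err, df_err):
        if ms_err <= 0 or df <= 0:
            return np.nan, np.nan
        f = ms(ss, df) / ms_err
        return float(f), float(sps.f.sf(f, df, df_err))

    f_g, p_g = ftest(ss_group, df_group, ms_subj, df_subj)
    f_t, p_t = ftest(ss_time, df_time, ms_error, df_error)
    f_i, p_i = ftest(ss_inter, df_inter, ms_error, df_error)
    return MixedAnovaResult(
        f_g, p_g, f_t, p_t, f_i, p_i,
        df={
            "between": (df_group, df_subj),
            "within": (df_time, df_error),
            "interaction": (df_inter, df_error),
        },
    )
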