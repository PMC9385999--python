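"""Group statistics: two-way mixed-design ANOVA and two-sample t-tests.

``rm_anova`` implements the classical balanced decomposition for one
between-subjects factor (e.g. genotype) crossed with one within-subjects
factor (intensity, frequency, or age): the between effect is tested against
the subjects-within-groups stratum, the within effect and the interaction
against the subject-by-factor residual. Bonferroni post-hoc comparisons test
the between-groups contrast at each within-factor level, the family being the
set of per-level comparisons. Sphericity corrections are not applied by
default (a mixed-design convention when uncorrected degrees of freedom are
reported); no correction flag is needed for two within levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from otokit._common import UnbalancedDesignError

__all__ = ["AnovaReport", "TTestResult", "rm_anova", "two_sample_t", "bonferroni"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class AnovaReport:
    """F table (one row per effect/error stratum) plus Bonferroni post-hocs."""

    table: pd.DataFrame
    posthoc: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("source").loc[name]


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p); never below the raw p."""
    if m < 1:
        raise ValueError("family size must be at least 1")
    return float(min(1.0, m * p_raw))


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sample t-test, Student (pooled variance) by default, Welch behind a flag.

    Degenerate zero-variance groups follow the conventions: equal means give
    t = 0, p = 1; unequal means give an infinite-t sentinel with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(t=sign * float("inf"), df=df, p=0.0)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def _validate_long_table(
    data: pd.DataFrame, dv: str, between: str, within: str, subject: str
) -> pd.DataFrame:
    for col in (dv, between, within, subject):
        if col not in data.columns:
            raise UnbalancedDesignError(f"column '{col}' missing from table")
    d = data[[subject, between, within, dv]].copy()
    if d[dv].isna().any():
        raise UnbalancedDesignError("missing values in the dependent variable")
    if (d.groupby(subject)[between].nunique() > 1).any():
        raise UnbalancedDesignError("a subject appears in more than one group")
    counts = d.groupby([subject, within]).size()
    if (counts != 1).any():
        raise UnbalancedDesignError("each subject needs exactly one value per level")
    levels = d[within].nunique()
    per_subject = d.groupby(subject)[within].nunique()
    if (per_subject != levels).any():
        raise UnbalancedDesignError("each subject must be measured at every level")
    if levels < 2 or d[between].nunique() < 2:
        raise UnbalancedDesignError("need at least two levels of each factor")
    if (d.groupby(between)[subject].nunique() < 2).any():
        raise UnbalancedDesignError("need at least two subjects per group")
    return d


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "genotype",
    within: str = "level",
    subject: str = "subject",
    listwise: bool = False,
) -> AnovaReport:
    """Two-way mixed-design ANOVA with Bonferroni post-hoc group comparisons.

    ``data`` is a long table with one row per (subject, within-level). The
    design must be complete per subject; set ``listwise`` to drop subjects
    with incomplete grids instead of raising. Group sizes may differ.

    The sums of squares satisfy the exact identity
    ``SS_total = SS_between + SS_subjects_within + SS_within + SS_interaction
    + SS_residual`` (asserted by the test suite to 1e-8 relative).
    """
    if listwise:
        levels = data[within].nunique()
        complete = data.groupby(subject)[within].transform("nunique") == levels
        sizes = data.groupby(subject)[within].transform("size") == levels
        data = data[complete & sizes]
    d = _validate_long_table(data, dv, between, within, subject)

    grand = d[dv].mean()
    p = d[within].nunique()
    groups = d[between].unique()
    n_subjects = d[subject].nunique()
    n_g = d.groupby(between)[subject].nunique()

    subj_means = d.groupby(subject)[dv].mean()
    subj_group = d.groupby(subject)[between].first()
    group_means = d.groupby(between)[dv].mean()
    level_means = d.groupby(within)[dv].mean()
    cell_means = d.groupby([between, within])[dv].mean()

    ss_between = p * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in groups)
    ss_subjects = p * sum(
        (subj_means[s] - group_means[subj_group[s]]) ** 2 for s in subj_means.index
    )
    ss_within = n_subjects * float(((level_means - grand) ** 2).sum())
    ss_cells_w = sum(
        n_g[g] * (cell_means[(g, b)] - group_means[g]) ** 2
        for g in groups
        for b in level_means.index
    )
    ss_interaction = ss_cells_w - ss_within
    centered = (
        d[dv]
        - d[subject].map(subj_means)
        - pd.MultiIndex.from_arrays([d[between], d[within]]).map(cell_means)
        + d[between].map(group_means)
    )
    ss_residual = float((centered**2).sum())
    # snap float-cancellation dust to zero so exact null effects report F = 0
    ss_total = float(((d[dv] - grand) ** 2).sum())
    tol = 1e-12 * max(ss_total, 1.0)
    ss_between, ss_subjects, ss_within, ss_interaction, ss_residual = (
        0.0 if abs(s) < tol else s
        for s in (ss_between, ss_subjects, ss_within, ss_interaction, ss_residual)
    )

    g = len(groups)
    df_between, df_subj = g - 1, n_subjects - g
    df_within = p - 1
    df_inter = (g - 1) * (p - 1)
    df_resid = (n_subjects - g) * (p - 1)

    def ms(ss, df):
        return ss / df if df > 0 else np.nan

    def f_ratio(ms_effect, ms_error):
        # a zero error stratum with a zero effect is read as "no effect"
        if not np.isfinite(ms_error) or ms_error == 0:
            return 0.0 if ms_effect == 0 else float("inf")
        return ms_effect / ms_error

    ms_subj = ms(ss_subjects, df_subj)
    ms_resid = ms(ss_residual, df_resid)
    rows = [
        ("between", ss_between, df_between, ms(ss_between, df_between),
         f_ratio(ms(ss_between, df_between), ms_subj), df_subj),
        ("subjects_within_groups", ss_subjects, df_subj, ms_subj, np.nan, np.nan),
        ("within", ss_within, df_within, ms(ss_within, df_within),
         f_ratio(ms(ss_within, df_within), ms_resid), df_resid),
        ("interaction", ss_interaction, df_inter, ms(ss_interaction, df_inter),
         f_ratio(ms(ss_interaction, df_inter), ms_resid), df_resid),
        ("residual", ss_residual, df_resid, ms_resid, np.nan, np.nan),
    ]
    table = pd.DataFrame(
        rows, columns=["source", "ss", "df", "ms", "F", "df_error"]
    )
    table["p"] = [
        float(sps.f.sf(f, dfn, dfe)) if np.isfinite(f) else np.nan
        for f, dfn, dfe in zip(table["F"], table["df"], table["df_error"])
    ]

    # Bonferroni family: the per-level pairwise group comparisons
    if len(groups) > 2:
        raise UnbalancedDesignError("post-hoc comparisons support exactly two groups")
    level_order = sorted(level_means.index)
    m = len(level_order)
    post_rows = []
    ga, gb = sorted(groups)
    for b in level_order:
        xa = d.loc[(d[between] == ga) & (d[within] == b), dv].to_numpy()
        xb = d.loc[(d[between] == gb) & (d[within] == b), dv].to_numpy()
        res = two_sample_t(xa, xb)
        post_rows.append(
            {
                "level": b,
                "comparison": f"{ga} vs {gb}",
                "t": res.t,
                "df": res.df,
                "p_raw": res.p,
                "p_bonferroni": bonferroni(res.p, m),
            }
        )
    return AnovaReport(table=table, posthoc=pd.DataFrame(post_rows))
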