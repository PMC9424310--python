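"""Group-level inferential statistics for the figure-style comparisons.

Provides the two tests used throughout the analyses: a two-way
mixed-design (split-plot) ANOVA with genotype group as the
between-subject factor and time (day, hour or circadian bin) as the
repeated within-subject factor, and the two-sample Kolmogorov-Smirnov
test for comparing per-subject parameter distributions.

The ANOVA is computed from the classical balanced-design sums of
squares: the group effect is tested against the subject-within-group
mean square, the time and interaction effects against the residual
(subject-by-time) mean square.  No sphericity correction is applied;
F ratios are reported uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import ks_2samp

__all__ = ["AnovaResult", "two_way_repeated_anova", "ks_two_sample"]


@dataclass(frozen=True)
class AnovaResult:
    factor: str  # "GROUP" | "TIME" | "INTERACTION"
    F: float
    p: float
    df: tuple[int, int]


def two_way_repeated_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    group: str = "group",
    time: str = "time",
) -> pd.DataFrame:
    """Mixed-design ANOVA: between-subject ``group`` x repeated ``time``.

    Requires a complete subject-by-time grid (every subject measured at
    every time level exactly once) and at least two subjects per group;
    incomplete designs are rejected with an explicit error rather than
    silently imputed.

    Returns a DataFrame with one row per factor (GROUP, TIME,
    INTERACTION): F, p and the degrees-of-freedom pair.
    """
    d = data[[subject, group, time, dv]].dropna(subset=[dv])

    times = sorted(d[time].unique(), key=str)
    subjects = d[subject].unique()
    T = len(times)
    S = len(subjects)
    counts = d.groupby([subject, time], sort=False).size()
    if (counts != 1).any() or len(counts) != S * T:
        raise ValueError(
            "unbalanced design: every subject must have exactly one value at "
            "every time level (drop incomplete subjects or time levels first)"
        )
    subj_group = d.groupby(subject)[group].nunique()
    if (subj_group != 1).any():
        raise ValueError("each subject must belong to exactly one group")
    group_sizes = d.drop_duplicates(subject).groupby(group).size()
    a = len(group_sizes)
    if a < 2 or (group_sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    if T < 2:
        raise ValueError("need >= 2 time levels for a repeated-measures factor")

    y = d[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    m_subj = d.groupby(subject)[dv].mean()
    ss_between_subj = float(T * ((m_subj - grand) ** 2).sum())

    m_group = d.groupby(group)[dv].mean()
    n_g = group_sizes
    ss_group = float((T * n_g * (m_group - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group

    m_time = d.groupby(time)[dv].mean()
    ss_time = float(S * ((m_time - grand) ** 2).sum())

    m_cell = d.groupby([group, time])[dv].mean()
    ss_cells = float(
        sum(
            n_g[g] * (m_cell[(g, t)] - grand) ** 2
            for g in n_g.index
            for t in times
        )
    )
    ss_inter = ss_cells - ss_group - ss_time
    ss_within_subj = ss_total - ss_between_subj
    ss_error = ss_within_subj - ss_time - ss_inter

    df_group, df_subj = a - 1, S - a
    df_time = T - 1
    df_inter = (a - 1) * (T - 1)
    df_error = (S - a) * (T - 1)

    def f_row(name, ss, df1, ss_err, df2):
        ms, ms_err = ss / df1, ss_err / df2
        F = ms / ms_err if ms_err > 0 else np.inf
        p = float(f_dist.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        return {"factor": name, "F": float(F), "p": p, "df1": df1, "df2": df2,
                "SS": float(ss), "SS_error": float(ss_err)}

    rows = [
        f_row("GROUP", ss_group, df_group, ss_subj_within, df_subj),
        f_row("TIME", ss_time, df_time, ss_error, df_error),
        f_row("INTERACTION", ss_inter, df_inter, ss_error, df_error),
    ]
    return pd.DataFrame(rows)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Standard two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
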