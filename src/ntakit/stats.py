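"""Tidy statistics for total-particle tables.

The workflow the toolkit supports ends with one total concentration per
biological replicate; this module screens those totals for normality
(Shapiro–Wilk per group, with a parametric / non-parametric
suggestion), compares groups by one-way ANOVA, follows up with
Tukey–Kramer pairwise comparisons (valid for unequal group sizes), and
offers Welch's t-test for two-group designs.

All functions take a tidy table plus column names and return tidy
tables (or a small dataclass), so their outputs feed straight into
plotting or CSV export.  Tail probabilities come from scipy's F and
studentized-range distributions; the decompositions themselves are
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateError, GroupCountError, SampleSizeError

__all__ = [
    "AnovaTable",
    "WelchResult",
    "nano_shapiro",
    "one_way_anova",
    "nano_tukey",
    "welch_t",
]


def _groups(table: pd.DataFrame, group_key: str, value_col: str):
    """Ordered (label, values) pairs; categorical level order respected."""
    for c in (group_key, value_col):
        if c not in table.columns:
            raise KeyError(f"column {c!r} not in table")
    g = table.groupby(group_key, observed=True, sort=True)[value_col]
    return [(label, np.asarray(v, dtype=float)) for label, v in g]


def nano_shapiro(
    table: pd.DataFrame,
    group_key: str,
    value_col: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Shapiro–Wilk normality screen per group.

    Returns one row per group with the W statistic, the p-value and a
    ``suggestion`` ("parametric" iff p > alpha), plus a final
    ``overall`` row suggesting a parametric test only when every group
    passes.  Requires 3..5000 observations per group with nonzero
    variance.
    """
    records = []
    all_parametric = True
    for label, values in _groups(table, group_key, value_col):
        n = values.size
        if n < 3:
            raise SampleSizeError(
                f"group {label!r} has {n} observations; Shapiro–Wilk needs >= 3"
            )
        if n > 5000:
            raise SampleSizeError(
                f"group {label!r} has {n} observations; Shapiro–Wilk is "
                "unreliable above 5000"
            )
        if np.ptp(values) == 0:
            raise DegenerateError(
                f"group {label!r} has zero variance; normality is undefined"
            )
        w, p = sps.shapiro(values)
        parametric = p > alpha
        all_parametric &= parametric
        records.append(
            {"group": label, "W": float(w), "p": float(p),
             "suggestion": "parametric" if parametric else "non-parametric"}
        )
    records.append(
        {"group": "overall", "W": np.nan, "p": np.nan,
         "suggestion": "parametric" if all_parametric else "non-parametric"}
    )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class AnovaTable:
    """One-way ANOVA decomposition.

    ``ss_between + ss_within`` equals the total sum of squares;
    ``F = ms_between / ms_within`` is referred to the
    F(df_between, df_within) upper tail.
    """

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p: float

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["between", "within"],
                "df": [self.df_between, self.df_within],
                "sum_sq": [self.ss_between, self.ss_within],
                "mean_sq": [self.ms_between, self.ms_within],
                "F": [self.F, np.nan],
                "p": [self.p, np.nan],
            }
        )


def one_way_anova(table: pd.DataFrame, group_key: str, value_col: str) -> AnovaTable:
    """Fixed-effects one-way analysis of variance.

    Needs k >= 2 groups and at least one within-group degree of
    freedom.  All-identical values give F = 0, p = 1 rather than an
    error (0/0 mean squares are resolved in favour of "no signal").
    """
    groups = _groups(table, group_key, value_col)
    k = len(groups)
    if k < 2:
        raise GroupCountError(f"ANOVA needs >= 2 groups, got {k}")
    ns = np.array([v.size for _, v in groups])
    n_total = int(ns.sum())
    df_within = n_total - k
    if df_within < 1:
        raise GroupCountError(
            f"{n_total} observations in {k} groups leave no within-group df"
        )
    values = np.concatenate([v for _, v in groups])
    grand = values.mean()
    means = np.array([v.mean() for _, v in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((v - m) ** 2) for (_, v), m in zip(groups, means)))
    if ss_within == 0.0 and ss_between == 0.0:
        return AnovaTable(0.0, 0.0, k - 1, df_within, 0.0, 1.0)
    ms_b = ss_between / (k - 1)
    ms_w = ss_within / df_within
    F = ms_b / ms_w if ms_w > 0 else np.inf
    p = float(sps.f.sf(F, k - 1, df_within))
    return AnovaTable(ss_between, ss_within, k - 1, df_within, float(F), p)


def nano_tukey(
    table: pd.DataFrame,
    group_key: str,
    value_col: str,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Tukey–Kramer all-pairs comparisons after a one-way ANOVA.

    For groups i, j the studentized statistic is

        q_ij = |mean_i - mean_j| / sqrt((MS_within / 2) (1/n_i + 1/n_j))

    with adjusted p-values and simultaneous intervals from the
    studentized-range distribution with parameters (k, df_within).
    The Kramer form handles unequal group sizes.  Returns one row per
    unordered pair: ``group_a, group_b, diff, ci_low, ci_high, p_adj``
    where ``diff = mean_b - mean_a`` in group order.
    """
    anova = one_way_anova(table, group_key, value_col)
    groups = _groups(table, group_key, value_col)
    k = len(groups)
    ms_w = anova.ms_within
    q_crit = float(sps.studentized_range.ppf(conf_level, k, anova.df_within))
    rows = []
    for (la, va), (lb, vb) in combinations(groups, 2):
        diff = vb.mean() - va.mean()
        half = np.sqrt((ms_w / 2.0) * (1.0 / va.size + 1.0 / vb.size))
        q = abs(diff) / half if half > 0 else np.inf
        p_adj = float(sps.studentized_range.sf(q, k, anova.df_within))
        margin = q_crit * half
        rows.append(
            {"group_a": la, "group_b": lb, "diff": float(diff),
             "ci_low": float(diff - margin), "ci_high": float(diff + margin),
             "p_adj": min(1.0, p_adj)}
        )
    return pd.DataFrame.from_records(rows)


@dataclass(frozen=True)
class WelchResult:
    """Welch's two-sample t-test: t statistic, Welch–Satterthwaite df, p."""

    t: float
    df: float
    p: float


def welch_t(table: pd.DataFrame, group_key: str, value_col: str) -> WelchResult:
    """Welch's unequal-variance t-test between exactly two groups.

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with the
    Welch–Satterthwaite degrees of freedom; two-sided p.  Group a is
    the first group in level order.
    """
    groups = _groups(table, group_key, value_col)
    if len(groups) != 2:
        raise GroupCountError(f"Welch's t-test needs exactly 2 groups, got {len(groups)}")
    (la, a), (lb, b) = groups
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateError("both groups have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(1.0, p))
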