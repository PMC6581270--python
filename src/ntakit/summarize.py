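"""Hierarchical replicate summarization and total-particle counting.

:func:`nanolyze` computes group-wise N / mean / sd / se with a caller
chosen column prefix, and its output is itself valid input for another
pass — the way NTA replicates are averaged up the hierarchy: technical
videos within an injection, injections within a biological sample,
samples within a treatment group.

:func:`nanocount` sums a value column within groups, optionally
restricted to a particle-size window (e.g. the 40–150 nm exosome
range), yielding one total concentration per group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import NTAError

__all__ = ["nanolyze", "nanocount"]

logger = logging.getLogger(__name__)


def _check_columns(table: pd.DataFrame, group_keys, param_var: str) -> None:
    missing = [c for c in [*group_keys, param_var] if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    if len(table) and not pd.api.types.is_numeric_dtype(table[param_var]):
        raise NTAError(f"value column {param_var!r} is not numeric")
    if table[param_var].isna().any():
        n = int(table[param_var].isna().sum())
        raise NTAError(
            f"value column {param_var!r} has {n} missing values; "
            "drop or impute them explicitly before summarizing"
        )


def nanolyze(
    table: pd.DataFrame,
    group_keys: list[str],
    param_var: str,
    prefix: str = "Stat",
) -> pd.DataFrame:
    """Group-wise summary statistics of one value column.

    Per group: ``<prefix>_N`` (row count), ``<prefix>_mean``
    (arithmetic mean), ``<prefix>_sd`` (sample standard deviation,
    N-1 denominator) and ``<prefix>_se`` (sd / sqrt(N)).  Groups of a
    single row get missing sd/se with a logged warning.  An empty input
    yields an empty output.  Group order follows categorical level
    order where the keys are categorical, never the row order.
    """
    _check_columns(table, group_keys, param_var)
    if len(table) == 0:
        out = table.loc[:, list(group_keys)].copy()
        for stat in ("N", "mean", "sd", "se"):
            out[f"{prefix}_{stat}"] = pd.Series(dtype=float)
        return out

    g = table.groupby(list(group_keys), observed=True, sort=True)[param_var]
    out = g.agg(N="size", mean="mean", sd="std").reset_index()  # std is ddof=1
    out["se"] = out["sd"] / np.sqrt(out["N"])
    n_single = int((out["N"] == 1).sum())
    if n_single:
        logger.warning(
            "%d group(s) of size 1 under keys %s: sd and se are undefined",
            n_single, list(group_keys),
        )
    return out.rename(
        columns={s: f"{prefix}_{s}" for s in ("N", "mean", "sd", "se")}
    )


def nanocount(
    table: pd.DataFrame,
    group_keys: list[str],
    param_var: str,
    size_range: tuple[float, float] | None = None,
    normalize_bin_width: float | None = None,
) -> pd.DataFrame:
    """Total particles per group, optionally within a size window.

    ``size_range=(lo, hi)`` keeps rows with ``lo <= particle_size < hi``
    (half-open on bin centres) before summing; groups left with no rows
    report a total of 0.  ``normalize_bin_width`` multiplies totals by
    the bin width in nm, converting a per-bin sum to an integral for
    non-unit bins; default off, matching 1-nm-bin exports.
    """
    _check_columns(table, group_keys, param_var)
    data = table
    if size_range is not None:
        lo, hi = float(size_range[0]), float(size_range[1])
        if not lo < hi:
            raise ValueError(f"inverted size_range ({lo}, {hi})")
        if "particle_size" not in data.columns:
            raise KeyError("size_range given but table has no particle_size column")
        data = data[(data["particle_size"] >= lo) & (data["particle_size"] < hi)]
    out = (
        data.groupby(list(group_keys), observed=True, sort=True)[param_var]
        .sum()
        .rename("total")
        .reset_index()
    )
    if size_range is not None and len(table):
        # groups emptied by the window still appear, with total 0
        all_groups = table[list(group_keys)].drop_duplicates()
        out = all_groups.merge(out, on=list(group_keys), how="left").fillna(
            {"total": 0.0}
        )
        out = out.sort_values(list(group_keys)).reset_index(drop=True)
    if normalize_bin_width is not None:
        out["total"] = out["total"] * float(normalize_bin_width)
    return out
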