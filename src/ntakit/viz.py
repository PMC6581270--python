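"""Static plots of summarized NTA data.

Two figures cover the toolkit's workflow: a size-distribution line
plot (mean concentration vs particle size per group, with a mean ± se
ribbon) and a totals plot (box-and-point per group, one point per
biological replicate).  Every number drawn is also returned — and
written as CSV next to the image — so tests and downstream analyses
work against the plotted-data table, never against pixels.

Figures are deterministic: identical inputs yield byte-identical
files (SVG date metadata is suppressed and the hash salt fixed).

Boxplot convention: quartiles by linear interpolation
(``numpy.percentile`` default); whiskers reach the most extreme data
point within 1.5 x IQR of the quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import EmptyInputError

__all__ = ["PlotSpec", "PlotResult", "plot_distribution", "plot_totals"]

matplotlib.rcParams["svg.hashsalt"] = "ntakit"


@dataclass(frozen=True)
class PlotSpec:
    """What to draw and where to put it.

    ``group_cols`` pick the line/box grouping; ``size_window`` limits
    the x-axis (nm) on distribution plots; ``path`` chooses the image
    format by its suffix (.png or .svg).
    """

    path: str
    group_cols: tuple[str, ...] = ()
    size_window: tuple[float, float] | None = None
    title: str = ""


@dataclass(frozen=True)
class PlotResult:
    """Image location plus the exact numbers drawn."""

    path: str
    data: pd.DataFrame
    box_stats: pd.DataFrame | None = None


def _check_cols(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")


def _save(fig, path: str) -> None:
    kwargs = {}
    if str(path).endswith(".svg"):
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, **kwargs)
    plt.close(fig)


def plot_distribution(summary: pd.DataFrame, spec: PlotSpec,
                      prefix: str = "Stat") -> PlotResult:
    """Mean concentration vs particle size, one line per group.

    ``summary`` must carry ``particle_size`` plus ``<prefix>_mean`` and
    ``<prefix>_se`` columns (a nanolyze output).  The ribbon spans
    mean ± se.  Returns the plotted coordinates (one row per input
    row) and writes them to ``<path>.csv``.
    """
    mean_col, se_col = f"{prefix}_mean", f"{prefix}_se"
    _check_cols(summary, ["particle_size", mean_col, se_col, *spec.group_cols])
    if len(summary) == 0:
        raise EmptyInputError("nothing to plot: summary table is empty")

    data = summary.loc[:, [*spec.group_cols, "particle_size", mean_col, se_col]].copy()
    data = data.rename(columns={mean_col: "mean", se_col: "se"})
    data["ribbon_low"] = data["mean"] - data["se"]
    data["ribbon_high"] = data["mean"] + data["se"]

    fig, ax = plt.subplots(figsize=(7, 4.5))
    if spec.group_cols:
        grouped = data.groupby(list(spec.group_cols), observed=True, sort=True)
    else:
        grouped = [("all", data)]
    for label, sub in grouped:
        sub = sub.sort_values("particle_size")
        label = label if isinstance(label, str) else "/".join(map(str, label))
        ax.plot(sub["particle_size"], sub["mean"], label=str(label), lw=1.2)
        ax.fill_between(sub["particle_size"], sub["ribbon_low"],
                        sub["ribbon_high"], alpha=0.25, lw=0)
    if spec.size_window is not None:
        ax.set_xlim(*spec.size_window)
    ax.set_xlabel("Particle size (nm)")
    ax.set_ylabel("Concentration (particles/mL)")
    if spec.title:
        ax.set_title(spec.title)
    if spec.group_cols:
        ax.legend(frameon=False, fontsize=8)
    _save(fig, spec.path)
    data.to_csv(spec.path + ".csv", index=False)
    return PlotResult(path=spec.path, data=data.reset_index(drop=True))


def plot_totals(counts: pd.DataFrame, spec: PlotSpec,
                total_col: str = "total") -> PlotResult:
    """Box-and-point plot of per-replicate totals by group.

    One box per group (levels in categorical order, not alphabetical)
    overlaid with every individual point.  Returns the points table and
    a ``box_stats`` table (median, quartiles, whiskers per group);
    both are written next to the image.
    """
    if not spec.group_cols:
        raise KeyError("plot_totals needs at least one group column in spec")
    group_col = spec.group_cols[0]
    _check_cols(counts, [group_col, total_col])
    if len(counts) == 0:
        raise EmptyInputError("nothing to plot: counts table is empty")

    if isinstance(counts[group_col].dtype, pd.CategoricalDtype):
        levels = [l for l in counts[group_col].cat.categories
                  if (counts[group_col] == l).any()]
    else:
        levels = list(dict.fromkeys(counts[group_col]))

    stats_rows, series = [], []
    for level in levels:
        v = np.asarray(counts.loc[counts[group_col] == level, total_col], float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        stats_rows.append({group_col: level, "n": v.size, "whisker_low": lo,
                           "q1": q1, "median": med, "q3": q3, "whisker_high": hi})
        series.append(v)
    box_stats = pd.DataFrame(stats_rows)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.boxplot(series, tick_labels=[str(l) for l in levels], showfliers=False,
               whis=1.5)
    rng = np.random.default_rng(0)  # jitter is cosmetic; fixed for determinism
    for i, v in enumerate(series, start=1):
        x = i + rng.uniform(-0.12, 0.12, size=v.size)
        ax.plot(x, v, "o", ms=4, alpha=0.7)
    ax.set_ylabel("Total concentration (particles/mL)")
    ax.set_xlabel(group_col)
    if spec.title:
        ax.set_title(spec.title)
    _save(fig, spec.path)

    points = counts.loc[:, [group_col, total_col]].reset_index(drop=True)
    points.to_csv(spec.path + ".csv", index=False)
    box_stats.to_csv(spec.path + ".box.csv", index=False)
    return PlotResult(path=spec.path, data=points, box_stats=box_stats)
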