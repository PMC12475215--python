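"""Rendering of the standard analysis figures.

All functions take prepared data (no computation happens here) and write a
PNG; they return the matplotlib Figure for testing/embedding.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.dates as mdates
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from zoomotion.motion import ActivityHeatmap
from zoomotion.stats import StudyPeriods, linear_trend


def plot_heatmap(heatmap: ActivityHeatmap, path: str | Path, bin_minutes: int = 10):
    """Day x time-of-day A1 raster (time on the vertical axis)."""
    fig, ax = plt.subplots(figsize=(10, 6))
    img = ax.imshow(
        heatmap.matrix.T,
        aspect="auto",
        origin="lower",
        interpolation="nearest",
        cmap="viridis",
        extent=(0, heatmap.matrix.shape[0], 0, 24),
    )
    ax.set_xlabel("day of study")
    ax.set_ylabel("hour (standard time)")
    ax.set_yticks(range(0, 25, 4))
    fig.colorbar(img, ax=ax, label="A1")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_daily_trends(
    daily: pd.Series,
    periods: StudyPeriods,
    path: str | Path,
):
    """Daily A1 with per-clock-period linear fits and event marker lines."""
    fig, ax = plt.subplots(figsize=(10, 4))
    dates = pd.to_datetime(pd.Index(daily.index))
    ax.plot(dates, daily.to_numpy(), "o-", ms=3, lw=0.8, color="gray", label="daily A1")
    colors = {"standard_time": "green", "dst": "red"}
    for name, (start, end) in (
        ("standard_time", periods.standard_time),
        ("dst", periods.dst),
    ):
        mask = [
            start <= d.date() <= end and d.date() not in periods.excluded_days
            for d in dates
        ]
        sub = daily[mask].dropna()
        if len(sub) >= 3:
            x = np.array([(pd.Timestamp(d).date() - start).days for d in sub.index], float)
            fit = linear_trend(x, sub.to_numpy())
            xs = np.array([x.min(), x.max()])
            ys = fit.estimate * xs + (sub.to_numpy().mean() - fit.estimate * x.mean())
            ax.plot(
                pd.Timestamp(start) + pd.to_timedelta(xs, unit="D"),
                ys,
                color=colors[name],
                lw=2,
                label=f"{name} fit (slope {fit.estimate:.2e})",
            )
    if periods.excluded_days:
        part = min(periods.excluded_days)
        ax.axvline(pd.Timestamp(part), color="purple", ls="--", label="parturition")
    ax.axvline(pd.Timestamp(periods.dst[0]), color="blue", ls="--", label="clock change")
    ax.xaxis.set_major_formatter(mdates.DateFormatter("%d %b"))
    ax.set_ylabel("daily A1")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_period_means(
    subsets: dict[str, pd.Series],
    path: str | Path,
    names: tuple[str, str] = ("prenatal", "postnatal"),
):
    """Mean +/- SD bars for two named periods."""
    fig, ax = plt.subplots(figsize=(4, 4))
    means = [subsets[n].mean() for n in names]
    sds = [subsets[n].std(ddof=1) for n in names]
    ax.bar(range(len(names)), means, yerr=sds, capsize=6, color=["tab:blue", "tab:orange"])
    ax.set_xticks(range(len(names)), names)
    ax.set_ylabel("A1 (mean ± SD)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def plot_pressure_panels(
    daily: pd.Series,
    pressure: pd.DataFrame,
    path: str | Path,
):
    """Two panels: daily A1 vs pressure p, and daily A1 vs delta-p."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    press = pressure.copy()
    press["date"] = pd.to_datetime(press["date"]).dt.date
    press = press.set_index("date")
    act_idx = [pd.Timestamp(d).date() for d in daily.index]
    common = [d for d in act_idx if d in press.index]
    a1 = pd.Series(daily.to_numpy(), index=act_idx).loc[common]
    for ax, col, label in (
        (axes[0], "p_hpa", "daily mean pressure p (hPa)"),
        (axes[1], "delta_p_hpa", "day-to-day change Δp (hPa)"),
    ):
        ax.scatter(press.loc[common, col], a1, s=12)
        ax.set_xlabel(label)
        ax.set_ylabel("daily A1")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig
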