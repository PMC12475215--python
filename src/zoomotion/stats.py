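"""Statistical stage: period splitting, trends, comparisons, correlations.

All tests are two-sided and report raw p-values (no multiple-testing
correction).  Sample standard deviations use the ``n - 1`` convention —
in contrast to the population convention inside the background model.

The study-level driver assembles, from a daily A1 series and a daily
pressure table, the named results the analysis reports: one linear trend
per clock period, the prenatal/postnatal mean comparison, the standard
time vs DST mean and variance comparisons, and Pearson correlations of
daily A1 with pressure and with its day-to-day change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("zoomotion")


@dataclass(frozen=True)
class StatResult:
    """Outcome of one statistical operation."""

    estimate: float
    se: float
    statistic: float
    df: float
    p_value: float
    test_name: str
    sides: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if not (math.isnan(self.se) or self.se >= 0):
            raise ValueError("standard error must be >= 0")


def _interval(start: str | Date, end: str | Date) -> tuple[Date, Date]:
    s, e = pd.Timestamp(start).date(), pd.Timestamp(end).date()
    if e < s:
        raise ValueError(f"reversed interval {s}..{e}")
    return (s, e)


@dataclass
class StudyPeriods:
    """Named inclusive date intervals of the study design.

    Defaults: prenatal 2016-03-04..03-13 (10 d), postnatal 2016-03-17..04-29
    (44 d), standard time 2016-03-01..03-26, DST 2016-03-27..04-29, with the
    two observation-stoppage days 2016-03-14/15 excluded from every subset.
    """

    prenatal: tuple[Date, Date] = ("2016-03-04", "2016-03-13")
    postnatal: tuple[Date, Date] = ("2016-03-17", "2016-04-29")
    standard_time: tuple[Date, Date] = ("2016-03-01", "2016-03-26")
    dst: tuple[Date, Date] = ("2016-03-27", "2016-04-29")
    excluded_days: frozenset = field(
        default_factory=lambda: frozenset({Date(2016, 3, 14), Date(2016, 3, 15)})
    )

    def __post_init__(self) -> None:
        self.prenatal = _interval(*self.prenatal)
        self.postnatal = _interval(*self.postnatal)
        self.standard_time = _interval(*self.standard_time)
        self.dst = _interval(*self.dst)
        self.excluded_days = frozenset(pd.Timestamp(d).date() for d in self.excluded_days)
        if self.prenatal[1] >= self.postnatal[0]:
            raise ValueError("prenatal and postnatal intervals overlap")
        if self.standard_time[1] >= self.dst[0]:
            raise ValueError("standard-time and DST intervals overlap")

    def named_intervals(self) -> dict[str, tuple[Date, Date]]:
        return {
            "prenatal": self.prenatal,
            "postnatal": self.postnatal,
            "standard_time": self.standard_time,
            "dst": self.dst,
        }


def split_periods(daily: pd.Series, periods: StudyPeriods) -> dict[str, pd.Series]:
    """Slice a daily series (indexed by date) into the named study periods.

    Excluded days are removed from every subset; an empty subset is an
    error naming the offending interval.
    """
    idx = pd.Index([pd.Timestamp(d).date() for d in daily.index])
    daily = pd.Series(daily.to_numpy(), index=idx)
    out: dict[str, pd.Series] = {}
    for name, (start, end) in periods.named_intervals().items():
        keep = [(start <= d <= end) and d not in periods.excluded_days for d in idx]
        subset = daily[keep].dropna()
        if subset.empty:
            raise ValueError(f"period {name!r} ({start}..{end}) contains no data")
        out[name] = subset
    return out


def linear_trend(x, y, test_name: str = "linear_trend") -> StatResult:
    """OLS slope with its t-test against zero (df = n - 2, two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a trend")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("degenerate x: all values equal")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    sse = np.sum(resid**2)
    df = n - 2
    se = math.sqrt(sse / df / sxx)
    if se == 0:
        t = 0.0 if slope == 0 else math.inf * np.sign(slope)
        p = 1.0 if slope == 0 else 0.0
    else:
        t = slope / se
        p = 2 * sps.t.sf(abs(t), df)
    return StatResult(slope, se, float(t), float(df), float(p), test_name)


def _t_from_summaries(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int,
    variant: str,
) -> tuple[float, float, float, float]:
    """(diff, se, t, df) for the two-sample t-test from summary statistics."""
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if n_a < 2 or n_b < 2:
        raise ValueError("each sample needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    diff = mean_a - mean_b
    va, vb = sd_a**2, sd_b**2
    if variant == "pooled":
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        se = math.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = float(n_a + n_b - 2)
    else:
        se = math.sqrt(va / n_a + vb / n_b)
        if se == 0:
            df = float(n_a + n_b - 2)
        else:
            df = (va / n_a + vb / n_b) ** 2 / (
                (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
            )
    if se == 0:
        # both variances zero: equal means -> t = 0, p = 1 by convention
        logger.info("two-sample t-test with zero variance in both samples")
        t = 0.0 if diff == 0 else math.inf * np.sign(diff)
    else:
        t = diff / se
    return diff, se, t, df


def compare_means_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "pooled",
) -> StatResult:
    """Two-sample t-test from summary statistics (pooled or Welch)."""
    diff, se, t, df = _t_from_summaries(mean_a, sd_a, n_a, mean_b, sd_b, n_b, variant)
    if math.isinf(t):
        p = 0.0
    else:
        p = 2 * sps.t.sf(abs(t), df)
    return StatResult(diff, se, float(t), df, float(p), f"t_{variant}")


def compare_means(a, b, variant: str = "pooled") -> StatResult:
    """Two-sample t-test on raw samples; SDs use the n-1 convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return compare_means_summary(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        variant,
    )


def compare_variances(a, b) -> StatResult:
    """F-test of equal variances, larger-over-smaller convention, two-sided.

    The two-sided p doubles the upper tail of F = s_max^2 / s_min^2 and is
    capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both variances are zero; F-test undefined")
    if va >= vb:
        num_var, den_var, dfn, dfd = va, vb, len(a) - 1, len(b) - 1
    else:
        num_var, den_var, dfn, dfd = vb, va, len(b) - 1, len(a) - 1
    if den_var == 0:
        f, p = math.inf, 0.0
    else:
        f = num_var / den_var
        p = min(1.0, 2 * sps.f.sf(f, dfn, dfd))
    return StatResult(float(f), math.nan, float(f), float(dfn), float(p), "f_variance")


def pearson_corr(x, y, test_name: str = "pearson") -> StatResult:
    """Pearson correlation with its t-test; missing pairs dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a correlation variable")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t, p = math.inf * np.sign(r), 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1 - r * r)
        p = 2 * sps.t.sf(abs(t), df)
    se = math.sqrt((1 - r * r) / df) if abs(r) < 1 else 0.0
    return StatResult(r, se, float(t), float(df), float(p), test_name)


F_GATE_ALPHA = 0.05


def _gated_mean_test(a: pd.Series, b: pd.Series) -> StatResult:
    """Pooled t by default; Welch when the F-test rejects equal variances."""
    gate = compare_variances(a.to_numpy(), b.to_numpy())
    variant = "welch" if gate.p_value < F_GATE_ALPHA else "pooled"
    if variant == "welch":
        logger.info("F gate rejected equal variances (p=%.3g); using Welch", gate.p_value)
    return compare_means(a.to_numpy(), b.to_numpy(), variant)


def run_study_analysis(
    activity_daily: pd.Series,
    pressure: pd.DataFrame,
    periods: StudyPeriods | None = None,
) -> pd.DataFrame:
    """Assemble the study's named statistical results as a flat table.

    ``activity_daily`` is the daily A1 series indexed by date; ``pressure``
    carries columns ``date``, ``p_hpa``, ``delta_p_hpa``.  Activity and
    pressure are aligned pairwise-complete on dates.  Output columns:
    test_name, period, estimate, se, statistic, df, p_value.
    """
    if periods is None:
        periods = StudyPeriods()
    subsets = split_periods(activity_daily, periods)

    press = pressure.copy()
    press["date"] = pd.to_datetime(press["date"]).dt.date
    press = press.set_index("date")
    act_dates = [pd.Timestamp(d).date() for d in activity_daily.dropna().index]
    act_dates = [d for d in act_dates if d not in periods.excluded_days]
    overlap = [d for d in act_dates if d in press.index]
    if len(overlap) < 3:
        missing = sorted(set(act_dates) - set(press.index))
        raise ValueError(
            f"insufficient activity/pressure overlap; pressure missing for {missing}"
        )
    act = pd.Series(
        activity_daily.dropna().to_numpy(),
        index=[pd.Timestamp(d).date() for d in activity_daily.dropna().index],
    ).loc[overlap]

    rows = []

    def add(name: str, period: str, res: StatResult) -> None:
        rows.append(
            {
                "test_name": name,
                "period": period,
                "estimate": res.estimate,
                "se": res.se,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )

    for pname in ("standard_time", "dst"):
        sub = subsets[pname]
        start = periods.named_intervals()[pname][0]
        x = np.array([(d - start).days for d in sub.index], dtype=float)
        add("trend_slope", pname, linear_trend(x, sub.to_numpy(), "trend_slope"))

    add("means_t", "prenatal_vs_postnatal", _gated_mean_test(subsets["prenatal"], subsets["postnatal"]))
    add("means_t", "standard_vs_dst", _gated_mean_test(subsets["standard_time"], subsets["dst"]))
    add(
        "variances_f",
        "standard_vs_dst",
        compare_variances(subsets["standard_time"].to_numpy(), subsets["dst"].to_numpy()),
    )

    p_vals = press.loc[overlap, "p_hpa"].to_numpy()
    dp_vals = press.loc[overlap, "delta_p_hpa"].to_numpy()
    add("pearson_r", "a1_vs_pressure", pearson_corr(act.to_numpy(), p_vals, "pearson_r"))
    add("pearson_r", "a1_vs_delta_pressure", pearson_corr(act.to_numpy(), dp_vals, "pearson_r"))

    return pd.DataFrame(rows)
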