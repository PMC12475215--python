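"""Station-pressure ingestion: daily means ``p`` and day-to-day changes ``dp``.

Input is a delimited text export from a synoptic station (column names,
delimiter and decimal mark vary between providers, so the mapping is
configurable).  ``dp_i = p_i - p_{i-1}``; a missing day breaks the chain, so
the day after a gap has no ``dp``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("zoomotion")

PLAUSIBLE_HPA = (870.0, 1085.0)


@dataclass
class PressureSeries:
    """Daily mean station pressure in hPa with per-day observation counts."""

    dates: pd.DatetimeIndex
    p: np.ndarray
    n_obs: np.ndarray
    flagged: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates).normalize()
        self.p = np.asarray(self.p, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        if len(self.dates) != len(self.p) or len(self.p) != len(self.n_obs):
            raise ValueError("dates, p and n_obs must have equal length")
        lo, hi = PLAUSIBLE_HPA
        self.flagged = (self.p < lo) | (self.p > hi)
        if self.flagged.any():
            logger.warning(
                "%d daily pressure values outside plausible range %s-%s hPa",
                int(self.flagged.sum()), lo, hi,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates.date, "p_hpa": self.p, "n_obs": self.n_obs})


@dataclass
class DeltaPressureSeries:
    """Day-to-day pressure change; NaN where the previous day is missing."""

    dates: pd.DatetimeIndex
    delta_p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates.date, "delta_p_hpa": self.delta_p})


def read_station_table(
    path: str | Path,
    date_column: str = "date",
    pressure_column: str = "pressure",
    delimiter: str = ",",
    decimal: str = ".",
    pressure_unit: str = "hPa",
) -> pd.DataFrame:
    """Parse raw station observations into (timestamp, pressure_hpa) rows.

    Unparseable rows are logged and skipped; an empty or all-bad file is an
    error.  ``pressure_unit`` may be ``hPa`` or ``Pa`` (divided by 100).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, decimal=decimal)
    if raw.empty:
        raise ValueError(f"empty station table {path}")
    for col in (date_column, pressure_column):
        if col not in raw.columns:
            raise ValueError(f"station table missing column {col!r}; has {list(raw.columns)}")
    ts = pd.to_datetime(raw[date_column], errors="coerce")
    p = pd.to_numeric(raw[pressure_column], errors="coerce")
    bad = ts.isna() | p.isna()
    if bad.any():
        logger.warning("skipped %d unparseable station rows", int(bad.sum()))
    obs = pd.DataFrame({"timestamp": ts[~bad], "pressure_hpa": p[~bad]})
    if obs.empty:
        raise ValueError(f"no parseable observations in {path}")
    if pressure_unit.lower() == "pa":
        obs["pressure_hpa"] /= 100.0
    elif pressure_unit.lower() != "hpa":
        raise ValueError(f"unsupported pressure unit {pressure_unit!r}")
    return obs.reset_index(drop=True)


def daily_mean(observations: pd.DataFrame) -> PressureSeries:
    """Arithmetic mean pressure per calendar day (all observations used)."""
    if observations.empty:
        raise ValueError("no observations")
    days = pd.DatetimeIndex(observations["timestamp"]).normalize()
    grouped = observations.groupby(days)["pressure_hpa"]
    mean = grouped.mean()
    return PressureSeries(
        dates=mean.index, p=mean.to_numpy(), n_obs=grouped.size().to_numpy()
    )


def delta_series(series: PressureSeries) -> DeltaPressureSeries:
    """dp_i = p_i - p_{i-1}; missing for the first day and after any gap."""
    if len(series.dates) < 2:
        raise ValueError("need at least 2 days for pressure deltas")
    delta = np.full(len(series.p), np.nan)
    day = pd.Timedelta(days=1)
    gaps = series.dates[1:] - series.dates[:-1]
    contiguous = gaps == day
    delta[1:][contiguous] = np.diff(series.p)[contiguous]
    return DeltaPressureSeries(dates=series.dates, delta_p=delta)


def pressure_table(series: PressureSeries) -> pd.DataFrame:
    """Combined output table: date, p_hpa, delta_p_hpa, n_obs."""
    delta = delta_series(series)
    out = series.to_frame()
    out.insert(2, "delta_p_hpa", delta.delta_p)
    return out


def read_pressure_csv(path: str | Path) -> pd.DataFrame:
    """Read a previously written pressure table (date, p_hpa, delta_p_hpa)."""
    raw = pd.read_csv(path)
    required = {"date", "p_hpa", "delta_p_hpa"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"pressure CSV missing columns: {sorted(missing)}")
    raw["date"] = pd.to_datetime(raw["date"])
    return raw
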