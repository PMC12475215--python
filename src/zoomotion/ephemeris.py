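"""Sunrise, sunset and day length via the NOAA solar-position method.

Implements the NOAA "low accuracy" solar calculator: Julian century ->
solar mean anomaly and ecliptic longitude -> declination and equation of
time -> hour angle at zenith 90.833 deg (0.833 deg refraction + solar-disc
correction).  Solar geometry is evaluated at local solar noon and event
times are rounded to the nearest minute, matching the calculator's display.
Polar day/night is out of scope and rejected explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import timedelta
from typing import Iterable, Sequence

import pandas as pd

ZENITH_DEG = 90.833

#: Default study site: Silesian Zoological Garden, Chorzow (approximate).
SITE_LATITUDE = 50.30
SITE_LONGITUDE = 18.95


class PolarDayError(ValueError):
    """The sun does not rise or set on this date at this latitude."""


@dataclass(frozen=True)
class SolarEvent:
    """Sunrise/sunset pair for one date and site, in a stated UTC offset."""

    date: Date
    latitude: float
    longitude: float
    utc_offset: float
    sunrise_local: "pd.Timestamp"
    sunset_local: "pd.Timestamp"
    day_length: float  # minutes


def _julian_day(d: Date) -> float:
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + day + b - 1524.5


def _declination_eot(jc: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (minutes) at a Julian
    century ``jc`` past J2000."""
    rad = math.radians
    gml = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_center = (
        math.sin(rad(gma)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(rad(2 * gma)) * (0.019993 - 0.000101 * jc)
        + math.sin(rad(3 * gma)) * 0.000289
    )
    true_lon = gml + eq_center
    app_lon = true_lon - 0.00569 - 0.00478 * math.sin(rad(125.04 - 1934.136 * jc))
    mean_obliq = 23 + (26 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60) / 60
    obliq = mean_obliq + 0.00256 * math.cos(rad(125.04 - 1934.136 * jc))
    decl = math.degrees(math.asin(math.sin(rad(obliq)) * math.sin(rad(app_lon))))
    var_y = math.tan(rad(obliq / 2)) ** 2
    eot = 4 * math.degrees(
        var_y * math.sin(2 * rad(gml))
        - 2 * ecc * math.sin(rad(gma))
        + 4 * ecc * var_y * math.sin(rad(gma)) * math.cos(2 * rad(gml))
        - 0.5 * var_y * var_y * math.sin(4 * rad(gml))
        - 1.25 * ecc * ecc * math.sin(2 * rad(gma))
    )
    return decl, eot


def sunrise_sunset(
    date: Date,
    latitude: float = SITE_LATITUDE,
    longitude: float = SITE_LONGITUDE,
    utc_offset: float = 1.0,
) -> SolarEvent:
    """Sunrise and sunset local clock times, rounded to the nearest minute.

    ``utc_offset`` is the fixed offset (hours, east positive) in which the
    returned clock times are expressed; DST must be applied by the caller
    through this offset.
    """
    if abs(latitude) >= 66.5:
        raise PolarDayError(
            f"latitude {latitude} is inside the polar circle; not supported"
        )
    # solar geometry evaluated at local noon (JD from _julian_day is 0h UT)
    jc = (_julian_day(date) + (12 - utc_offset) / 24 - 2451545.0) / 36525.0
    decl, eot = _declination_eot(jc)
    rad = math.radians
    cos_ha = math.cos(rad(ZENITH_DEG)) / (
        math.cos(rad(latitude)) * math.cos(rad(decl))
    ) - math.tan(rad(latitude)) * math.tan(rad(decl))
    if not -1.0 < cos_ha < 1.0:
        raise PolarDayError(f"sun does not rise/set on {date} at latitude {latitude}")
    ha = math.degrees(math.acos(cos_ha))
    noon_min = 720 - 4 * longitude - eot + utc_offset * 60
    sunrise_min = round(noon_min - 4 * ha)
    sunset_min = round(noon_min + 4 * ha)
    midnight = pd.Timestamp(date)
    return SolarEvent(
        date=date,
        latitude=latitude,
        longitude=longitude,
        utc_offset=utc_offset,
        sunrise_local=midnight + timedelta(minutes=sunrise_min),
        sunset_local=midnight + timedelta(minutes=sunset_min),
        day_length=float(sunset_min - sunrise_min),
    )


def day_length_series(
    dates: Iterable[Date] | Sequence[Date],
    latitude: float = SITE_LATITUDE,
    longitude: float = SITE_LONGITUDE,
    utc_offset: float = 1.0,
) -> pd.Series:
    """Day length in minutes for each date (index: date)."""
    dates = list(dates)
    values = [
        sunrise_sunset(d, latitude, longitude, utc_offset).day_length for d in dates
    ]
    return pd.Series(values, index=pd.Index(dates, name="date"), name="day_length_min")


def ephemeris_table(
    start: Date,
    end: Date,
    latitude: float = SITE_LATITUDE,
    longitude: float = SITE_LONGITUDE,
    utc_offset: float = 1.0,
) -> pd.DataFrame:
    """Per-date sunrise/sunset/day-length table for an inclusive date range."""
    if end < start:
        raise ValueError(f"reversed date range {start}..{end}")
    rows = []
    for d in pd.date_range(start, end, freq="D"):
        ev = sunrise_sunset(d.date(), latitude, longitude, utc_offset)
        rows.append(
            {
                "date": ev.date,
                "sunrise": ev.sunrise_local.strftime("%H:%M"),
                "sunset": ev.sunset_local.strftime("%H:%M"),
                "day_length_min": ev.day_length,
                "utc_offset": utc_offset,
            }
        )
    return pd.DataFrame(rows)
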