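"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own code paths: the motion oracle is
a scalar triple loop, and the solar oracle locates horizon crossings of the
sun's altitude computed from right ascension and sidereal time (a different
formulation from the hour-angle/equation-of-time route in the package).
"""

from __future__ import annotations

import math

import numpy as np


def naive_A_series(
    frames: list[np.ndarray],
    window: int = 28,
    k: float = 3.0,
    sd_floor: float = 2.0,
) -> list[float]:
    """Per-pixel scalar-loop version of the full A-index chain."""
    out = []
    h, w = frames[0].shape
    for t in range(window, len(frames)):
        count = 0
        for i in range(h):
            for j in range(w):
                s = 0
                sq = 0
                for u in range(t - window, t):
                    v = int(frames[u][i, j])
                    s += v
                    sq += v * v
                mean = s / window
                var = sq / window - mean * mean
                if var < 0:
                    var = 0.0
                sd = math.sqrt(var)
                if sd < sd_floor:
                    sd = sd_floor
                d = abs(int(frames[t][i, j]) - mean) / sd
                if d > k:
                    count += 1
        out.append(count / (h * w))
    return out


def _sun_radec(jd: float) -> tuple[float, float]:
    t = (jd - 2451545.0) / 36525.0
    rad = math.radians
    l0 = (280.46646 + 36000.76983 * t) % 360
    m = 357.52911 + 35999.05029 * t
    c = (
        (1.914602 - 0.004817 * t) * math.sin(rad(m))
        + (0.019993 - 0.000101 * t) * math.sin(rad(2 * m))
        + 0.000289 * math.sin(rad(3 * m))
    )
    lam = l0 + c - 0.00569 - 0.00478 * math.sin(rad(125.04 - 1934.136 * t))
    eps = 23.439291 - 0.0130042 * t + 0.00256 * math.cos(rad(125.04 - 1934.136 * t))
    ra = math.degrees(
        math.atan2(math.cos(rad(eps)) * math.sin(rad(lam)), math.cos(rad(lam)))
    ) % 360
    dec = math.degrees(math.asin(math.sin(rad(eps)) * math.sin(rad(lam))))
    return ra, dec


def _sun_altitude(jd: float, lat: float, lon: float) -> float:
    ra, dec = _sun_radec(jd)
    t = (jd - 2451545.0) / 36525.0
    gmst = (
        280.46061837 + 360.98564736629 * (jd - 2451545.0) + 0.000387933 * t * t
    ) % 360
    hour_angle = (gmst + lon - ra) % 360
    rad = math.radians
    return math.degrees(
        math.asin(
            math.sin(rad(lat)) * math.sin(rad(dec))
            + math.cos(rad(lat)) * math.cos(rad(dec)) * math.cos(rad(hour_angle))
        )
    )


def julian_day_0h(d) -> float:
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return (
        math.floor(365.25 * (y + 4716))
        + math.floor(30.6001 * (m + 1))
        + day
        + b
        - 1524.5
    )


def altitude_scan_events(d, lat: float, lon: float, utc_offset: float):
    """(sunrise, sunset) as minutes past local midnight, by scanning the
    solar altitude for -0.833 deg crossings at 2-minute steps with linear
    interpolation."""
    jd0 = julian_day_0h(d) - utc_offset / 24.0
    alts = [_sun_altitude(jd0 + m / 1440.0, lat, lon) for m in range(0, 1441, 2)]
    rise = sunset = None
    for i in range(len(alts) - 1):
        a, b = alts[i] + 0.833, alts[i + 1] + 0.833
        if a * b < 0:
            minute = 2 * i + 2 * (a / (a - b))
            if b > a and rise is None:
                rise = minute
            if b < a and sunset is None:
                sunset = minute
    return rise, sunset


def flash_block_video(
    n_frames: int,
    active: np.ndarray,
    shape: tuple[int, int] = (48, 48),
    block: int = 5,
    base: int = 100,
    bright: int = 200,
) -> list[np.ndarray]:
    """Video where "active" frames flash a block at a fresh location.

    Each active frame paints one ``block x block`` square for exactly that
    frame, cycling round-robin over a grid of disjoint sites.  As long as
    the number of sites exceeds the background window length, every flash
    lands on a site whose whole window history is the static base, so
    exactly ``block**2`` pixels are detected and ``A`` is known in closed
    form per frame.
    """
    h, w = shape
    per_row = w // block
    n_sites = (h // block) * per_row
    frames = []
    site = 0
    for t in range(n_frames):
        frame = np.full(shape, base, dtype=np.uint8)
        if active[t]:
            r = (site // per_row) * block
            c = (site % per_row) * block
            frame[r : r + block, c : c + block] = bright
            site = (site + 1) % n_sites
        frames.append(frame)
    return frames
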