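"""Synthetic study generator with known ground truth.

Produces the three kinds of input the pipeline consumes, all seeded and
reproducible:

* a per-bin activity-probability schedule (daylight gate opening relative
  to sunrise, fixed evening close, parturition step, post-clock-change
  drift, day-to-day pressure coupling);
* series-level A1 draws (binomial thinning per bin plus truncated Gaussian
  observation noise) that bypass video rendering;
* rendered grayscale frame streams — static textured background, moving
  disc "animals", night IR palette, additive sensor noise — whose true
  per-frame changed-pixel fraction is recorded alongside.

Ground truth is emitted separately from the rendered/simulated artifacts so
tests never have to recover it through the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import time as Time
from datetime import timedelta
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from zoomotion import ephemeris, meteo
from zoomotion.frames import FrameSeries
from zoomotion.motion import STANDARD_TIME, ActivitySeries

DAY_MINUTES = 24 * 60


@dataclass
class ScheduleConfig:
    """Parameters of the circadian activity-probability schedule."""

    start_date: Date = Date(2016, 3, 1)
    end_date: Date = Date(2016, 4, 29)
    latitude: float = ephemeris.SITE_LATITUDE
    longitude: float = ephemeris.SITE_LONGITUDE
    utc_offset: float = 1.0  # schedule built on fixed standard time
    baseline_active_prob: float = 0.115
    sunrise_onset_offset_min: float = 0.0
    evening_offset_clock: Time = Time(17, 0)
    parturition_date: Date | None = Date(2016, 3, 14)
    step_effect: float = 0.0419 / 0.0512  # multiplicative, from parturition on
    dst_date: Date | None = Date(2016, 3, 27)
    post_shift_trend: float = 0.0  # per-day fractional drift after dst_date
    pressure_coupling: float = 0.0  # per hPa of daily delta-p
    lights_on: Time = Time(7, 0)
    lights_off: Time = Time(17, 0)
    bin_minutes: int = 10
    stop_dates: frozenset = field(
        default_factory=lambda: frozenset({Date(2016, 3, 14), Date(2016, 3, 15)})
    )

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("reversed date range")
        if not 0 <= self.baseline_active_prob <= 1:
            raise ValueError("baseline_active_prob must lie in [0, 1]")
        if DAY_MINUTES % self.bin_minutes != 0:
            raise ValueError("bin_minutes must divide 24 h")

    @property
    def dates(self) -> list[Date]:
        return [d.date() for d in pd.date_range(self.start_date, self.end_date, freq="D")]


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    bin_probability: pd.Series  # per-bin true active probability
    daily_mean: pd.Series  # per-day true expected A1
    step_effect: float
    post_shift_trend: float
    pressure_coupling: float

    def to_csv(self, path) -> None:
        out = self.bin_probability.rename("p_active").rename_axis("bin_start").reset_index()
        out["bin_start"] = out["bin_start"].map(pd.Timestamp.isoformat)
        out.to_csv(path, index=False)


def make_schedule(
    config: ScheduleConfig,
    delta_p: pd.Series | None = None,
) -> tuple[pd.Series, GroundTruth]:
    """Build the per-bin true active-probability schedule.

    Per 10-minute bin: ``baseline`` x daylight gate (open from sunrise +
    onset offset until the fixed evening close) x parturition step (dates on
    or after ``parturition_date``) x ``(1 + trend * days since dst_date)`` x
    ``(1 + coupling * delta_p(day))``, clamped to [0, 1].  ``delta_p`` is a
    per-date series in hPa; missing days contribute no modulation.
    """
    bins_per_day = DAY_MINUTES // config.bin_minutes
    index = []
    probs = []
    for day in config.dates:
        ev = ephemeris.sunrise_sunset(
            day, config.latitude, config.longitude, config.utc_offset
        )
        open_min = (
            ev.sunrise_local - pd.Timestamp(day)
        ).total_seconds() / 60 + config.sunrise_onset_offset_min
        close_min = config.evening_offset_clock.hour * 60 + config.evening_offset_clock.minute
        factor = config.baseline_active_prob
        if config.parturition_date is not None and day >= config.parturition_date:
            factor *= config.step_effect
        if config.dst_date is not None and day >= config.dst_date:
            factor *= 1 + config.post_shift_trend * (day - config.dst_date).days
        if delta_p is not None and config.pressure_coupling != 0:
            dp = delta_p.get(day, np.nan)
            if not np.isnan(dp):
                factor *= 1 + config.pressure_coupling * dp
        midnight = pd.Timestamp(day, tz=STANDARD_TIME)
        for b in range(bins_per_day):
            start_min = b * config.bin_minutes
            gate = open_min <= start_min < close_min
            index.append(midnight + pd.Timedelta(minutes=start_min))
            probs.append(float(np.clip(factor, 0.0, 1.0)) if gate else 0.0)
    schedule = pd.Series(probs, index=pd.DatetimeIndex(index, name="bin_start"), name="p_active")
    daily = schedule.groupby(schedule.index.date).mean().rename("true_daily_A1")
    truth = GroundTruth(
        bin_probability=schedule,
        daily_mean=daily,
        step_effect=config.step_effect,
        post_shift_trend=config.post_shift_trend,
        pressure_coupling=config.pressure_coupling,
    )
    return schedule, truth


def simulate_A1_series(
    schedule: pd.Series,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
    frames_per_bin: int = 8400,
    fps: float = 14.0,
    stop_dates: frozenset = frozenset(),
) -> ActivitySeries:
    """Draw a 10-minute A1 series directly from the schedule.

    Per bin ``A1 = Binomial(frames_per_bin, p) / frames_per_bin`` plus
    zero-mean truncated Gaussian noise (truncated so A1 stays in [0, 1]).
    Bins on ``stop_dates`` are emitted as missing, emulating observation
    stoppages.  Bit-reproducible for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = schedule.to_numpy(dtype=float)
    a1 = rng.binomial(frames_per_bin, p) / frames_per_bin
    if noise_sd > 0:
        lo = (0.0 - a1) / noise_sd
        hi = (1.0 - a1) / noise_sd
        eps = sps.truncnorm.rvs(lo, hi, scale=noise_sd, random_state=rng)
        a1 = a1 + eps
    a1 = np.clip(a1, 0.0, 1.0)
    stopped = np.array([ts.date() in stop_dates for ts in schedule.index])
    a1 = np.where(stopped, np.nan, a1)
    n_frames = np.where(stopped, 0, frames_per_bin)
    data = pd.DataFrame(
        {
            "A1": a1,
            "n_frames": n_frames,
            "coverage": np.where(stopped, 0.0, 1.0),
        },
        index=schedule.index,
    )
    bin_length = schedule.index[1] - schedule.index[0] if len(schedule) > 1 else pd.Timedelta(minutes=10)
    return ActivitySeries(data=data, bin_length=bin_length)


@dataclass
class RenderConfig:
    """Parameters of the blob-video renderer."""

    geometry: tuple[int, int] = (352, 288)  # (width, height)
    fps: float = 14.0
    n_blobs: int = 9
    parturition_date: Date | None = Date(2016, 3, 14)  # +1 blob from here on
    blob_radius: int = 12
    blob_intensity: int = 230
    move_scale: float = 30.0  # displacement magnitude when active (px)
    night_ir_gain: float = 0.55
    noise_sd: float = 1.0
    lights_on: Time = Time(7, 0)
    lights_off: Time = Time(17, 0)
    seconds_per_bin: float | None = None  # None = render full bins
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.geometry
        margin = self.blob_radius + 1
        if 2 * margin >= min(w, h):
            raise ValueError("blob radius too large for frame geometry")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _disc_mask(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx * xx + yy * yy) <= radius * radius


def make_background(geometry: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Static textured background: smoothed noise over a mid-gray base."""
    w, h = geometry
    rough = rng.normal(0, 40, size=(h, w))
    texture = ndimage.gaussian_filter(rough, sigma=4)
    return np.clip(110 + texture, 0, 255).astype(np.uint8)


class _BlobField:
    """Positions and painting of the moving discs."""

    def __init__(self, cfg: RenderConfig, n: int, rng: np.random.Generator):
        w, h = cfg.geometry
        self.cfg = cfg
        self.margin = cfg.blob_radius + 1
        self.pos = np.column_stack(
            [
                rng.uniform(self.margin, w - self.margin, size=n),
                rng.uniform(self.margin, h - self.margin, size=n),
            ]
        )
        self.disc = _disc_mask(cfg.blob_radius)

    def move(self, rng: np.random.Generator) -> None:
        w, h = self.cfg.geometry
        angle = rng.uniform(0, 2 * np.pi, size=len(self.pos))
        step = self.cfg.move_scale
        self.pos[:, 0] += step * np.cos(angle)
        self.pos[:, 1] += step * np.sin(angle)
        # reflect back inside the frame
        for axis, limit in ((0, w), (1, h)):
            lo, hi = self.margin, limit - self.margin
            p = self.pos[:, axis]
            p[:] = np.where(p < lo, 2 * lo - p, p)
            p[:] = np.where(p > hi, 2 * hi - p, p)
            np.clip(p, lo, hi, out=p)

    def paint(self, canvas: np.ndarray, intensity: float, count: int | None = None) -> None:
        r = self.cfg.blob_radius
        pos = self.pos if count is None else self.pos[:count]
        for x, y in np.rint(pos).astype(int):
            canvas[y - r : y + r + 1, x - r : x + r + 1][self.disc] = intensity


def iter_rendered_frames(
    schedule: pd.Series,
    render: RenderConfig,
) -> Iterator[tuple[pd.Timestamp, np.ndarray, float]]:
    """Stream ``(timestamp, frame, true_changed_fraction)`` triples.

    In each bin the group is active per frame with the bin's scheduled
    probability; on an active frame every blob jumps by ``move_scale``,
    otherwise all freeze.  Night bins (outside lights-on hours) use the IR
    palette (intensity scaled by ``night_ir_gain``).  The changed-pixel
    fraction is measured on the clean canvas, before sensor noise.
    """
    rng = np.random.default_rng(render.seed)
    background = make_background(render.geometry, rng)
    n_blobs = render.n_blobs
    blobs = _BlobField(render, n_blobs + 1, rng)  # allocate the newborn too
    bin_length = (
        schedule.index[1] - schedule.index[0] if len(schedule) > 1 else pd.Timedelta(minutes=10)
    )
    seconds = render.seconds_per_bin or bin_length.total_seconds()
    n_frames = int(round(render.fps * seconds))
    frame_dt = pd.Timedelta(seconds=1.0 / render.fps)
    prev_clean = None
    size = background.size
    for bin_start, p_active in schedule.items():
        day = bin_start.date()
        active_blobs = n_blobs
        if render.parturition_date is not None and day >= render.parturition_date:
            active_blobs = n_blobs + 1
        tod = bin_start.time()
        night = not (render.lights_on <= tod < render.lights_off)
        if night:
            base = (background * render.night_ir_gain).astype(np.uint8)
            intensity = render.blob_intensity * render.night_ir_gain
        else:
            base = background
            intensity = render.blob_intensity
        for i in range(n_frames):
            if rng.random() < p_active:
                blobs.move(rng)
            clean = base.copy()
            blobs.paint(clean, intensity, count=active_blobs)
            changed = 0.0 if prev_clean is None else np.count_nonzero(clean != prev_clean) / size
            prev_clean = clean
            if render.noise_sd > 0:
                noisy = clean + rng.standard_normal(clean.shape, dtype=np.float32) * render.noise_sd
                frame = np.clip(noisy, 0, 255).astype(np.uint8)
            else:
                frame = clean
            yield bin_start + i * frame_dt, frame, changed


def render_frames(
    schedule: pd.Series,
    render: RenderConfig,
) -> tuple[FrameSeries, pd.DataFrame]:
    """Materialize a rendered schedule as a FrameSeries plus ground truth.

    Ground-truth columns: timestamp, changed_fraction (true per-frame
    changed-pixel share of the clean canvases).  For long schedules prefer
    :func:`iter_rendered_frames` to keep memory flat.
    """
    frames, timestamps, truth_rows = [], [], []
    for ts, frame, changed in iter_rendered_frames(schedule, render):
        frames.append(frame)
        timestamps.append(ts)
        truth_rows.append({"timestamp": ts, "changed_fraction": changed})
    series = FrameSeries(
        frames=frames, timestamps=pd.DatetimeIndex(timestamps), fps=render.fps
    )
    return series, pd.DataFrame(truth_rows)


def simulate_pressure(
    dates,
    mean_hpa: float = 1012.0,
    ar_coeff: float = 0.8,
    innovation_sd: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> meteo.PressureSeries:
    """AR(1) daily-mean pressure around ``mean_hpa``, seeded.

    Initialized from the stationary distribution, so the series has
    marginal SD ``innovation_sd / sqrt(1 - ar_coeff**2)`` throughout.
    """
    if not abs(ar_coeff) < 1:
        raise ValueError("|ar_coeff| must be < 1 for a stationary series")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize()
    n = len(dates)
    x = np.empty(n)
    if n == 0:
        raise ValueError("no dates")
    stat_sd = innovation_sd / np.sqrt(1 - ar_coeff**2) if innovation_sd > 0 else 0.0
    x[0] = rng.normal(0, stat_sd) if stat_sd > 0 else 0.0
    for i in range(1, n):
        x[i] = ar_coeff * x[i - 1] + (rng.normal(0, innovation_sd) if innovation_sd > 0 else 0.0)
    return meteo.PressureSeries(dates=dates, p=mean_hpa + x, n_obs=np.ones(n, dtype=int))


@dataclass
class StudyBundle:
    """Everything one synthetic study run produces."""

    activity: ActivitySeries  # 10-minute bins
    pressure: meteo.PressureSeries
    truth: GroundTruth
    schedule: pd.Series


def simulate_study(
    config: ScheduleConfig | None = None,
    noise_sd: float = 0.01,
    frames_per_bin: int = 8400,
    pressure_mean: float = 1012.0,
    pressure_ar: float = 0.8,
    pressure_sd: float = 3.0,
    seed: int = 0,
) -> StudyBundle:
    """Generate a full series-level study: pressure, schedule, A1 draws.

    Pressure is simulated first so its day-to-day change can modulate the
    activity schedule when ``pressure_coupling`` is nonzero.
    """
    if config is None:
        config = ScheduleConfig()
    rng = np.random.default_rng(seed)
    pressure = simulate_pressure(
        config.dates, pressure_mean, pressure_ar, pressure_sd, rng
    )
    dp = meteo.delta_series(pressure)
    dp_by_date = pd.Series(dp.delta_p, index=[d.date() for d in dp.dates])
    schedule, truth = make_schedule(config, delta_p=dp_by_date)
    activity = simulate_A1_series(
        schedule,
        noise_sd=noise_sd,
        seed=rng,
        frames_per_bin=frames_per_bin,
        stop_dates=config.stop_dates,
    )
    return StudyBundle(activity=activity, pressure=pressure, truth=truth, schedule=schedule)
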