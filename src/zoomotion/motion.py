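"""Per-frame activity fraction ``A`` and binned activity index ``A1``.

The detection chain scores every frame against a background model built from
the ``W`` frames that precede it (the frame itself is excluded):

1. convert to 8-bit grayscale;
2. per-pixel mean and population standard deviation over the sliding window,
   the SD floored to avoid division blow-up on static pixels;
3. per-pixel 1-D Mahalanobis distance ``|x - mean| / sd``;
4. binary motion mask where the distance strictly exceeds the pixel
   threshold ``k``;
5. ``A`` = fraction of active ("white") pixels in the frame.

``A1`` over a time bin is the fraction of frames whose ``A`` strictly
exceeds ``a_threshold`` (default 0.01).  Both inequalities are strict.

Conventions fixed here: the window SD divides by ``W`` (population form);
statistics elsewhere in the package use the ``n - 1`` sample form.  All
internal timestamps are kept in fixed local standard time; daylight-saving
labels are a display-layer concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import timedelta, timezone
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from zoomotion.frames import NOMINAL_FPS, FrameSeries

logger = logging.getLogger("zoomotion")

DEFAULT_WINDOW = 28
DEFAULT_PIXEL_THRESHOLD = 3.0
DEFAULT_SD_FLOOR = 2.0
DEFAULT_A_THRESHOLD = 0.01
DEFAULT_COVERAGE_MIN = 0.5

#: Fixed local standard time of the study site (UTC+1, no DST).
STANDARD_TIME = timezone(timedelta(hours=1))

# ITU-R BT.601 luma weights for 3-channel -> grayscale conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class WarmupError(ValueError):
    """Raised when fewer frames than the background window are available."""


class ActivitySample(NamedTuple):
    """One scored frame: its timestamp and activity fraction ``A``."""

    timestamp: pd.Timestamp
    A: float


@dataclass
class BackgroundModel:
    """Per-pixel mean/SD summary of the ``window_size`` preceding frames."""

    mean: np.ndarray
    sd: np.ndarray
    window_size: int

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must share one geometry")


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit frame to single-channel grayscale.

    Single-channel input (e.g. night-time IR footage) is returned unchanged;
    3-channel input is reduced with BT.601 luma weights (0.299, 0.587,
    0.114) and rounded to the nearest integer.
    """
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise ValueError(f"expected 8-bit frames, got dtype {frame.dtype}")
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 3:
        luma = frame.astype(np.float64) @ _LUMA_WEIGHTS
        return np.rint(luma).clip(0, 255).astype(np.uint8)
    raise ValueError(f"unsupported frame shape {frame.shape}")


def update_background(
    window: Sequence[np.ndarray],
    window_size: int | None = None,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> BackgroundModel:
    """Build the background model from exactly ``window_size`` frames.

    The to-be-scored frame must NOT be part of the window.  The SD uses the
    population convention (divide by ``W``) and is floored at ``sd_floor``.
    """
    if window_size is None:
        window_size = len(window)
    if len(window) != window_size or len(window) < 2:
        raise WarmupError(
            f"background window holds {len(window)} frames, needs {max(window_size, 2)}"
        )
    if sd_floor <= 0:
        raise ValueError("sd_floor must be positive")
    stack = np.stack([np.asarray(f, dtype=np.int64) for f in window])
    w = len(window)
    s = stack.sum(axis=0)
    sq = (stack * stack).sum(axis=0)
    mean = s / w
    var = sq / w - mean * mean
    np.maximum(var, 0.0, out=var)
    sd = np.sqrt(var)
    np.maximum(sd, sd_floor, out=sd)
    return BackgroundModel(mean=mean, sd=sd, window_size=w)


def mahalanobis_map(frame: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Per-pixel 1-D Mahalanobis distance ``|x - mean| / sd`` (>= 0)."""
    frame = np.asarray(frame)
    if frame.shape != model.mean.shape:
        raise ValueError(
            f"frame geometry {frame.shape} does not match model {model.mean.shape}"
        )
    return np.abs(frame - model.mean) / model.sd


def threshold_mask(dist: np.ndarray, k: float = DEFAULT_PIXEL_THRESHOLD) -> np.ndarray:
    """Binary motion mask: 1 ("white") where the distance strictly exceeds ``k``."""
    if k <= 0:
        raise ValueError("pixel threshold k must be positive")
    return (np.asarray(dist) > k).astype(np.uint8)


def frame_A(mask: np.ndarray) -> float:
    """Fraction of active pixels in the mask — the per-frame ``A`` index."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(mask) / mask.size)


def compute_A_series(
    frames: FrameSeries | Iterable[tuple[pd.Timestamp, np.ndarray]],
    window_size: int = DEFAULT_WINDOW,
    k: float = DEFAULT_PIXEL_THRESHOLD,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> list[ActivitySample]:
    """Score every frame after the warm-up against its sliding background.

    The first ``window_size`` frames only prime the model and yield no
    samples (missing, not zero).  Accepts a :class:`FrameSeries` or any
    iterable of ``(timestamp, frame)`` pairs; the latter is streamed, so
    arbitrarily long inputs need only ``window_size + 1`` frames in memory.

    Window sums are kept as exact integers, so the result is identical to
    rebuilding the model from scratch at every frame.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if k <= 0:
        raise ValueError("pixel threshold k must be positive")
    if sd_floor <= 0:
        raise ValueError("sd_floor must be positive")

    ring: list[np.ndarray] = []
    s = sq = None
    pos = 0
    samples: list[ActivitySample] = []
    n_seen = 0
    for ts, raw in iter(frames):
        n_seen += 1
        x = to_grayscale(np.asarray(raw))
        xi = x.astype(np.int64)
        if s is None:
            s = np.zeros_like(xi)
            sq = np.zeros_like(xi)
        if len(ring) == window_size:
            # score current frame against the W preceding frames
            mean = s / window_size
            var = sq / window_size - mean * mean
            np.maximum(var, 0.0, out=var)
            sd = np.sqrt(var)
            np.maximum(sd, sd_floor, out=sd)
            d = np.abs(x - mean) / sd
            active = d > k
            samples.append(
                ActivitySample(pd.Timestamp(ts), float(active.sum() / active.size))
            )
            old = ring[pos]
            s -= old
            sq -= old * old
            ring[pos] = xi
            pos = (pos + 1) % window_size
        else:
            ring.append(xi)
        s += xi
        sq += xi * xi
    if not samples:
        raise WarmupError(
            f"need more than {window_size} frames, got {n_seen}; warm-up not complete"
        )
    return samples


@dataclass
class ActivitySeries:
    """Time-binned ``A1`` values.

    ``data`` is indexed by timezone-annotated bin starts and carries columns
    ``A1`` (NaN where missing), ``n_frames`` and ``coverage``.
    """

    data: pd.DataFrame
    bin_length: pd.Timedelta

    def __post_init__(self) -> None:
        a1 = self.data["A1"].dropna()
        if len(a1) and not ((a1 >= 0) & (a1 <= 1)).all():
            raise ValueError("A1 values must lie in [0, 1]")
        starts = self.data.index
        if not starts.is_monotonic_increasing:
            raise ValueError("bins must be ordered")

    @property
    def bin_starts(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def A1(self) -> pd.Series:
        return self.data["A1"]

    def to_csv(self, path) -> None:
        out = self.data.reset_index(names="bin_start")
        out.insert(0, "bin_start_iso", out.pop("bin_start").map(pd.Timestamp.isoformat))
        out.insert(1, "bin_length_s", self.bin_length.total_seconds())
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ActivitySeries":
        raw = pd.read_csv(path)
        required = {"bin_start_iso", "bin_length_s", "A1", "n_frames", "coverage"}
        missing = required - set(raw.columns)
        if missing:
            raise ValueError(f"activity CSV missing columns: {sorted(missing)}")
        idx = pd.DatetimeIndex(pd.to_datetime(raw["bin_start_iso"], format="ISO8601"), name="bin_start")
        data = raw[["A1", "n_frames", "coverage"]].set_index(idx)
        return cls(data=data, bin_length=pd.Timedelta(seconds=raw["bin_length_s"].iloc[0]))

    def daily_mean(self) -> pd.Series:
        """Mean A1 per calendar day (index: date), skipping missing bins."""
        valid = self.data["A1"].dropna()
        return valid.groupby(valid.index.date).mean().rename("A1")


def aggregate_A1(
    samples: Sequence[ActivitySample],
    bin_length: timedelta | pd.Timedelta,
    a_threshold: float = DEFAULT_A_THRESHOLD,
    fps: float = NOMINAL_FPS,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> ActivitySeries:
    """Aggregate A samples into per-bin A1 values.

    ``A1`` per bin is the fraction of samples whose ``A`` strictly exceeds
    ``a_threshold``.  Coverage is recorded as observed / expected frame
    count (``fps * bin_length``); bins with coverage below ``coverage_min``
    and bins with no samples inside the observed span are reported missing
    (NaN), never zero.
    """
    if not samples:
        raise ValueError("no samples to aggregate")
    if a_threshold < 0:
        raise ValueError("a_threshold must be >= 0")
    bin_length = pd.Timedelta(bin_length)
    if bin_length <= pd.Timedelta(0):
        raise ValueError("bin_length must be positive")
    frame = pd.DataFrame(samples, columns=["timestamp", "A"])
    ts = pd.DatetimeIndex(frame["timestamp"])
    bins = ts.floor(bin_length)
    exceed = (frame["A"] > a_threshold).groupby(bins).sum()
    n = frame["A"].groupby(bins).size()
    a1 = exceed / n
    expected = fps * bin_length.total_seconds()
    coverage = (n / expected).clip(upper=1.0)
    data = pd.DataFrame({"A1": a1, "n_frames": n, "coverage": coverage})
    full_index = pd.date_range(bins.min(), bins.max(), freq=bin_length)
    data = data.reindex(full_index)
    data["n_frames"] = data["n_frames"].fillna(0).astype(int)
    data["coverage"] = data["coverage"].fillna(0.0)
    low = data["coverage"] < coverage_min
    if low.any():
        logger.info("%d of %d bins below coverage %.2f -> missing", int(low.sum()), len(data), coverage_min)
    data.loc[low, "A1"] = np.nan
    data.index.name = "bin_start"
    return ActivitySeries(data=data, bin_length=bin_length)


@dataclass
class ActivityHeatmap:
    """Day x time-of-day raster of A1 on a fixed (standard-time) clock."""

    matrix: np.ndarray
    day_labels: list
    clock_basis: timezone

    def column_labels(self, bin_length: pd.Timedelta) -> list[str]:
        n = self.matrix.shape[1]
        return [
            (pd.Timestamp("2000-01-01") + i * bin_length).strftime("%H:%M")
            for i in range(n)
        ]

    def to_frame(self, bin_length: pd.Timedelta = pd.Timedelta(minutes=10)) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.day_labels, columns=self.column_labels(bin_length)
        )


def build_heatmap(
    series: ActivitySeries,
    clock_basis: timezone = STANDARD_TIME,
) -> ActivityHeatmap:
    """Reshape a 10-minute A1 series into a day x 144 matrix.

    Bin starts are re-expressed on the fixed standard-time clock, so a bin
    recorded at civil 05:00 during DST lands in the 04:00 column.  Days with
    no data (e.g. observation stoppages) appear as fully missing rows.
    """
    day = pd.Timedelta(days=1)
    if day % series.bin_length != pd.Timedelta(0):
        raise ValueError("bin_length must divide 24 h")
    n_cols = int(day / series.bin_length)

    idx = series.bin_starts
    if idx.tz is None:
        local = idx.tz_localize(clock_basis)
    else:
        local = idx.tz_convert(clock_basis)
    dates = local.date
    col = ((local - local.normalize()) / series.bin_length).astype(int)

    all_days = pd.date_range(dates.min(), dates.max(), freq="D").date
    row_of = {d: i for i, d in enumerate(all_days)}
    matrix = np.full((len(all_days), n_cols), np.nan)
    rows = np.array([row_of[d] for d in dates])
    matrix[rows, col] = series.A1.to_numpy()
    return ActivityHeatmap(matrix=matrix, day_labels=list(all_days), clock_basis=clock_basis)
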