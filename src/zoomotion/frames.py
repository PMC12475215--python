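"""Frame-sequence container and plain-file frame I/O.

Frames are 8-bit grayscale ``numpy`` arrays of one fixed geometry with a
strictly increasing timestamp per frame.  On disk a frame set is a directory
of numbered PNGs plus a ``timestamps.tsv`` table (frame filename + ISO 8601
instant, one row per frame), which keeps the format inspectable and
camera-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("zoomotion")

TIMESTAMP_TABLE = "timestamps.tsv"

#: Nominal recording rate of the reference camera (Hz).
NOMINAL_FPS = 14.0

#: Nominal recording geometry of the reference camera, (width, height).
NOMINAL_GEOMETRY = (704, 576)


@dataclass
class FrameSeries:
    """Ordered grayscale frames with per-frame timestamps and one geometry.

    Parameters
    ----------
    frames
        Sequence of 2-D ``uint8`` arrays (height x width), or a 3-D array.
    timestamps
        Strictly increasing timezone-aware instants, one per frame.
    fps
        Nominal frames per second.  If it disagrees with the rate implied
        by the timestamps by more than 1 % it is recomputed and logged.
    """

    frames: Sequence[np.ndarray]
    timestamps: pd.DatetimeIndex
    fps: float = NOMINAL_FPS
    geometry: tuple[int, int] = field(init=False)  # (width, height)

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("FrameSeries requires at least one frame")
        if len(self.frames) != len(self.timestamps):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.timestamps)} timestamps"
            )
        first = np.asarray(self.frames[0])
        if first.ndim != 2:
            raise ValueError("frames must be 2-D grayscale arrays")
        h, w = first.shape
        for f in self.frames:
            if np.asarray(f).shape != (h, w):
                raise ValueError("all frames must share one geometry")
        self.geometry = (w, h)
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        diffs = np.diff(self.timestamps.asi8)
        if len(diffs) and not (diffs > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self._reconcile_fps()

    def _reconcile_fps(self) -> None:
        if len(self.timestamps) < 2:
            return
        span_s = (self.timestamps[-1] - self.timestamps[0]).total_seconds()
        if span_s <= 0:
            return
        implied = (len(self.timestamps) - 1) / span_s
        if abs(implied - self.fps) / self.fps > 0.01:
            logger.warning(
                "nominal fps %.3f disagrees with timestamp-implied %.3f by >1%%; "
                "using implied rate",
                self.fps,
                implied,
            )
            self.fps = implied

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[tuple[pd.Timestamp, np.ndarray]]:
        for ts, frame in zip(self.timestamps, self.frames):
            yield ts, np.asarray(frame)


def write_frame_dir(series: FrameSeries, path: str | Path) -> Path:
    """Write a :class:`FrameSeries` as numbered PNGs plus a timestamp table."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (_, frame) in enumerate(series):
        name = f"frame_{i:07d}.png"
        iio.imwrite(path / name, np.asarray(frame, dtype=np.uint8))
        names.append(name)
    table = pd.DataFrame(
        {"frame": names, "timestamp": [ts.isoformat() for ts in series.timestamps]}
    )
    table.to_csv(path / TIMESTAMP_TABLE, sep="\t", index=False)
    return path


def read_frame_dir(path: str | Path, fps: float = NOMINAL_FPS) -> FrameSeries:
    """Read a directory of numbered PNG frames and its timestamp table."""
    import imageio.v3 as iio

    path = Path(path)
    table_path = path / TIMESTAMP_TABLE
    if not table_path.exists():
        raise FileNotFoundError(f"missing timestamp table {table_path}")
    table = pd.read_csv(table_path, sep="\t")
    if table.empty:
        raise ValueError(f"empty timestamp table {table_path}")
    frames = [iio.imread(path / name) for name in table["frame"]]
    timestamps = pd.DatetimeIndex(pd.to_datetime(table["timestamp"], format="ISO8601"))
    return FrameSeries(frames=frames, timestamps=timestamps, fps=fps)


def iter_frame_dir(
    path: str | Path,
) -> Iterable[tuple[pd.Timestamp, np.ndarray]]:
    """Stream (timestamp, frame) pairs from a frame directory without
    loading everything into memory."""
    import imageio.v3 as iio

    path = Path(path)
    table = pd.read_csv(path / TIMESTAMP_TABLE, sep="\t")
    for name, ts in zip(table["frame"], pd.to_datetime(table["timestamp"], format="ISO8601")):
        yield ts, iio.imread(path / name)
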