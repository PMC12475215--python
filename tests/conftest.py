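import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20160301)


@pytest.fixture
def frame_timestamps():
    """Timestamp factory at the nominal 14 Hz, fixed standard time."""

    def make(n, start="2016-03-01 06:00:00+01:00", fps=14.0):
        t0 = pd.Timestamp(start)
        step = pd.Timedelta(seconds=1.0 / fps)
        return pd.DatetimeIndex([t0 + i * step for i in range(n)])

    return make


@pytest.fixture
def random_video(rng, frame_timestamps):
    """Small random uint8 video as (frames, timestamps)."""

    def make(n_frames=60, shape=(16, 16)):
        frames = [
            rng.integers(0, 256, size=shape, dtype=np.uint8) for _ in range(n_frames)
        ]
        return frames, frame_timestamps(n_frames)

    return make
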