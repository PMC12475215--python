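import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from oracles import flash_block_video, naive_A_series
from zoomotion.motion import (
    STANDARD_TIME,
    ActivitySample,
    ActivitySeries,
    BackgroundModel,
    WarmupError,
    aggregate_A1,
    build_heatmap,
    compute_A_series,
    frame_A,
    mahalanobis_map,
    threshold_mask,
    to_grayscale,
    update_background,
)


class TestToGrayscale:
    def test_single_channel_identity(self):
        frame = np.full((4, 6), 100, dtype=np.uint8)
        out = to_grayscale(frame)
        np.testing.assert_array_equal(out, frame)

    def test_equal_channels(self):
        frame = np.full((4, 6, 3), 100, dtype=np.uint8)
        assert (to_grayscale(frame) == 100).all()

    def test_pure_green_luma(self):
        frame = np.zeros((2, 2, 3), dtype=np.uint8)
        frame[..., 1] = 255
        # round(0.587 * 255) = 150
        assert (to_grayscale(frame) == 150).all()

    def test_rejects_wrong_dtype(self):
        with pytest.raises(ValueError, match="8-bit"):
            to_grayscale(np.zeros((4, 4), dtype=np.uint16))

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError, match="shape"):
            to_grayscale(np.zeros((4, 4, 4), dtype=np.uint8))


class TestUpdateBackground:
    def test_identical_frames_hit_sd_floor(self):
        window = [np.full((5, 5), 100, dtype=np.uint8)] * 28
        model = update_background(window)
        assert (model.mean == 100).all()
        assert (model.sd == 2.0).all()

    def test_alternating_frames_population_sd(self):
        window = [
            np.full((3, 3), 0 if i % 2 == 0 else 255, dtype=np.uint8)
            for i in range(28)
        ]
        model = update_background(window)
        assert (model.mean == 127.5).all()
        assert (model.sd == 127.5).all()

    def test_short_window_is_warmup_error(self):
        window = [np.zeros((3, 3), dtype=np.uint8)] * 27
        with pytest.raises(WarmupError):
            update_background(window, window_size=28)

    def test_matches_brute_force_statistics(self, rng):
        window = [rng.integers(0, 256, (6, 6), dtype=np.uint8) for _ in range(28)]
        model = update_background(window, sd_floor=0.5)
        stack = np.stack(window).astype(float)
        np.testing.assert_allclose(model.mean, stack.mean(axis=0), rtol=1e-12)
        expect_sd = np.maximum(stack.std(axis=0), 0.5)  # population convention
        np.testing.assert_allclose(model.sd, expect_sd, rtol=1e-12)


class TestMahalanobisMap:
    def _model(self, mean, sd, shape=(4, 4)):
        return BackgroundModel(
            mean=np.full(shape, float(mean)),
            sd=np.full(shape, float(sd)),
            window_size=28,
        )

    def test_zero_at_the_mean(self):
        model = self._model(100, 5)
        frame = np.full((4, 4), 100, dtype=np.uint8)
        assert (mahalanobis_map(frame, model) == 0).all()

    def test_hand_value(self):
        model = self._model(100, 10)
        frame = np.full((4, 4), 130, dtype=np.uint8)
        np.testing.assert_allclose(mahalanobis_map(frame, model), 3.0)

    def test_matches_scalar_loop(self, rng):
        mean = rng.uniform(0, 255, (16, 16))
        sd = rng.uniform(2, 50, (16, 16))
        model = BackgroundModel(mean=mean, sd=sd, window_size=28)
        frame = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        got = mahalanobis_map(frame, model)
        for i in range(16):
            for j in range(16):
                assert got[i, j] == abs(int(frame[i, j]) - mean[i, j]) / sd[i, j]

    def test_geometry_mismatch(self):
        model = self._model(100, 10, shape=(4, 4))
        with pytest.raises(ValueError, match="geometry"):
            mahalanobis_map(np.zeros((5, 5), dtype=np.uint8), model)


class TestThresholdMask:
    def test_all_zero_distances(self):
        assert (threshold_mask(np.zeros((10, 10)), 3.0) == 0).all()

    def test_counts_exceeding_pixels(self):
        k = 2.5
        d = np.zeros(100)
        d[:5] = k + 1
        mask = threshold_mask(d.reshape(10, 10), k)
        assert mask.sum() == 5
        assert set(np.unique(mask)) <= {0, 1}

    def test_boundary_is_strict(self):
        d = np.full((3, 3), 3.0)
        assert (threshold_mask(d, 3.0) == 0).all()

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(np.zeros((2, 2)), 0.0)


class TestFrameA:
    def test_all_black(self):
        assert frame_A(np.zeros((10, 10), dtype=np.uint8)) == 0.0

    def test_all_white(self):
        assert frame_A(np.ones((10, 10), dtype=np.uint8)) == 1.0

    def test_nominal_geometry_count(self):
        mask = np.zeros((576, 704), dtype=np.uint8)
        mask.ravel()[:4055] = 1
        assert frame_A(mask) == pytest.approx(4055 / 405504)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            frame_A(np.zeros((0, 0), dtype=np.uint8))


class TestComputeASeries:
    def test_static_video_all_zero(self, frame_timestamps):
        frames = [np.full((8, 8), 77, dtype=np.uint8)] * 40
        samples = compute_A_series(zip(frame_timestamps(40), frames))
        assert len(samples) == 40 - 28
        assert all(s.A == 0.0 for s in samples)

    def test_inverting_video_distance_is_exactly_one(self, frame_timestamps):
        # 0 <-> 255 alternation: the 28-frame window holds 14 of each, so
        # the population SD is 127.5 and every pixel's distance is exactly
        # |x - 127.5| / 127.5 = 1.0.  A == 1 for k < 1 and A == 0 for k >= 1
        # (verified against the scalar-loop oracle).
        frames = [
            np.full((8, 8), 0 if i % 2 == 0 else 255, dtype=np.uint8)
            for i in range(40)
        ]
        ts = frame_timestamps(40)
        low_k = compute_A_series(zip(ts, frames), k=0.5)
        assert all(s.A == 1.0 for s in low_k)
        default_k = compute_A_series(zip(ts, frames), k=3.0)
        assert all(s.A == 0.0 for s in default_k)
        assert [s.A for s in low_k] == naive_A_series(frames, k=0.5)

    def test_warmup_yields_no_samples(self, frame_timestamps):
        frames = [np.zeros((4, 4), dtype=np.uint8)] * 28
        with pytest.raises(WarmupError):
            compute_A_series(zip(frame_timestamps(28), frames))

    def test_known_flash_fraction(self, frame_timestamps):
        n = 120
        active = np.zeros(n, dtype=bool)
        active[28::3] = True  # every 3rd frame after warm-up flashes a block
        frames = flash_block_video(n, active, shape=(48, 48), block=5)
        samples = compute_A_series(zip(frame_timestamps(n), frames))
        f = 25 / (48 * 48)
        for is_active, s in zip(active[28:], samples):
            expect = f if is_active else 0.0
            assert abs(s.A - expect) <= 0.005
            assert s.A == pytest.approx(expect)

    def test_matches_naive_oracle_on_random_video(self, random_video):
        frames, ts = random_video(n_frames=60, shape=(16, 16))
        got = [s.A for s in compute_A_series(zip(ts, frames))]
        assert got == naive_A_series(frames)

    def test_timestamps_passed_through(self, random_video):
        frames, ts = random_video(n_frames=32, shape=(8, 8))
        samples = compute_A_series(zip(ts, frames))
        assert [s.timestamp for s in samples] == list(ts[28:])


class TestAggregateA1:
    def _samples(self, a_values, start="2016-03-01 10:00:00+01:00", fps=14.0):
        t0 = pd.Timestamp(start)
        step = pd.Timedelta(seconds=1 / fps)
        return [
            ActivitySample(t0 + i * step, a) for i, a in enumerate(a_values)
        ]

    def test_direct_count(self):
        samples = self._samples([0.02] * 300 + [0.005] * 300)
        series = aggregate_A1(samples, pd.Timedelta(minutes=10), coverage_min=0.0)
        assert series.A1.iloc[0] == 0.5

    def test_all_zero(self):
        samples = self._samples([0.0] * 100)
        series = aggregate_A1(samples, pd.Timedelta(minutes=10), coverage_min=0.0)
        assert series.A1.iloc[0] == 0.0

    def test_boundary_is_strict(self):
        samples = self._samples([0.01] * 100)
        series = aggregate_A1(samples, pd.Timedelta(minutes=10), coverage_min=0.0)
        assert series.A1.iloc[0] == 0.0

    def test_low_coverage_marked_missing(self):
        # 100 samples in a 10-minute bin is far below 14 Hz * 600 s
        samples = self._samples([0.5] * 100)
        series = aggregate_A1(samples, pd.Timedelta(minutes=10), coverage_min=0.5)
        assert np.isnan(series.A1.iloc[0])
        assert series.data["n_frames"].iloc[0] == 100

    def test_interior_empty_bin_is_missing_not_zero(self):
        first = self._samples([0.5] * 50, start="2016-03-01 10:00:00+01:00")
        third = self._samples([0.5] * 50, start="2016-03-01 10:20:00+01:00")
        series = aggregate_A1(first + third, pd.Timedelta(minutes=10), coverage_min=0.0)
        assert len(series.data) == 3
        assert np.isnan(series.A1.iloc[1])
        assert series.data["n_frames"].iloc[1] == 0

    def test_coverage_fraction_recorded(self):
        samples = self._samples([0.5] * 4200)  # half of a 10-min bin at 14 Hz
        series = aggregate_A1(samples, pd.Timedelta(minutes=10), coverage_min=0.0)
        assert series.data["coverage"].iloc[0] == pytest.approx(0.5)

    def test_csv_round_trip(self, tmp_path):
        samples = self._samples([0.02] * 300 + [0.0] * 300)
        series = aggregate_A1(samples, pd.Timedelta(minutes=10), coverage_min=0.0)
        path = tmp_path / "a1.csv"
        series.to_csv(path)
        back = ActivitySeries.from_csv(path)
        assert back.bin_length == series.bin_length
        pd.testing.assert_frame_equal(back.data, series.data, check_freq=False)


class TestHeatmap:
    def _series(self, index, a1):
        data = pd.DataFrame(
            {"A1": a1, "n_frames": 8400, "coverage": 1.0},
            index=pd.DatetimeIndex(index, name="bin_start"),
        )
        return ActivitySeries(data=data, bin_length=pd.Timedelta(minutes=10))

    def test_two_full_days(self, rng):
        index = pd.date_range(
            "2016-03-01 00:00", periods=288, freq="10min", tz=STANDARD_TIME
        )
        a1 = rng.uniform(0, 1, 288)
        hm = build_heatmap(self._series(index, a1))
        assert hm.matrix.shape == (2, 144)
        assert not np.isnan(hm.matrix).any()
        np.testing.assert_allclose(hm.matrix.ravel(), a1)

    def test_gap_days_fully_missing(self):
        d1 = pd.date_range("2016-03-13 00:00", periods=144, freq="10min", tz=STANDARD_TIME)
        d4 = pd.date_range("2016-03-16 00:00", periods=144, freq="10min", tz=STANDARD_TIME)
        series = self._series(d1.append(d4), [0.5] * 288)
        hm = build_heatmap(series)
        assert hm.matrix.shape == (4, 144)
        assert np.isnan(hm.matrix[1]).all() and np.isnan(hm.matrix[2]).all()
        assert not np.isnan(hm.matrix[0]).any()

    def test_dst_bin_lands_in_standard_time_column(self):
        # civil 05:00 CEST (UTC+2) is 04:00 on the fixed UTC+1 clock
        index = pd.DatetimeIndex([pd.Timestamp("2016-04-01 05:00:00+02:00")])
        hm = build_heatmap(self._series(index, [0.7]))
        assert hm.matrix.shape == (1, 144)
        col = np.flatnonzero(~np.isnan(hm.matrix[0]))
        assert list(col) == [24]  # 04:00 at 10-minute resolution

    def test_reshaping_conserves_values(self, rng):
        index = pd.date_range(
            "2016-03-01 00:00", periods=3 * 144, freq="10min", tz=STANDARD_TIME
        )
        a1 = rng.uniform(0, 1, len(index))
        keep = rng.random(len(index)) > 0.3
        series = self._series(index[keep], a1[keep])
        hm = build_heatmap(series)
        values = hm.matrix[~np.isnan(hm.matrix)]
        assert sorted(values) == sorted(a1[keep])

    def test_wrong_bin_length_rejected(self):
        index = pd.date_range("2016-03-01", periods=10, freq="7min", tz=STANDARD_TIME)
        data = pd.DataFrame(
            {"A1": 0.5, "n_frames": 1, "coverage": 1.0}, index=index
        )
        series = ActivitySeries(data=data, bin_length=pd.Timedelta(minutes=7))
        with pytest.raises(ValueError, match="divide"):
            build_heatmap(series)


class TestProperties:
    @given(
        frames=st.lists(
            hnp.arrays(np.uint8, (6, 6), elements=st.integers(0, 255)),
            min_size=31,
            max_size=36,
        ),
        k=st.floats(0.5, 6.0),
    )
    def test_A_bounds(self, frames, k):
        ts = pd.date_range("2016-03-01", periods=len(frames), freq="100ms")
        samples = compute_A_series(zip(ts, frames), window_size=28, k=k)
        assert all(0.0 <= s.A <= 1.0 for s in samples)

    def test_A1_monotone_in_k_and_threshold(self, random_video):
        frames, ts = random_video(n_frames=80, shape=(12, 12))
        bin_len = pd.Timedelta(minutes=10)
        prev = None
        for k in (0.5, 1.0, 2.0, 4.0):
            samples = compute_A_series(zip(ts, frames), k=k)
            a1 = aggregate_A1(samples, bin_len, coverage_min=0.0).A1.iloc[0]
            if prev is not None:
                assert a1 <= prev
            prev = a1
        samples = compute_A_series(zip(ts, frames), k=1.0)
        prev = None
        for thr in (0.0, 0.01, 0.05, 0.2, 0.9):
            a1 = aggregate_A1(samples, bin_len, a_threshold=thr, coverage_min=0.0).A1.iloc[0]
            if prev is not None:
                assert a1 <= prev
            prev = a1

    def test_A1_recovers_known_active_fraction(self, rng, frame_timestamps):
        # schedule with a known fraction of noticeably-active frames
        n = 5600
        f = 0.22
        active = np.zeros(n, dtype=bool)
        active[28:] = rng.random(n - 28) < f
        frames = flash_block_video(n, active, shape=(48, 48), block=5)
        samples = compute_A_series(zip(frame_timestamps(n), frames))
        series = aggregate_A1(
            samples, pd.Timedelta(hours=1), fps=14.0, coverage_min=0.0
        )
        total = series.data["n_frames"].sum()
        recovered = np.nansum(series.A1 * series.data["n_frames"]) / total
        true_f = active[28:].mean()
        assert abs(recovered - true_f) <= 0.01
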