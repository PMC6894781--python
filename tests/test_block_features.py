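"""Overall and TAMA blockwise statistics against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import dyadspeech as ds
from dyadspeech.errors import UndefinedFeatureError


def track_from(values, valid=None, shift=1.0, t0=0.0):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return ds.FrameTrack(shift, t0, values, valid)


def brute_force_blocks(track, cfg, duration):
    """Oracle: per-window averaging by explicit frame-center membership."""
    times = track.times
    means, counts = [], []
    k = 0
    while k * cfg.hop_s < duration:
        lo, hi = k * cfg.hop_s, k * cfg.hop_s + cfg.block_len_s
        sel = track.valid & (times >= lo) & (times < hi)
        counts.append(int(sel.sum()))
        means.append(track.values[sel].mean() if sel.any() else math.nan)
        k += 1
    return np.array(means), np.array(counts)


class TestOverallStats:
    def test_mean_and_population_sd(self):
        mean, sd = ds.overall_stats(track_from([1.0, 2.0, 3.0]))
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(math.sqrt(2.0 / 3.0))

    def test_degenerate_cases(self):
        assert ds.overall_stats(track_from([5.0]))[1] == 0.0
        assert ds.overall_stats(track_from([4.0, 4.0, 4.0]))[1] == 0.0
        with pytest.raises(UndefinedFeatureError):
            ds.overall_stats(track_from([np.nan, np.nan]))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=200))
    def test_matches_brute_force(self, values):
        track = track_from(values, valid=np.ones(len(values), bool))
        mean, sd = ds.overall_stats(track)
        arr = np.asarray(values)
        assert mean == pytest.approx(arr.mean(), abs=1e-12)
        assert sd == pytest.approx(
            math.sqrt(((arr - arr.mean()) ** 2).mean()), abs=1e-12
        )


class TestBlockwiseMeans:
    def test_documented_example(self):
        track = track_from([0.0, 0.0, 6.0, 6.0])  # frames at t = 0, 1, 2, 3 s
        series = ds.blockwise_means(track, ds.BlockConfig(2.0, 1.0))
        assert np.allclose(series.means, [0.0, 3.0, 6.0, 6.0])
        assert list(series.counts) == [2, 2, 2, 1]

    def test_constant_track(self):
        track = track_from(np.full(100, 7.0), shift=0.5)
        series = ds.blockwise_means(track, ds.BlockConfig(16.0, 8.0))
        assert np.allclose(series.means[series.counts > 0], 7.0)

    def test_empty_blocks_have_zero_count_and_nan_mean(self):
        values = np.full(6000, np.nan)
        values[:400] = 1.0  # valid only in [0, 4) of a 60 s session
        track = track_from(values, shift=0.01, t0=0.005)
        series = ds.blockwise_means(track, ds.BlockConfig(16.0, 8.0), 60.0)
        assert series.counts[0] > 0
        assert series.counts[-1] == 0 and math.isnan(series.means[-1])

    @given(st.data())
    def test_matches_brute_force(self, data):
        n = data.draw(st.integers(5, 300))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        track = ds.FrameTrack(0.25, 0.125, rng.normal(size=n), rng.random(n) < 0.7)
        cfg = ds.BlockConfig(block_len_s=4.0, hop_s=2.0)
        duration = n * 0.25
        series = ds.blockwise_means(track, cfg, duration)
        means, counts = brute_force_blocks(track, cfg, duration)
        assert np.array_equal(series.counts, counts)
        assert np.allclose(series.means, means, atol=1e-12, equal_nan=True)


class TestBlockwiseSd:
    def test_examples(self):
        assert ds.blockwise_sd(
            ds.BlockSeries(ds.BlockConfig(), [2.0, 2.0, 2.0], [3, 1, 2])
        ) == 0.0
        assert ds.blockwise_sd(
            ds.BlockSeries(ds.BlockConfig(), [0.0, 3.0, 6.0, 6.0], [1, 1, 1, 1])
        ) == pytest.approx(math.sqrt(6.1875))
        assert ds.blockwise_sd(
            ds.BlockSeries(ds.BlockConfig(), [4.2], [5])
        ) == 0.0

    def test_zero_usable_blocks(self):
        with pytest.raises(UndefinedFeatureError):
            ds.blockwise_sd(ds.BlockSeries(ds.BlockConfig(), [math.nan], [0]))

    def test_single_frame_blocks_reduce_to_overall_sd(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=64)
        track = track_from(values, shift=1.0, t0=0.5)
        series = ds.blockwise_means(track, ds.BlockConfig(1.0, 1.0), 64.0)
        assert ds.blockwise_sd(series) == pytest.approx(
            ds.overall_stats(track)[1], abs=1e-12
        )


def block_series(means, counts=None):
    means = np.asarray(means, dtype=float)
    if counts is None:
        counts = np.ones(len(means), int)
    return ds.BlockSeries(ds.BlockConfig(), means, counts)


class TestBlockwiseCorrelation:
    def test_perfect_and_inverse(self):
        x = block_series([1.0, 2.0, 3.0])
        assert ds.blockwise_correlation(x, x).r == pytest.approx(1.0)
        y = block_series([-1.0, -2.0, -3.0])
        assert ds.blockwise_correlation(x, y).r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        result = ds.blockwise_correlation(block_series(x), block_series(y))
        assert result.r == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)
        assert result.r == pytest.approx(0.8)
        assert result.n_blocks_used == 4

    def test_only_common_blocks_used(self):
        x = ds.BlockSeries(ds.BlockConfig(), [1.0, 2.0, 3.0, 9.0], [1, 1, 1, 0])
        y = ds.BlockSeries(ds.BlockConfig(), [2.0, 4.0, 6.0, 8.0], [1, 1, 1, 1])
        result = ds.blockwise_correlation(x, y)
        assert result.n_blocks_used == 3
        assert result.r == pytest.approx(1.0)

    def test_undefined_not_zero(self):
        with pytest.raises(UndefinedFeatureError):
            ds.blockwise_correlation(block_series([1.0]), block_series([2.0]))
        with pytest.raises(UndefinedFeatureError):
            ds.blockwise_correlation(
                block_series([1.0, 1.0, 1.0]), block_series([1.0, 2.0, 3.0])
            )

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=20),
        st.floats(0.1, 5),
        st.floats(-3, 3),
    )
    def test_symmetric_and_affine_invariant(self, xs, gain, offset):
        if np.ptp(xs) < 1e-3:
            return  # constant series: synchrony undefined by contract
        rng = np.random.default_rng(0)
        ys = rng.normal(size=len(xs))
        x, y = block_series(xs), block_series(ys)
        r_xy = ds.blockwise_correlation(x, y).r
        assert ds.blockwise_correlation(y, x).r == pytest.approx(r_xy, abs=1e-12)
        scaled = block_series(gain * np.asarray(xs) + offset)
        assert ds.blockwise_correlation(scaled, y).r == pytest.approx(r_xy, abs=1e-9)


class TestTimelineFeatures:
    def test_speech_rate(self):
        tl = ds.SessionTimeline(
            "t",
            (
                ds.IpuSegment("participant", 0.0, 2.0, 18),
                ds.IpuSegment("participant", 3.0, 4.0, 12),
            ),
            5.0,
        )
        assert ds.speech_rate(tl, "participant") == pytest.approx(10.0)

    def test_speech_rate_missing_mora(self):
        tl = ds.SessionTimeline(
            "t",
            (
                ds.IpuSegment("participant", 0.0, 1.0, 8),
                ds.IpuSegment("participant", 2.0, 3.0, None),
            ),
            4.0,
        )
        with pytest.raises(UndefinedFeatureError):
            ds.speech_rate(tl, "participant")

    def test_speaking_time_stats(self):
        tl = ds.SessionTimeline(
            "t",
            (
                ds.IpuSegment("participant", 0.0, 1.0),
                ds.IpuSegment("participant", 2.0, 5.0),
            ),
            6.0,
        )
        mean, sd = ds.speaking_time_stats(tl, "participant")
        assert (mean, sd) == (pytest.approx(2.0), pytest.approx(1.0))
        with pytest.raises(UndefinedFeatureError):
            ds.speaking_time_stats(tl, "administrator")


class TestAssembleFeatures:
    def test_simulated_session_complete(self, sim_session):
        timeline, tracks, _ = sim_session
        vec = ds.assemble_features(
            timeline,
            tracks["participant"]["f0"], tracks["participant"]["intensity"],
            tracks["administrator"]["f0"], tracks["administrator"]["intensity"],
        )
        values = vec.as_dict()
        assert len(values) == 13
        assert all(math.isfinite(v) for v in values.values())
        assert vec.is_complete

    def test_silent_participant_flags_undefined(self, sim_session):
        timeline, tracks, _ = sim_session
        silent = ds.SessionTimeline(
            "t", timeline.speaker_ipus("administrator"), timeline.duration_s
        )
        vec = ds.assemble_features(
            timeline=silent,
            participant_f0=tracks["participant"]["f0"],
            participant_intensity=tracks["participant"]["intensity"],
            administrator_f0=tracks["administrator"]["f0"],
            administrator_intensity=tracks["administrator"]["intensity"],
        )
        assert "mean_speaking_time_s" in vec.undefined_reasons
        assert "pause_to_turn_ratio" in vec.undefined_reasons
        assert math.isnan(vec.mean_turn_gap_s)

    def test_identical_blockwise_tracks_give_unit_synchrony(self):
        # step function constant within each 2 s block; speakers alternate IPUs
        shift = 0.1
        n = 80
        times = shift / 2 + shift * np.arange(n)
        values = np.floor(times / 2.0)
        ipus = []
        for k in range(4):
            ipus.append(ds.IpuSegment("administrator", 2 * k, 2 * k + 0.5))
            ipus.append(ds.IpuSegment("participant", 2 * k + 1.0, 2 * k + 1.5))
        tl = ds.SessionTimeline("t", tuple(ipus), 8.0)
        track = ds.FrameTrack(shift, shift / 2, values, np.ones(n, bool))
        vec = ds.assemble_features(
            tl, track, track, track, track, ds.BlockConfig(2.0, 2.0)
        )
        assert vec.corr_block_log_f0 == pytest.approx(1.0)
        assert vec.corr_block_intensity == pytest.approx(1.0)
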