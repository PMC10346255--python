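import numpy as np
import pytest

from semgkit.preprocess import denoise
from semgkit.segmentation import (
    ActiveSegment,
    SegmentationParams,
    detect_active_segments,
    extract_segments,
    frame_series,
    frame_variance,
    mean_signal,
    resample_to_length,
    segment_recording,
    short_term_energy,
)
from semgkit.signal_io import Recording
from semgkit.synthetic_data import generate_recording, make_templates


def enumerate_frames(series, frame_len, hop):
    """Independent oracle: explicitly list every full frame."""
    out = []
    start = 0
    while start + frame_len <= len(series):
        out.append(series[start : start + frame_len])
        start += hop
    return np.asarray(out)


class TestMeanSignal:
    @pytest.mark.parametrize(
        "data,expected",
        [
            ([[1, 1], [3, 3]], [2, 2]),
            ([[1, -1], [-1, 1]], [0, 0]),
        ],
    )
    def test_examples(self, data, expected):
        rec = Recording(data=np.asarray(data, float), fs=1)
        np.testing.assert_allclose(mean_signal(rec), expected)

    def test_single_channel_identity(self, rng):
        x = rng.standard_normal((1, 20))
        rec = Recording(data=x, fs=1)
        np.testing.assert_allclose(mean_signal(rec), x[0])


class TestFraming:
    @pytest.mark.parametrize(
        "length,frame_len,hop,n_expected",
        [(10, 4, 2, 4), (10, 10, 3, 1), (2664, 50, 30, 88), (101, 100, 50, 1)],
    )
    def test_frame_count_and_content(self, rng, length, frame_len, hop, n_expected):
        series = rng.standard_normal(length)
        frames = frame_series(series, frame_len, hop)
        oracle = enumerate_frames(series, frame_len, hop)
        assert frames.shape[0] == n_expected == oracle.shape[0]
        np.testing.assert_array_equal(frames, oracle)

    def test_frame_starts(self, rng):
        series = rng.standard_normal(10)
        frames = frame_series(series, 4, 2)
        for i, start in enumerate([0, 2, 4, 6]):
            np.testing.assert_array_equal(frames[i], series[start : start + 4])

    def test_frame_longer_than_series_errors(self):
        with pytest.raises(ValueError):
            frame_series(np.zeros(5), 6, 1)


class TestFrameStatistics:
    @pytest.mark.parametrize(
        "frame,expected",
        [([2, 2, 2, 2], 4.0), ([1, -1, 1, -1], 1.0), ([0, 0, 0], 0.0)],
    )
    def test_energy_examples(self, frame, expected):
        assert short_term_energy(np.asarray(frame, float)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "frame,expected",
        [([3, 3, 3], 0.0), ([1, -1], 1.0), ([0, 2], 1.0)],
    )
    def test_variance_examples(self, frame, expected):
        assert frame_variance(np.asarray(frame, float)) == pytest.approx(expected)

    def test_empty_frame_errors(self):
        with pytest.raises(ValueError):
            short_term_energy(np.array([]))
        with pytest.raises(ValueError):
            frame_variance(np.array([]))

    def test_quadratic_scaling(self, rng):
        frame = rng.standard_normal(32)
        for a in (0.5, 3.0, -2.0):
            assert short_term_energy(a * frame) == pytest.approx(
                a**2 * short_term_energy(frame)
            )
            assert frame_variance(a * frame) == pytest.approx(
                a**2 * frame_variance(frame)
            )


class TestDetection:
    def test_all_zero_series_is_inactive(self):
        params = SegmentationParams(energy_threshold=0.1, var_threshold=0.1)
        assert detect_active_segments(np.zeros(2000), params) == []

    def test_single_frame_blip_filtered_by_min_duration(self):
        series = np.zeros(2000)
        series[1000:1060] = 5.0 * np.sin(np.arange(60))
        params = SegmentationParams(
            frame_len=100, hop=100,  # non-overlapping: the blip hits one frame
            energy_threshold=0.5, var_threshold=0.5, min_segment_frames=2,
        )
        assert detect_active_segments(series, params) == []
        # with the duration filter relaxed, the same blip is reported
        relaxed = SegmentationParams(
            frame_len=100, hop=100,
            energy_threshold=0.5, var_threshold=0.5, min_segment_frames=1,
        )
        assert detect_active_segments(series, relaxed) == [(1000, 1100)]

    def test_known_bursts_recovered_within_one_hop(self, tiny_protocol):
        templates = make_templates(tiny_protocol, np.random.default_rng(3))
        params = SegmentationParams(expected_segments=tiny_protocol.n_repetitions)
        for seed in range(5):
            rec = denoise(generate_recording(tiny_protocol, templates[seed % 3], seed=seed))
            intervals = detect_active_segments(mean_signal(rec), params)
            assert len(intervals) == tiny_protocol.n_repetitions
            for (a, b), (ta, tb) in zip(intervals, rec.annotations):
                assert abs(a - ta) <= params.hop
                assert abs(b - tb) <= params.hop

    def test_boundaries_shift_at_most_one_hop_under_delay(self, rng):
        series = np.zeros(4000)
        series[1000:2200] = rng.standard_normal(1200) * 3
        params = SegmentationParams(energy_threshold=1.0, var_threshold=1.0)
        base = detect_active_segments(series, params)
        for delay in (10, 30, 49):
            shifted = np.r_[np.zeros(delay), series][:4000]
            moved = detect_active_segments(shifted, params)
            assert len(moved) == len(base) == 1
            assert abs(moved[0][0] - base[0][0]) <= params.hop
            assert abs(moved[0][1] - base[0][1]) <= params.hop


class TestExtraction:
    def test_identity_slice(self, rng):
        rec = Recording(data=rng.standard_normal((3, 40)), fs=1)
        [seg] = extract_segments(rec, [(0, 40)])
        np.testing.assert_array_equal(seg.data, rec.data)

    def test_length_conservation(self, rng):
        rec = Recording(data=rng.standard_normal((2, 100)), fs=1)
        segs = extract_segments(rec, [(5, 25), (60, 90)])
        assert sum(s.n_samples for s in segs) == 20 + 30

    def test_out_of_range_interval_errors(self, rng):
        rec = Recording(data=rng.standard_normal((2, 50)), fs=1)
        with pytest.raises(IndexError, match=r"\(40, 60\)"):
            extract_segments(rec, [(40, 60)])


class TestResampling:
    def test_identity_when_already_target_length(self, rng):
        seg = ActiveSegment(0, 30, rng.standard_normal((2, 30)))
        out = resample_to_length(seg, 30)
        np.testing.assert_allclose(out.data, seg.data, atol=1e-12)

    def test_linear_ramp_stays_linear(self):
        seg = ActiveSegment(0, 10, np.arange(10, dtype=float)[None, :])
        out = resample_to_length(seg, 19)
        np.testing.assert_allclose(out.data[0], np.linspace(0, 9, 19), atol=1e-12)
        assert out.data[0, 0] == 0.0 and out.data[0, -1] == 9.0

    def test_matches_pointwise_interpolation_oracle(self, rng):
        n_in, n_out = 37, 95
        seg = ActiveSegment(0, n_in, rng.standard_normal((2, n_in)))
        out = resample_to_length(seg, n_out)
        for c in range(2):
            for j in range(n_out):
                pos = j * (n_in - 1) / (n_out - 1)
                i = min(int(pos), n_in - 2)
                frac = pos - i
                expected = seg.data[c, i] * (1 - frac) + seg.data[c, i + 1] * frac
                assert out.data[c, j] == pytest.approx(expected, abs=1e-9)

    def test_target_too_short_errors(self, rng):
        seg = ActiveSegment(0, 10, rng.standard_normal((1, 10)))
        with pytest.raises(ValueError):
            resample_to_length(seg, 1)


def test_detect_extract_resample_pipeline(tiny_protocol):
    """End-to-end recovery: every recording yields the expected number of
    equal-length segments."""
    templates = make_templates(tiny_protocol, np.random.default_rng(3))
    params = SegmentationParams(expected_segments=tiny_protocol.n_repetitions)
    rec = denoise(generate_recording(tiny_protocol, templates[0], seed=11))
    segments = segment_recording(rec, params, target_len=900)
    assert len(segments) == tiny_protocol.n_repetitions
    assert all(s.data.shape == (tiny_protocol.n_channels, 900) for s in segments)
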