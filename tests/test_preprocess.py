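"""Trajectory cleaning: interpolation, zero-lag filtering, mirroring,
height normalisation."""

import numpy as np
import pytest

from stskit import (
    KeypointSeries,
    LandmarkID,
    MotionScript,
    NoiseSpec,
    PreprocessConfig,
    corrupt,
    preprocess,
    simulate_sts,
)
from stskit.kinematics import trunk_angle
from stskit.preprocess import (
    ConfigurationError,
    detect_facing_and_mirror,
    height_normalize,
    interpolate_gaps,
    lowpass_zero_lag,
)


def _series_from_xy(xy, conf=None, fps=30.0):
    if conf is None:
        conf = np.full(xy.shape[:2], 0.9)
    return KeypointSeries(xy=xy, confidence=conf, fps=fps)


class TestInterpolateGaps:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 100, size=(20, 25, 2))
        series = _series_from_xy(xy)
        out, qc = interpolate_gaps(series)
        np.testing.assert_array_equal(out.xy, xy)
        assert qc.n_interpolated_frames == 0

    def test_single_frame_gap_filled_linearly(self):
        xy = np.zeros((3, 25, 2))
        conf = np.full((3, 25), 0.9)
        xy[0, :, :] = [0.0, 0.0]
        xy[2, :, :] = [2.0, 4.0]
        conf[1, :] = 0.0  # frame 1 missing everywhere
        out, qc = interpolate_gaps(_series_from_xy(xy, conf))
        np.testing.assert_allclose(out.xy[1], np.broadcast_to([1.0, 2.0], (25, 2)))
        assert qc.n_interpolated_frames == 1
        assert qc.longest_gap == 1

    def test_long_gap_filled_but_flagged(self):
        T = 12
        xy = np.tile(np.linspace(0, 11, T)[:, None, None], (1, 25, 2))
        conf = np.full((T, 25), 0.9)
        conf[3:8, :] = 0.0  # 5-frame gap, max_gap_frames default 3
        out, qc = interpolate_gaps(_series_from_xy(xy, conf))
        assert qc.longest_gap == 5
        assert qc.exclusion_recommend
        np.testing.assert_allclose(out.xy[:, 0, 0], np.linspace(0, 11, T))

    def test_leading_gap_takes_nearest_value(self):
        xy = np.tile(np.arange(5.0)[:, None, None], (1, 25, 2))
        conf = np.full((5, 25), 0.9)
        conf[0, :] = 0.0
        out, _ = interpolate_gaps(_series_from_xy(xy, conf))
        np.testing.assert_allclose(out.xy[0, 0], [1.0, 1.0])

    def test_always_missing_landmark_marked_unavailable(self):
        xy = np.ones((10, 25, 2))
        conf = np.full((10, 25), 0.9)
        conf[:, int(LandmarkID.LEFT_EAR)] = 0.0
        _, qc = interpolate_gaps(_series_from_xy(xy, conf))
        assert int(LandmarkID.LEFT_EAR) in qc.unavailable_landmarks


class TestZeroLagFilter:
    fps = 30.0

    def _amplitude(self, y, t, freq):
        X = np.column_stack([np.sin(2 * np.pi * freq * t),
                             np.cos(2 * np.pi * freq * t)])
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        coef, *_ = np.linalg.lstsq(X[mid], y[mid], rcond=None)
        return float(np.hypot(*coef))

    def test_dc_gain_is_exactly_one(self):
        out = lowpass_zero_lag(np.full(200, 3.7), self.fps)
        np.testing.assert_allclose(out, 3.7, atol=1e-12)

    def test_passband_sinusoid_amplitude_preserved(self):
        # oracle: squared analog Butterworth magnitude |H(f)|^2 = 1/(1+(f/fc)^(2n))
        t = np.arange(0, 20, 1 / self.fps)
        y = lowpass_zero_lag(np.sin(2 * np.pi * 1.0 * t), self.fps)
        predicted = 1.0 / (1.0 + (1.0 / 6.0) ** 10)
        assert abs(self._amplitude(y, t, 1.0) - predicted) < 0.01

    def test_stopband_sinusoid_attenuated_at_least_as_predicted(self):
        t = np.arange(0, 20, 1 / self.fps)
        y = lowpass_zero_lag(np.sin(2 * np.pi * 12.0 * t), self.fps)
        predicted = 1.0 / (1.0 + (12.0 / 6.0) ** 10)
        amp = self._amplitude(y, t, 12.0)
        assert 0.0 <= amp <= 1.1 * predicted

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError, match="cutoff"):
            lowpass_zero_lag(np.zeros(100), fps=10.0)

    def test_short_trace_passes_through_with_flag(self):
        from stskit.preprocess import QCReport

        qc = QCReport()
        x = np.arange(10.0)
        out = lowpass_zero_lag(x, self.fps, qc=qc)
        np.testing.assert_array_equal(out, x)
        assert qc.too_short_for_filter

    def test_refiltering_changes_less_than_filtering(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 10, 1 / self.fps)
        raw = np.sin(2 * np.pi * 0.5 * t) + 0.3 * rng.standard_normal(len(t))
        once = lowpass_zero_lag(raw, self.fps)
        twice = lowpass_zero_lag(once, self.fps)
        assert np.linalg.norm(twice - once) < np.linalg.norm(once - raw)


class TestMirroring:
    def test_rightward_subject_unchanged(self, five_cycle_sim):
        series, _ = five_cycle_sim
        out, mirrored = detect_facing_and_mirror(series.xy)
        assert not mirrored
        np.testing.assert_array_equal(out, series.xy)

    def test_left_facing_recovered_up_to_translation(self, five_cycle_sim):
        series, _ = five_cycle_sim
        flipped = corrupt(series, NoiseSpec(facing="left"))
        out, mirrored = detect_facing_and_mirror(flipped.xy)
        assert mirrored
        shift = out[..., 0] - series.xy[..., 0]
        np.testing.assert_allclose(shift, shift.flat[0], atol=1e-9)
        np.testing.assert_allclose(out[..., 1], series.xy[..., 1], atol=1e-9)

    def test_double_mirror_preserves_trunk_angle(self, five_cycle_sim):
        series, _ = five_cycle_sim
        cfg = PreprocessConfig(mirror_policy="force")
        once, _ = detect_facing_and_mirror(series.xy, cfg)
        twice, _ = detect_facing_and_mirror(once, cfg)
        clean_a = preprocess(series, PreprocessConfig(mirror_policy="off"))
        series_b = KeypointSeries(xy=twice, confidence=series.confidence,
                                  fps=series.fps)
        clean_b = preprocess(series_b, PreprocessConfig(mirror_policy="off"))
        np.testing.assert_allclose(trunk_angle(clean_a).angle_deg,
                                   trunk_angle(clean_b).angle_deg, atol=1e-6)


class TestHeightNormalize:
    def test_matches_percentile_closed_form(self):
        # 96 frames with ankle-nose distance 100 px, 4 with 60 px
        T = 100
        xy = np.zeros((T, 25, 2))
        xy[:, LandmarkID.NOSE, 1] = 100.0
        xy[:4, LandmarkID.NOSE, 1] = 60.0
        _, height = height_normalize(xy)
        assert height == pytest.approx(100.0)

    def test_scale_invariance(self, five_cycle_sim):
        series, _ = five_cycle_sim
        a, _ = height_normalize(series.xy)
        b, _ = height_normalize(series.xy * 3.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_normalized_ankle_nose_95th_percentile_is_one(self, five_cycle_sim):
        series, _ = five_cycle_sim
        clean = preprocess(series)
        d = np.linalg.norm(clean.trace(LandmarkID.NOSE)
                           - clean.trace(LandmarkID.RIGHT_ANKLE), axis=1)
        assert np.percentile(d, 95) == pytest.approx(1.0, abs=0.02)


class TestPreprocessPipeline:
    def test_clean_input_has_empty_qc(self, five_cycle_sim):
        series, _ = five_cycle_sim
        clean = preprocess(series)
        assert not clean.qc.exclusion_recommend
        assert clean.qc.n_interpolated_frames == 0

    def test_dropped_frame_counted(self, five_cycle_sim):
        series, _ = five_cycle_sim
        noisy = corrupt(series, NoiseSpec(dropout_prob=0.004, seed=2))
        n_dropped = int((noisy.confidence.max(axis=1) == 0).sum())
        assert n_dropped >= 1
        clean = preprocess(noisy)
        assert clean.qc.n_interpolated_frames == n_dropped

    def test_output_is_finite_and_up_positive(self, five_cycle_sim):
        series, _ = five_cycle_sim
        clean = preprocess(series)
        assert np.all(np.isfinite(clean.xy))
        nose_up = clean.trace(LandmarkID.NOSE)[:, 1]
        ankle_up = clean.trace(LandmarkID.RIGHT_ANKLE)[:, 1]
        assert np.median(nose_up) > np.median(ankle_up)

    def test_noiseless_cleaning_tracks_ground_truth_trajectory(self):
        series, _ = simulate_sts(script=MotionScript())
        clean = preprocess(series, PreprocessConfig(normalize=False))
        # filtering should barely move a band-limited noiseless trajectory
        nose_raw = -series.xy[:, LandmarkID.NOSE, 1]
        nose_clean = clean.trace(LandmarkID.NOSE)[:, 1]
        err = np.abs(nose_clean - nose_raw)
        interior = err[20:-20]
        assert interior.max() < 2.0  # px, at ~520 px subject height
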