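import numpy as np
import pytest

from tugait.errors import SegmentationError, StateMachineError
from tugait.io import CANONICAL_JOINTS, Keypoints3DSequence
from tugait.segmentation import (
    PhaseSegmentation,
    SegmentationConfig,
    detect_turns,
    segment_phases,
    sts_thresholds,
    vertical_signal,
)
from tugait.simulate import conference_room, simulate_trial


def _kp3d(y_pelvis, y_ankle=0.0, frames=20):
    coords = np.zeros((frames, 8, 3))
    coords[:, CANONICAL_JOINTS.index("pelvis"), 1] = y_pelvis
    coords[:, CANONICAL_JOINTS.index("left_ankle"), 1] = y_ankle
    coords[:, CANONICAL_JOINTS.index("right_ankle"), 1] = y_ankle
    return Keypoints3DSequence(fps=30, joints=list(CANONICAL_JOINTS), coords=coords)


class TestVerticalSignal:
    def test_constant_seated_pose_gives_constant_height(self):
        h = vertical_signal(_kp3d(0.77), smooth=False)
        np.testing.assert_allclose(h, 0.77)

    def test_standing_exceeds_seated(self):
        assert vertical_signal(_kp3d(0.93), smooth=False)[0] > vertical_signal(
            _kp3d(0.77), smooth=False
        )[0]

    def test_y_axis_sign_flip_is_invisible(self):
        seq = _kp3d(0.9)
        flipped = Keypoints3DSequence(
            fps=30, joints=seq.joints, coords=seq.coords * [1, -1, 1]
        )
        np.testing.assert_allclose(
            vertical_signal(seq, smooth=False), vertical_signal(flipped, smooth=False)
        )


class TestThresholds:
    def test_default_fractions_of_the_range(self):
        # seated and standing plateaus bracket the rise, as in a real TUG
        h = np.concatenate([np.full(30, 0.4), np.linspace(0.4, 0.9, 40), np.full(30, 0.9)])
        t_high, t_low = sts_thresholds(h)
        assert t_high == pytest.approx(0.8)
        assert t_low == pytest.approx(0.55)

    def test_constant_signal_rejected(self):
        with pytest.raises(SegmentationError):
            sts_thresholds(np.full(50, 0.8))

    def test_scale_equivariance(self):
        h = np.linspace(0.4, 0.9, 50)
        t1 = sts_thresholds(h)
        t2 = sts_thresholds(3.0 * h)
        assert t2[0] == pytest.approx(3.0 * t1[0])
        assert t2[1] == pytest.approx(3.0 * t1[1])


class TestDetectTurns:
    def test_two_synthetic_turns_recovered_with_tight_boundaries(self):
        n = 500
        dz = np.zeros(n)
        t = np.arange(n)
        for c, w in ((167, 18), (350, 20)):
            dz += 0.42 * np.exp(-0.5 * ((t - c) / w) ** 2)
        intervals = detect_turns(dz, fps=30)
        # half-prominence of a Gaussian: center +- w*sqrt(2 ln 2)
        for (lo, hi), (c, w) in zip(intervals, ((167, 18), (350, 20))):
            half = w * np.sqrt(2 * np.log(2))
            assert lo == pytest.approx(c - half, abs=5)
            assert hi == pytest.approx(c + half, abs=5)

    def test_straight_walking_has_no_turns(self):
        with pytest.raises(SegmentationError, match="turn"):
            detect_turns(np.abs(np.random.default_rng(0).normal(0, 0.01, 300)), fps=30)

    def test_simulated_shoulder_signal_peaks_at_full_breadth(self):
        tr = simulate_trial(
            conference_room(subject_height_m=1.76, pixel_noise_sigma_px=0, pose_noise_m=0, seed=5)
        )
        dz = tr.truth["dz_shoulder"]
        walk = tr.truth["phase_bounds"]["Walk1"]
        turn = tr.truth["phase_bounds"]["Turn1"]
        breadth = 2 * 0.1225 * 1.76
        assert np.max(dz[walk[0] + 5 : walk[1] - 5]) < 0.05
        assert np.max(dz[turn[0] : turn[1]]) == pytest.approx(breadth, rel=0.05)


class TestSegmentPhases:
    def test_clean_trial_reproduces_simulator_truth_exactly(self):
        tr = simulate_trial(
            conference_room(subject_height_m=1.76, pixel_noise_sigma_px=0, pose_noise_m=0, seed=5)
        )
        seg = segment_phases(
            tr.truth["h_foot"], tr.truth["dz_shoulder"], SegmentationConfig(), 30.0
        )
        assert seg.intervals == tr.truth["phase_bounds"]

    def test_intervals_tile_the_span_in_order(self):
        tr = simulate_trial(conference_room(seed=6))
        seg = segment_phases(
            tr.truth["h_foot"], tr.truth["dz_shoulder"], SegmentationConfig(), 30.0
        )
        bounds = [seg.intervals[n] for n in seg.intervals]
        assert bounds[0][0] == 0
        for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
            assert e1 == s2
        assert bounds[-1][1] == tr.frames

    def test_subject_who_never_sits_down_is_rejected(self):
        tr = simulate_trial(
            conference_room(subject_height_m=1.76, pixel_noise_sigma_px=0, pose_noise_m=0, seed=5)
        )
        h = tr.truth["h_foot"].copy()
        stsit = tr.truth["phase_bounds"]["StandToSit"][0]
        h[stsit:] = h[stsit - 1]  # freeze standing forever
        with pytest.raises(StateMachineError, match="sit"):
            segment_phases(h, tr.truth["dz_shoulder"], SegmentationConfig(), 30.0)

    def test_turn_before_standing_is_an_ordering_error(self):
        tr = simulate_trial(
            conference_room(subject_height_m=1.76, pixel_noise_sigma_px=0, pose_noise_m=0, seed=5)
        )
        dz = np.roll(tr.truth["dz_shoulder"], -200)  # drags turn 1 before the rise
        with pytest.raises(SegmentationError):
            segment_phases(tr.truth["h_foot"], dz, SegmentationConfig(), 30.0)

    def test_determinism(self):
        tr = simulate_trial(conference_room(seed=8))
        a = segment_phases(tr.truth["h_foot"], tr.truth["dz_shoulder"], None, 30.0)
        b = segment_phases(tr.truth["h_foot"], tr.truth["dz_shoulder"], None, 30.0)
        assert a.intervals == b.intervals

    def test_frame_rate_equivariance(self):
        """Resampling the driving signals to 60 fps doubles every boundary
        to within a frame or two of interpolation slack."""
        tr = simulate_trial(
            conference_room(subject_height_m=1.76, pixel_noise_sigma_px=0, pose_noise_m=0, seed=5)
        )
        h, dz = tr.truth["h_foot"], tr.truth["dz_shoulder"]
        n = len(h)
        x2 = np.arange(2 * n) / 2.0
        h2 = np.interp(x2, np.arange(n), h)
        dz2 = np.interp(x2, np.arange(n), dz)
        seg1 = segment_phases(h, dz, None, 30.0)
        seg2 = segment_phases(h2, dz2, None, 60.0)
        for name in seg1.intervals:
            (s1, e1), (s2, e2) = seg1.intervals[name], seg2.intervals[name]
            assert abs(s2 - 2 * s1) <= 2
            assert abs(e2 - 2 * e1) <= 2
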