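import numpy as np
import pytest

from tugait.calibration import calibrate, geometric_depth_track, select_calibration_frames
from tugait.errors import CalibrationError
from tugait.io import CANONICAL_JOINTS, Keypoints2DSequence
from tugait.pipeline import PipelineConfig, run_session
from tugait.simulate import conference_room, simulate_trial


def _clean_trial(**kw):
    kw.setdefault("subject_height_m", 1.76)
    kw.setdefault("pixel_noise_sigma_px", 0.0)
    kw.setdefault("pose_noise_m", 0.0)
    kw.setdefault("seed", 3)
    return simulate_trial(conference_room(**kw))


class TestFrameSelection:
    def test_selected_frames_are_standing_not_seated(self):
        tr = _clean_trial()
        frames = select_calibration_frames(tr.kp2d, k=5)
        sts_end = tr.truth["phase_bounds"]["SitToStand"][1]
        stsit = tr.truth["phase_bounds"]["StandToSit"][0]
        assert all(sts_end <= t < stsit for t in frames)

    def test_k1_reduces_to_argmax(self):
        tr = _clean_trial()
        extent = tr.kp2d.ankle_midpoint()[:, 1] - tr.kp2d.joint("head")[:, 1]
        frames = select_calibration_frames(tr.kp2d, k=1)
        valid = select_calibration_frames(tr.kp2d, k=30, min_separation=1)
        best = max(valid, key=lambda t: extent[t])
        assert frames == [best]

    def test_tie_breaks_to_earliest_frame(self):
        coords = np.zeros((20, 8, 2))
        # constant upright posture: head above pelvis above ankles, same column
        coords[:, CANONICAL_JOINTS.index("head")] = [500, 100]
        coords[:, CANONICAL_JOINTS.index("pelvis")] = [500, 400]
        for j in ("left_ankle", "right_ankle"):
            coords[:, CANONICAL_JOINTS.index(j)] = [500, 700]
        seq = Keypoints2DSequence(
            fps=30, width=1000, height=1000, joints=list(CANONICAL_JOINTS), coords=coords
        )
        assert select_calibration_frames(seq, k=1) == [0]

    def test_minimum_separation_enforced(self):
        tr = _clean_trial()
        frames = select_calibration_frames(tr.kp2d, k=5, min_separation=10)
        assert min(np.diff(sorted(frames))) >= 10

    def test_all_seated_sequence_fails(self):
        cfg = conference_room(
            subject_height_m=1.76, pixel_noise_sigma_px=0.0, pose_noise_m=0.0, seed=3
        )
        tr = simulate_trial(cfg)
        sit_end = tr.truth["phase_bounds"]["Sit1"][1]
        seated = Keypoints2DSequence(
            fps=30,
            width=tr.kp2d.width,
            height=tr.kp2d.height,
            joints=tr.kp2d.joints,
            coords=tr.kp2d.coords[:sit_end],
        )
        with pytest.raises(CalibrationError):
            calibrate(seated, 1.76, 1.1)


class TestCalibrate:
    def test_noise_free_recovery_within_a_degree(self):
        tr = _clean_trial(fov_deg=60.0, pitch_deg=5.0)
        res = calibrate(tr.kp2d, 1.76, 1.1)
        assert abs(res.camera.fov_deg - 60.0) < 1.0
        assert abs(res.camera.pitch_deg - 5.0) < 0.5
        assert res.residual_m < 1e-3
        assert res.converged

    def test_noisy_recovery_median_over_seeds(self):
        """sigma = 2 px keypoint noise: FOV within 5 degrees and near-point
        ankle depth error below 5 cm, as medians over repeated trials."""
        fov_errs, depth_errs = [], []
        for seed in range(7):
            tr = simulate_trial(
                conference_room(subject_height_m=1.76, pixel_noise_sigma_px=2.0, seed=400 + seed)
            )
            rep = run_session(
                tr.kp2d, tr.kp3d, PipelineConfig(subject_height_m=1.76, cam_height_m=1.1)
            )
            fov_errs.append(abs(rep.calibration.camera.fov_deg - 80.0))
            near_true = tr.truth["near_point_m"]
            turn = rep.phases["Turn1"]
            z = rep.depth.z_geo_root[turn[0] : turn[1]]
            depth_errs.append(abs(float(np.median(z)) - near_true))
        assert np.median(fov_errs) < 5.0
        assert np.median(depth_errs) < 0.05

    def test_invariant_to_horizontal_keypoint_translation(self):
        tr = _clean_trial(fov_deg=60.0, pitch_deg=5.0)
        res1 = calibrate(tr.kp2d, 1.76, 1.1)
        shifted = Keypoints2DSequence(
            fps=30,
            width=tr.kp2d.width,
            height=tr.kp2d.height,
            joints=tr.kp2d.joints,
            coords=tr.kp2d.coords + np.array([37.0, 0.0]),
        )
        res2 = calibrate(shifted, 1.76, 1.1)
        assert res2.camera.fov_deg == pytest.approx(res1.camera.fov_deg, abs=1e-6)
        assert res2.camera.pitch_deg == pytest.approx(res1.camera.pitch_deg, abs=1e-6)

    def test_implausible_subject_height_rejected(self):
        tr = _clean_trial()
        with pytest.raises(CalibrationError):
            calibrate(tr.kp2d, 2.9, 1.1)


class TestGeometricDepthTrack:
    def test_noise_free_depths_match_truth(self):
        tr = _clean_trial()
        geo = geometric_depth_track(tr.kp2d, tr.truth["camera"])
        for side in ("left", "right"):
            err = np.nanmax(np.abs(geo[side] - tr.truth[f"z_{side}"]))
            assert err < 0.01

    def test_stationary_subject_constant_depth(self):
        tr = _clean_trial()
        geo = geometric_depth_track(tr.kp2d, tr.truth["camera"])
        sit = tr.truth["phase_bounds"]["Sit1"]
        z = geo["root"][sit[0] : sit[1]]
        assert np.nanmax(z) - np.nanmin(z) < 1e-3

    def test_depth_noise_grows_with_distance(self):
        """Pixel jitter amplifies into depth noise quadratically with range:
        the same sigma = 2 px produces a larger depth spread at 4.2 m than
        at 1.2 m."""
        from tugait.camera import ground_depth_from_pixel, project_pinhole

        cam = conference_room().camera
        rng = np.random.default_rng(11)
        spreads = []
        for z in (1.2, 4.2):
            v = project_pinhole(np.array([0.0, 0.0, z]), cam)[1]
            depths = ground_depth_from_pixel(v + rng.normal(0, 2.0, 4000), cam)
            spreads.append(np.std(depths[np.isfinite(depths)]))
        assert spreads[1] > spreads[0]
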