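"""Ground-truthed synthetic TUG sessions and labeled feature cohorts.

The trial simulator animates a kinematic stick figure (head, shoulders,
pelvis, hips, ankles at classic anthropometric fractions of stature)
through the standard TUG protocol: static sitting at the far point, a
sit-to-stand rise, a walk toward the camera, a 180-degree turn at the near
point, the walk back, a turn-and-sit, and static sitting.  The figure is
projected through an exact pinhole camera (known FOV, pitch, mounting
height), Gaussian pixel noise plus an optional jitter burst is added, and a
scale-ambiguous smoothed 3D pose stream is emitted alongside — so every
pipeline stage can be exercised against known truth without any recording.

The bodies are kinematic, not biomechanical: ankles stay at floor height
(ground contact is always valid), posture is perfectly upright, and the
foot depth split is a windowed sinusoid of configurable stride amplitude
and cadence.  The 3D pose stream is divided by an arbitrary per-trial scale
(log-uniform in [0.5, 2]) so the scale-alignment machinery is never
vacuously exercised at scale 1.

Ground-truth phase boundaries are computed by applying the segmentation
definitions (threshold crossings, half-prominence turn regions) to the
noise-free kinematic signals — the boundary definitions ARE the crossings,
so this is the exact segmentation of the clean session.  The configured
protocol schedule is stored separately.

The cohort simulator draws labeled gait state vectors directly: per-subject
baselines, multiplicative condition effects for mild (M) and severe (P)
cognitive load, and per-trial Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .camera import CameraModel, project_pinhole
from .errors import ConfigError
from .features import extrema_events
from .io import CANONICAL_JOINTS, Keypoints2DSequence, Keypoints3DSequence
from .segmentation import SegmentationConfig, segment_phases

#: Anthropometric landmark heights as fractions of stature.
HEAD_FRAC = 1.0
SHOULDER_FRAC = 0.82
PELVIS_FRAC = 0.53
SEATED_PELVIS_FRAC = 0.45
SHOULDER_HALFWIDTH_FRAC = 0.1225  # half of a ~0.245*stature biacromial breadth
HIP_HALFWIDTH_FRAC = 0.055
FOOT_HALFWIDTH_M = 0.05

PHASE_NAMES = (
    "sit1",
    "sit_to_stand",
    "walk1",
    "turn1",
    "walk2",
    "turn2",
    "stand_to_sit",
    "sit2",
)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return 3 * x**2 - 2 * x**3


@dataclass
class TrialConfig:
    """One synthetic TUG session; defaults mirror the conference-room setup
    (camera 1.1 m, far point 4.2 m, near point 1.2 m, 1920x1080 at 30 fps)."""

    subject_height_m: float = 1.70
    cam_height_m: float = 1.1
    fov_deg: float = 80.0
    pitch_deg: float = 12.0
    width: int = 1920
    height: int = 1080
    fps: float = 30.0
    far_point_m: float = 4.2
    near_point_m: float = 1.2
    stride_length_m: float = 0.5
    cadence_hz: float = 1.0
    phase_durations_s: dict = field(
        default_factory=lambda: {
            "sit1": 2.0,
            "sit_to_stand": 1.5,
            "walk1": 3.5,
            "turn1": 1.5,
            "walk2": 3.5,
            "turn2": 1.5,
            "stand_to_sit": 1.5,
            "sit2": 2.0,
        }
    )
    pixel_noise_sigma_px: float = 2.0
    burst: tuple | None = None  # (start_s, duration_s, sigma_px)
    pose_scale: float | None = None  # None: drawn log-uniform in [0.5, 2]
    pose_noise_m: float = 0.004  # smooth 3D-pose noise, std in truth meters
    step_ramp_s: float = 0.35  # envelope ramp of the step sinusoid
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.far_point_m > self.near_point_m > 0:
            raise ConfigError("need far_point > near_point > 0")
        missing = [p for p in PHASE_NAMES if p not in self.phase_durations_s]
        if missing:
            raise ConfigError(f"phase durations missing for {missing}")
        if any(self.phase_durations_s[p] <= 0 for p in PHASE_NAMES):
            raise ConfigError("phase durations must be positive")
        if self.burst is not None:
            start, dur, _sig = self.burst
            if start < 0 or dur <= 0 or start + dur > self.total_duration_s:
                raise ConfigError("burst window must lie inside the trial")

    @property
    def total_duration_s(self) -> float:
        return float(sum(self.phase_durations_s[p] for p in PHASE_NAMES))

    @property
    def camera(self) -> CameraModel:
        return CameraModel(
            fov_deg=self.fov_deg,
            pitch_deg=self.pitch_deg,
            cam_height_m=self.cam_height_m,
            width=self.width,
            height=self.height,
        )

    def phase_frame_bounds(self) -> dict[str, tuple[int, int]]:
        """Configured protocol schedule as half-open frame intervals."""
        bounds = {}
        t0 = 0.0
        for p in PHASE_NAMES:
            t1 = t0 + self.phase_durations_s[p]
            bounds[p] = (int(round(t0 * self.fps)), int(round(t1 * self.fps)))
            t0 = t1
        return bounds


def conference_room(**overrides) -> TrialConfig:
    params = {"cam_height_m": 1.1, "far_point_m": 4.2, "near_point_m": 1.2}
    params.update(overrides)
    return TrialConfig(**params)


def living_room(**overrides) -> TrialConfig:
    params = {"cam_height_m": 0.9, "far_point_m": 4.6, "near_point_m": 1.6}
    params.update(overrides)
    return TrialConfig(**params)


PRESETS = {"conference_room": conference_room, "living_room": living_room}


def default_burst(config: TrialConfig, sigma_px: float = 15.0) -> tuple:
    """A 1-second jitter burst late in the walk back, where the subject is
    far from the camera and pixel noise amplifies most strongly into depth."""
    start = sum(
        config.phase_durations_s[p] for p in ("sit1", "sit_to_stand", "walk1", "turn1")
    ) + 0.65 * config.phase_durations_s["walk2"]
    return (start, 1.3, sigma_px)


@dataclass
class SyntheticTrial:
    kp2d: Keypoints2DSequence
    kp3d: Keypoints3DSequence
    truth: dict

    @property
    def frames(self) -> int:
        return self.kp2d.frames


def _phase_profile(config: TrialConfig, n: int):
    """Per-frame root depth z(t), pelvis height y(t), yaw psi(t), step split D(t)."""
    fps = config.fps
    bounds = config.phase_frame_bounds()
    H = config.subject_height_m
    z = np.full(n, config.far_point_m)
    y = np.full(n, SEATED_PELVIS_FRAC * H)
    psi = np.zeros(n)
    d = np.zeros(n)

    standing = PELVIS_FRAC * H
    seated = SEATED_PELVIS_FRAC * H

    def local_tau(name):
        s, e = bounds[name]
        idx = np.arange(s, min(e, n))
        dur = max((e - s) / fps, 1e-9)
        return idx, (idx - s) / fps, dur

    # postural transitions
    idx, tau, dur = local_tau("sit_to_stand")
    y[idx] = seated + (standing - seated) * _smoothstep(tau / dur)
    for name in ("walk1", "turn1", "walk2", "turn2"):
        s, e = bounds[name]
        y[s:e] = standing
    idx, tau, dur = local_tau("stand_to_sit")
    y[idx] = standing + (seated - standing) * _smoothstep(tau / dur)
    s, _ = bounds["sit2"]
    y[s:] = seated

    # root depth
    idx, tau, dur = local_tau("walk1")
    z[idx] = config.far_point_m + (config.near_point_m - config.far_point_m) * _smoothstep(tau / dur)
    for name in ("turn1",):
        s, e = bounds[name]
        z[s:e] = config.near_point_m
    idx, tau, dur = local_tau("walk2")
    z[idx] = config.near_point_m + (config.far_point_m - config.near_point_m) * _smoothstep(tau / dur)
    s, _ = bounds["turn2"]
    z[s:] = config.far_point_m

    # torso yaw: 0 facing the camera, pi after the first turn, 2*pi after the second
    idx, tau, dur = local_tau("turn1")
    psi[idx] = np.pi * _smoothstep(tau / dur)
    s, e = bounds["turn1"]
    psi[e:] = np.pi
    idx, tau, dur = local_tau("turn2")
    psi[idx] = np.pi + np.pi * _smoothstep(tau / dur)
    s, _ = bounds["turn2"]
    e2 = bounds["turn2"][1]
    psi[e2:] = 2 * np.pi

    # alternating step split inside the walking phases, smoothly windowed
    r = config.step_ramp_s
    for name in ("walk1", "walk2"):
        idx, tau, dur = local_tau(name)
        env = np.minimum(_smoothstep(tau / r), _smoothstep((dur - tau) / r))
        d[idx] = config.stride_length_m * np.sin(2 * np.pi * config.cadence_hz * tau) * env
    return z, y, psi, d


def _joint_positions(config: TrialConfig, n: int):
    """(n, 8, 3) world joint positions in canonical order, plus raw profiles."""
    H = config.subject_height_m
    z, y_pelvis, psi, d = _phase_profile(config, n)
    axis = np.stack([np.cos(psi), np.zeros(n), np.sin(psi)], axis=1)
    root = np.stack([np.zeros(n), y_pelvis, z], axis=1)

    def offset(height, lateral, depth=0.0):
        p = root + lateral * axis
        p = p + np.stack(
            [np.zeros(n), height - y_pelvis, np.full(n, 0.0) + depth], axis=1
        )
        return p

    head = offset(y_pelvis + (HEAD_FRAC - PELVIS_FRAC) * H, 0.0)
    sh_y = y_pelvis + (SHOULDER_FRAC - PELVIS_FRAC) * H
    hw_sh = SHOULDER_HALFWIDTH_FRAC * H
    l_sh = offset(sh_y, +hw_sh)
    r_sh = offset(sh_y, -hw_sh)
    pelvis = root
    hw_hip = HIP_HALFWIDTH_FRAC * H
    l_hip = offset(y_pelvis, +hw_hip)
    r_hip = offset(y_pelvis, -hw_hip)
    ankle_y = np.zeros(n)
    l_ank = offset(ankle_y, +FOOT_HALFWIDTH_M, 0.0)
    r_ank = offset(ankle_y, -FOOT_HALFWIDTH_M, 0.0)
    # the step split acts along the walking (depth) axis
    l_ank[:, 2] += d / 2.0
    r_ank[:, 2] -= d / 2.0

    joints = np.stack([head, l_sh, r_sh, pelvis, l_hip, r_hip, l_ank, r_ank], axis=1)
    return joints, {"z_root": z, "y_pelvis": y_pelvis, "psi": psi, "d": d}


def simulate_trial(config: TrialConfig | None = None) -> SyntheticTrial:
    """Generate one ground-truthed TUG session (2D pixels + 3D pose + truth)."""
    config = config or TrialConfig()
    rng = np.random.default_rng(config.seed)
    fps = config.fps
    n = int(round(config.total_duration_s * fps))
    camera = config.camera

    joints, profiles = _joint_positions(config, n)

    # ---- exact projection, then the detector-noise model -----------------
    pixels = project_pinhole(joints, camera)  # (n, 8, 2)
    in_frame = (
        np.isfinite(pixels).all(axis=-1)
        & (pixels[..., 0] >= 0)
        & (pixels[..., 0] <= config.width)
        & (pixels[..., 1] >= 0)
        & (pixels[..., 1] <= config.height)
    )
    noisy = pixels + rng.normal(0.0, config.pixel_noise_sigma_px, size=pixels.shape)
    if config.burst is not None:
        b0, bdur, bsig = config.burst
        s, e = int(round(b0 * fps)), int(round((b0 + bdur) * fps))
        noisy[s:e] += rng.normal(0.0, bsig, size=noisy[s:e].shape)
    # clipping policy: joints whose true projection leaves the frame are
    # lost (NaN, as a detector would lose them); noisy survivors are clipped
    # to the image bounds.
    noisy[..., 0] = np.clip(noisy[..., 0], 0, config.width)
    noisy[..., 1] = np.clip(noisy[..., 1], 0, config.height)
    noisy[~in_frame] = np.nan

    kp2d = Keypoints2DSequence(
        fps=fps,
        width=config.width,
        height=config.height,
        joints=list(CANONICAL_JOINTS),
        coords=noisy,
    )

    # ---- scale-ambiguous smoothed 3D pose stream -------------------------
    if config.pose_scale is None:
        scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    else:
        scale = float(config.pose_scale)
    cam_centered = joints.copy()
    cam_centered[..., 1] -= config.cam_height_m
    pose = cam_centered / scale
    if config.pose_noise_m > 0:
        white = rng.normal(0.0, 1.0, size=pose.shape)
        smooth = gaussian_filter1d(white, sigma=3.0, axis=0)
        smooth *= 1.0 / max(np.std(smooth), 1e-12)
        pose = pose + smooth * (config.pose_noise_m / scale)
    kp3d = Keypoints3DSequence(fps=fps, joints=list(CANONICAL_JOINTS), coords=pose)

    # ---- ground truth -----------------------------------------------------
    z_l = joints[:, list(CANONICAL_JOINTS).index("left_ankle"), 2]
    z_r = joints[:, list(CANONICAL_JOINTS).index("right_ankle"), 2]
    d_clean = z_l - z_r
    h_clean = profiles["y_pelvis"]  # ankles are on the floor
    i_lsh = list(CANONICAL_JOINTS).index("left_shoulder")
    i_rsh = list(CANONICAL_JOINTS).index("right_shoulder")
    dz_clean = np.abs(joints[:, i_lsh, 2] - joints[:, i_rsh, 2])
    truth_seg = segment_phases(h_clean, dz_clean, SegmentationConfig(), fps)

    # truth step events use the same event definition as the detector:
    # prominent extrema of the clean foot split with the cadence-bound
    # refractory gap (0.36 s), at a prominence floor tied to the stride.
    step_prom = 0.25 * config.stride_length_m
    all_steps = extrema_events(
        d_clean, step_prom, int(round(0.36 * fps)), min_abs=step_prom
    )
    walk_mask = truth_seg.walking_mask(n)
    walk_steps = all_steps[walk_mask[all_steps]]

    truth = {
        "camera": camera,
        "pose_scale": scale,
        "phase_bounds": dict(truth_seg.intervals),
        "protocol_bounds": config.phase_frame_bounds(),
        "step_frames_all": all_steps,
        "step_frames_walk": walk_steps,
        "step_strides_m": np.abs(d_clean[walk_steps]),
        "near_point_m": config.near_point_m,
        "far_point_m": config.far_point_m,
        "walking_distance_m": config.far_point_m - config.near_point_m,
        "z_left": z_l,
        "z_right": z_r,
        "z_root": profiles["z_root"],
        "d_signal": d_clean,
        "h_foot": h_clean,
        "dz_shoulder": dz_clean,
        "subject_height_m": config.subject_height_m,
        "cam_height_m": config.cam_height_m,
        "fps": fps,
    }
    return SyntheticTrial(kp2d=kp2d, kp3d=kp3d, truth=truth)


# ---------------------------------------------------------------------------
# labeled feature cohorts
# ---------------------------------------------------------------------------

#: Per-subject baseline (mean, between-subject SD) of each state-vector
#: component for an unimpaired adult performing a ~3 m TUG.
BASELINES = {
    "T_total": (10.5, 0.8),
    "V_walk": (0.55, 0.05),
    "T_turn": (1.2, 0.10),
    "T_sts": (1.5, 0.15),
    "N_total": (14.0, 1.0),
    "N_walk": (12.0, 1.0),
    "SL_mean": (0.55, 0.04),
    "CV": (12.0, 2.0),
}

#: Multiplicative condition effects: mild load slows and destabilizes gait,
#: severe load more so (plus turning and sit-to-stand penalties).
DEFAULT_EFFECTS = {
    "M": {"T_total": 1.15, "CV": 1.5, "V_walk": 0.9},
    "P": {"T_total": 1.35, "CV": 2.2, "V_walk": 0.75, "T_turn": 1.4, "T_sts": 1.3},
}


@dataclass
class CohortSpec:
    n_subjects: int = 10
    trials_per_condition: int = 3
    effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()})
    noise_sd: float = 0.05  # relative per-trial noise
    subject_sd_scale: float = 1.0  # scales between-subject baseline spread
    seed: int = 0

    def __post_init__(self) -> None:
        m, p = self.effects.get("M", {}), self.effects.get("P", {})
        for feat, em in m.items():
            ep = p.get(feat, 1.0)
            if np.sign(np.log(ep)) not in (0.0, np.sign(np.log(em))) or abs(
                np.log(ep)
            ) < abs(np.log(em)) - 1e-12:
                raise ConfigError(
                    f"effect ordering violated for {feat}: P ({ep}) must be at "
                    f"least as extreme as M ({em})"
                )


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a labeled cohort feature table (one row per subject x condition x trial)."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    feats = list(BASELINES)
    for subj in range(spec.n_subjects):
        base = {
            f: mu + spec.subject_sd_scale * sd * rng.standard_normal()
            for f, (mu, sd) in BASELINES.items()
        }
        base["N_walk"] = max(4.0, base["N_walk"])
        base["N_total"] = max(base["N_walk"], base["N_total"])
        for label in ("N", "M", "P"):
            eff = spec.effects.get(label, {})
            for trial in range(spec.trials_per_condition):
                row = {"subject_id": f"S{subj + 1}", "trial_id": f"{label}{trial + 1}", "label": label}
                for f in feats:
                    val = base[f] * eff.get(f, 1.0)
                    val *= 1.0 + spec.noise_sd * rng.standard_normal()
                    row[f] = val
                row["N_walk"] = int(max(2, round(row["N_walk"])))
                row["N_total"] = int(max(row["N_walk"], round(row["N_total"])))
                row["CV"] = max(0.5, row["CV"])
                for f in ("T_total", "V_walk", "T_turn", "T_sts", "SL_mean"):
                    row[f] = max(1e-3, row[f])
                rows.append(row)
    cols = ["subject_id", "trial_id", "label"] + feats
    return pd.DataFrame(rows)[cols]


def separable_cohort_spec(seed: int = 0) -> CohortSpec:
    """A cohort whose class means sit several pooled SDs apart: tiny noise,
    tight subject baselines, strong ordered effects."""
    return CohortSpec(
        n_subjects=10,
        trials_per_condition=1,
        effects={
            "M": {"T_total": 1.3, "CV": 1.8, "V_walk": 0.85},
            "P": {"T_total": 1.7, "CV": 3.2, "V_walk": 0.65, "T_turn": 1.6, "T_sts": 1.5},
        },
        noise_sd=0.02,
        subject_sd_scale=0.15,
        seed=seed,
    )


def overlap_cohort_spec(seed: int = 0) -> CohortSpec:
    """M and P share identical strong effects: both sit far from N, but are
    mutually indistinguishable, forcing errors into the M/P block only."""
    shared = {"T_total": 1.5, "CV": 2.5, "V_walk": 0.7}
    return CohortSpec(
        n_subjects=8,
        trials_per_condition=2,
        effects={"M": dict(shared), "P": dict(shared)},
        noise_sd=0.03,
        subject_sd_scale=0.15,
        seed=seed,
    )
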