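"""End-to-end session analysis: keypoints in, clinical report out.

``run_session`` executes the full chain in order — load & smooth, geometric
self-calibration, noise-adaptive depth fusion, phase segmentation, gait
parameter extraction — and assembles a :class:`SessionReport`.  When
simulator truth is available, ``evaluate_against_truth`` scores the three
spatial error indicators (near-point, far-point and walking-distance error)
that quantify metric fidelity under the standardized TUG geometry.

Far/near point estimates use robust extremes (2nd/98th percentile of the
fused root depth within the relevant phases) rather than raw min/max, so a
single surviving outlier frame cannot masquerade as the turning point.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .calibration import CalibrationResult, calibrate, geometric_depth_track
from .errors import SchemaError, TugError
from .features import GaitStateVector, StepEvents, build_state_vector, detect_steps, foot_depth_difference
from .fusion import DepthTrack, FusionConfig, fuse_track
from .io import (
    Keypoints2DSequence,
    Keypoints3DSequence,
    check_paired,
    interpolate_gaps,
    load_keypoints2d,
    load_keypoints3d,
    preprocess_sequence,
)
from .segmentation import (
    PhaseSegmentation,
    SegmentationConfig,
    segment_phases,
    shoulder_depth_signal,
    vertical_signal,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of a session analysis, fully serializable."""

    subject_height_m: float = 1.70
    cam_height_m: float = 1.1
    calib_k: int = 5
    calib_min_separation: int = 10
    smoothing_cutoff_hz: float = 6.0
    smoothing_order: int = 4
    smooth_2d: bool = True
    smooth_3d: bool = True
    max_gap_frames: int = 10
    fusion: FusionConfig = field(default_factory=FusionConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    min_step_interval_s: float = 0.36
    step_prominence_frac: float = 0.5
    step_lowpass_hz: float | None = 3.0  # band-limit D(t); cadence ~1 Hz passes
    fps_override: float | None = None
    extreme_percentile: float = 2.0  # robust far/near extremes

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("fusion"), dict):
            d["fusion"] = FusionConfig(**d["fusion"])
        if isinstance(d.get("segmentation"), dict):
            d["segmentation"] = SegmentationConfig(**d["segmentation"])
        return cls(**d)


@dataclass
class SessionReport:
    """Everything one TUG session produced, stage by stage."""

    calibration: CalibrationResult
    phases: PhaseSegmentation
    state_vector: GaitStateVector
    steps: StepEvents
    depth: DepthTrack
    near_point_m: float
    far_point_m: float
    walking_distance_m: float
    stage_timings_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "calibration": self.calibration.to_dict(),
            "phases": self.phases.to_records(),
            "state_vector": self.state_vector.to_dict(),
            "state_table": self.state_vector.to_table().to_dict(orient="records"),
            "steps": self.steps.to_frame(self.phases.fps).to_dict(orient="records"),
            "near_point_m": self.near_point_m,
            "far_point_m": self.far_point_m,
            "walking_distance_m": self.walking_distance_m,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _robust_extreme(series: np.ndarray, mask: np.ndarray, pct: float, upper: bool) -> float:
    vals = series[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise SchemaError("no finite depth samples inside the requested phases")
    q = 100.0 - pct if upper else pct
    return float(np.percentile(vals, q))


def run_session(
    kp2d: Keypoints2DSequence | str | Path,
    kp3d: Keypoints3DSequence | str | Path,
    config: PipelineConfig,
) -> SessionReport:
    """Analyze one TUG session end to end.

    Steps: (1) pose streams are gap-filled and low-pass smoothed; (2) the
    camera is self-calibrated from upright frames plus the known subject and
    camera heights; (3) ground-plane ankle depths are fused with the aligned
    3D-pose prior under the jitter-driven confidence weight; (4) phases are
    segmented from vertical displacement and shoulder depth difference;
    (5) step events and the state vector are extracted.
    """
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if not isinstance(kp2d, Keypoints2DSequence):
        kp2d = load_keypoints2d(kp2d)
    if not isinstance(kp3d, Keypoints3DSequence):
        kp3d = load_keypoints3d(kp3d)
    if config.fps_override:
        kp2d.fps = config.fps_override
        kp3d.fps = config.fps_override
    check_paired(kp2d, kp3d)
    fps = kp2d.fps
    if config.smooth_2d:
        kp2d = preprocess_sequence(
            kp2d, config.max_gap_frames, config.smoothing_cutoff_hz, config.smoothing_order
        )
    if config.smooth_3d:
        kp3d = preprocess_sequence(
            kp3d, config.max_gap_frames, config.smoothing_cutoff_hz, config.smoothing_order
        )
    timings["load_smooth"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    calib = calibrate(
        kp2d,
        config.subject_height_m,
        config.cam_height_m,
        k=config.calib_k,
        min_separation=config.calib_min_separation,
    )
    timings["calibrate"] = time.perf_counter() - t0
    logger.info(
        "calibrated: fov=%.2f deg pitch=%.2f deg residual=%.4f m",
        calib.camera.fov_deg,
        calib.camera.pitch_deg,
        calib.residual_m,
    )

    t0 = time.perf_counter()
    geo = geometric_depth_track(kp2d, calib.camera)
    z_geo_l = interpolate_gaps(geo["left"], max_gap_frames=kp2d.frames)
    z_geo_r = interpolate_gaps(geo["right"], max_gap_frames=kp2d.frames)
    z_dl_l = kp3d.joint("left_ankle")[:, 2]
    z_dl_r = kp3d.joint("right_ankle")[:, 2]
    depth = fuse_track(z_geo_l, z_geo_r, z_dl_l, z_dl_r, fps, config.fusion)
    timings["fuse"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    h_foot = vertical_signal(kp3d, smooth=not config.smooth_3d)
    dz_sh = shoulder_depth_signal(kp3d, depth.scale, smooth=not config.smooth_3d)
    phases = segment_phases(h_foot, dz_sh, config.segmentation, fps)
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    d_signal = foot_depth_difference(depth.z_final_left, depth.z_final_right)
    if config.step_lowpass_hz:
        from .io import lowpass_smooth

        d_signal = lowpass_smooth(
            d_signal, fps, cutoff_hz=config.step_lowpass_hz, order=config.smoothing_order
        )
    steps = detect_steps(
        d_signal,
        phases,
        fps,
        min_step_interval_s=config.min_step_interval_s,
        prominence_frac=config.step_prominence_frac,
    )
    state = build_state_vector(steps, phases, fps)
    timings["extract"] = time.perf_counter() - t0

    n = kp2d.frames
    near_mask = np.zeros(n, dtype=bool)
    for name in ("Walk1", "Turn1"):
        s, e = phases[name]
        near_mask[s:e] = True
    far_mask = np.zeros(n, dtype=bool)
    for name in ("SitToStand", "Walk1"):
        s, e = phases[name]
        far_mask[s:e] = True
    near = _robust_extreme(depth.z_final_root, near_mask, config.extreme_percentile, upper=False)
    far = _robust_extreme(depth.z_final_root, far_mask, config.extreme_percentile, upper=True)

    return SessionReport(
        calibration=calib,
        phases=phases,
        state_vector=state,
        steps=steps,
        depth=depth,
        near_point_m=near,
        far_point_m=far,
        walking_distance_m=far - near,
        stage_timings_s=timings,
    )


def evaluate_against_truth(report: SessionReport, truth: dict) -> dict:
    """Spatial error indicators against simulator (or tape-measured) truth."""
    for key in ("near_point_m", "far_point_m", "walking_distance_m"):
        if key not in truth:
            raise SchemaError(f"truth is missing field {key!r}")
    return {
        "near_point_error_m": abs(report.near_point_m - truth["near_point_m"]),
        "far_point_error_m": abs(report.far_point_m - truth["far_point_m"]),
        "walking_distance_error_m": abs(
            report.walking_distance_m - truth["walking_distance_m"]
        ),
    }


def error_summary(errors: list[dict]) -> dict:
    """Median and inter-quartile range per indicator over a batch of trials."""
    out = {}
    for key in ("near_point_error_m", "far_point_error_m", "walking_distance_error_m"):
        vals = np.asarray([e[key] for e in errors], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[key] = {"median": float(med), "iqr": float(q3 - q1), "n": len(vals)}
    return out
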