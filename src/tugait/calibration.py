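"""Optimization-based geometric self-calibration.

Recovers the unknown camera parameters Phi = {FOV, pitch} from the keypoint
stream plus two easily measured scalars — the subject's standing height and
the camera mounting height.  Upright frames are selected by maximizing the
vertical pixel extent of the body; at each selected frame the back-projected
body height under candidate parameters is compared with the known height,
and the squared residuals are minimized with the Trust Region Reflective
solver inside the physical parameter box.

With a single calibration frame the residual is scalar and the two-parameter
problem is underdetermined, so by default the top-k (k=5) upright frames
with a minimum pairwise separation are used; walking between them spans
different depths, which makes FOV and pitch jointly identifiable.  ``k=1``
with the pitch pinned to zero is retained as a strict single-frame mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .camera import (
    FOV_BOUNDS_DEG,
    PITCH_BOUNDS_DEG,
    CameraModel,
    back_project_height,
    ground_depth_from_pixel,
)
from .errors import CalibrationError, DegenerateGeometryError, HorizonError
from .io import Keypoints2DSequence

#: Coarse FOV multi-start grid; the height-residual valley is shallow along
#: the FOV axis, so a single start can settle in a local minimum.
FOV_STARTS_DEG = (40.0, 60.0, 80.0)

#: Selected calibration frames must span at least this much vertical ankle
#: travel (px): at a single depth the two camera parameters are not jointly
#: identifiable, and a static (e.g. never-standing) sequence has none.
MIN_ANKLE_SPREAD_PX = 5.0


@dataclass
class CalibrationResult:
    camera: CameraModel
    calib_frames: list[int]
    residual_m: float  # RMS height residual over the calibration frames
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fov_deg": self.camera.fov_deg,
            "pitch_deg": self.camera.pitch_deg,
            "cam_height_m": self.camera.cam_height_m,
            "residual_m": self.residual_m,
            "calib_frames": [int(t) for t in self.calib_frames],
        }


def _upright_mask(
    kp2d: Keypoints2DSequence, tol_deg: float, ankle_disparity_tol_px: float
) -> np.ndarray:
    """Frames where the subject is upright and in mid-stance.

    Two screens: the angle between the pelvis->head and ankle->pelvis pixel
    vectors must stay below ``tol_deg`` (excludes mid-stride lean and seated
    forward-bend frames), and the two ankle pixels must be vertically
    aligned within ``ankle_disparity_tol_px`` (excludes frames where the
    feet are split in depth, which would bias the ankle-midpoint ground
    anchor).
    """
    head = kp2d.joint("head")
    pelvis = kp2d.joint("pelvis")
    ankle = kp2d.ankle_midpoint()
    up1 = pelvis - head  # toward the floor in pixel space (v down)
    up2 = ankle - pelvis
    n1 = np.linalg.norm(up1, axis=1)
    n2 = np.linalg.norm(up2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", up1, up2) / (n1 * n2)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    finite = np.isfinite(head).all(1) & np.isfinite(ankle).all(1) & np.isfinite(pelvis).all(1)
    disparity = np.abs(
        kp2d.joint("left_ankle")[:, 1] - kp2d.joint("right_ankle")[:, 1]
    )
    midstance = disparity <= ankle_disparity_tol_px
    return finite & (n1 > 0) & (n2 > 0) & (ang <= tol_deg) & midstance


def select_calibration_frames(
    kp2d: Keypoints2DSequence,
    k: int = 5,
    min_separation: int = 10,
    posture_tol_deg: float = 10.0,
    ankle_disparity_tol_px: float = 6.0,
) -> list[int]:
    """Pick the k most upright frames by vertical pixel extent.

    Frames are ranked by ``v_ankle - v_head`` (largest body projection) and
    selected greedily subject to a minimum pairwise frame separation so the
    chosen frames span different depths.  Ties break toward the earliest
    frame.  ``k=1`` reduces to a plain argmax.
    """
    if k < 1:
        raise CalibrationError("k must be >= 1")
    extent = kp2d.ankle_midpoint()[:, 1] - kp2d.joint("head")[:, 1]
    valid = (
        _upright_mask(kp2d, posture_tol_deg, ankle_disparity_tol_px)
        & np.isfinite(extent)
        & (extent > 0)
    )
    if valid.sum() < k:
        raise CalibrationError(
            f"only {int(valid.sum())} valid upright frames, need {k}"
        )
    candidates = np.flatnonzero(valid)
    # stable sort: descending extent, then ascending frame index
    order = candidates[np.lexsort((candidates, -extent[candidates]))]
    chosen: list[int] = []
    for t in order:
        if all(abs(int(t) - c) >= min_separation for c in chosen):
            chosen.append(int(t))
            if len(chosen) == k:
                break
    if len(chosen) < k:
        raise CalibrationError(
            f"could not find {k} upright frames separated by {min_separation}; "
            f"got {len(chosen)}"
        )
    return sorted(chosen)


def _height_residuals(
    params: np.ndarray,
    fixed_pitch: float | None,
    v_ankle: np.ndarray,
    v_head: np.ndarray,
    cam_height_m: float,
    subject_height_m: float,
    width: int,
    height: int,
) -> np.ndarray:
    if fixed_pitch is None:
        fov, pitch = params
    else:
        fov, pitch = params[0], fixed_pitch
    cam = CameraModel(
        fov_deg=float(fov),
        pitch_deg=float(pitch),
        cam_height_m=cam_height_m,
        width=width,
        height=height,
    )
    out = np.empty(len(v_ankle))
    for i, (va, vh) in enumerate(zip(v_ankle, v_head)):
        try:
            out[i] = back_project_height(va, vh, cam) - subject_height_m
        except (HorizonError, DegenerateGeometryError):
            out[i] = 10.0  # large penalty steers the solver back in bounds
    return out


def calibrate(
    kp2d: Keypoints2DSequence,
    subject_height_m: float,
    cam_height_m: float,
    k: int = 5,
    min_separation: int = 10,
    posture_tol_deg: float = 10.0,
    ankle_disparity_tol_px: float = 6.0,
    max_residual_m: float = 0.15,
) -> CalibrationResult:
    """Solve for {FOV, pitch} from upright frames and known heights."""
    if not 1.0 <= subject_height_m <= 2.3:
        raise CalibrationError(
            f"subject height {subject_height_m} m outside plausible range [1.0, 2.3]"
        )
    frames = select_calibration_frames(
        kp2d, k, min_separation, posture_tol_deg, ankle_disparity_tol_px
    )
    v_ankle = kp2d.ankle_midpoint()[frames, 1]
    v_head = kp2d.joint("head")[frames, 1]
    if k > 1 and float(v_ankle.max() - v_ankle.min()) < MIN_ANKLE_SPREAD_PX:
        raise CalibrationError(
            "calibration frames show no depth diversity (ankle rows span "
            f"{float(v_ankle.max() - v_ankle.min()):.1f} px); the subject "
            "must traverse the walkway upright — a static or seated-only "
            "sequence cannot constrain FOV and pitch"
        )

    fixed_pitch = 0.0 if k == 1 else None
    eps = 1e-6
    if fixed_pitch is None:
        lb = [FOV_BOUNDS_DEG[0] + eps, PITCH_BOUNDS_DEG[0] + eps]
        ub = [FOV_BOUNDS_DEG[1] - eps, PITCH_BOUNDS_DEG[1] - eps]
    else:
        lb, ub = [FOV_BOUNDS_DEG[0] + eps], [FOV_BOUNDS_DEG[1] - eps]

    best = None
    for fov0 in FOV_STARTS_DEG:
        x0 = [fov0] if fixed_pitch is not None else [fov0, 0.0]
        sol = least_squares(
            _height_residuals,
            x0,
            bounds=(lb, ub),
            method="trf",
            args=(
                fixed_pitch,
                v_ankle,
                v_head,
                cam_height_m,
                subject_height_m,
                kp2d.width,
                kp2d.height,
            ),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    fov = float(best.x[0])
    pitch = float(best.x[1]) if fixed_pitch is None else fixed_pitch
    residual = float(np.sqrt(np.mean(best.fun**2)))
    camera = CameraModel(
        fov_deg=fov,
        pitch_deg=pitch,
        cam_height_m=cam_height_m,
        width=kp2d.width,
        height=kp2d.height,
    )
    diagnostics = {
        "cost": float(best.cost),
        "status": int(best.status),
        "n_frames": len(frames),
        # at (near-)zero pitch the height residual is focal-length invariant:
        # Z = h*f/(v_a - c_y) and est H = h*(v_a - v_h)/(v_a - c_y), so the
        # FOV cancels exactly and only the pitch is observable.
        "fov_identifiable": abs(pitch) >= 0.5,
    }
    if not best.success or residual > max_residual_m:
        raise CalibrationError(
            f"calibration failed: residual {residual:.3f} m "
            f"(limit {max_residual_m} m), solver status {best.status}; "
            f"frames {frames}"
        )
    return CalibrationResult(
        camera=camera,
        calib_frames=frames,
        residual_m=residual,
        converged=bool(best.success),
        diagnostics=diagnostics,
    )


def geometric_depth_track(
    kp2d: Keypoints2DSequence, camera: CameraModel
) -> dict[str, np.ndarray]:
    """Per-frame metric ankle depths under the ground-plane constraint.

    Returns ``{"left", "right", "root"}`` depth series in meters; frames
    whose ray misses the floor (at/above horizon) propagate as NaN gaps.
    """
    z_left = ground_depth_from_pixel(kp2d.joint("left_ankle")[:, 1], camera)
    z_right = ground_depth_from_pixel(kp2d.joint("right_ankle")[:, 1], camera)
    return {
        "left": z_left,
        "right": z_right,
        "root": 0.5 * (z_left + z_right),
    }
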