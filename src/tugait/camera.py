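"""Pinhole camera model and ground-plane geometry.

The camera is a minimal pinhole: vertical field of view (FOV), downward
pitch angle theta, principal point at the image center, zero skew and
distortion.  The world frame has its origin on the floor directly under the
optical center, ``y`` up and ``z`` running along the ground away from the
camera; the camera sits at ``(0, cam_height, 0)`` with its optical axis
tilted ``pitch`` degrees toward the floor (positive = looking down).

Under the ground-plane constraint (a pixel known to image a floor-contact
point, here the ankle midpoint), depth is recovered in closed form:

    Z = cam_height / tan(theta + arctan((v - c_y) / f))

and the subject's head height follows from the same ray geometry at the
recovered ground distance.  ``project_pinhole`` is the exact forward model
and serves as the independent oracle for all back-projection math.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, HorizonError

FOV_BOUNDS_DEG = (20.0, 120.0)
PITCH_BOUNDS_DEG = (-30.0, 30.0)


@dataclass(frozen=True)
class CameraModel:
    """Calibration parameter set: FOV and pitch plus known mounting geometry."""

    fov_deg: float  # vertical field of view
    pitch_deg: float  # downward pitch (positive = toward the floor)
    cam_height_m: float  # optical-center height above the floor
    width: int = 1920
    height: int = 1080

    def __post_init__(self) -> None:
        lo, hi = FOV_BOUNDS_DEG
        if not lo <= self.fov_deg <= hi:
            raise ValueError(f"fov_deg must be in [{lo}, {hi}], got {self.fov_deg}")
        lo, hi = PITCH_BOUNDS_DEG
        if not lo <= self.pitch_deg <= hi:
            raise ValueError(f"pitch_deg must be in [{lo}, {hi}], got {self.pitch_deg}")
        if not self.cam_height_m > 0:
            raise ValueError("cam_height_m must be positive")

    @property
    def focal_px(self) -> float:
        return (self.height / 2.0) / math.tan(math.radians(self.fov_deg) / 2.0)

    @property
    def cx(self) -> float:
        return self.width / 2.0

    @property
    def cy(self) -> float:
        return self.height / 2.0

    @property
    def pitch_rad(self) -> float:
        return math.radians(self.pitch_deg)

    def to_dict(self) -> dict:
        return {
            "fov_deg": self.fov_deg,
            "pitch_deg": self.pitch_deg,
            "cam_height_m": self.cam_height_m,
            "width": self.width,
            "height": self.height,
        }


def project_pinhole(points3d_world: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Project world points (floor origin, y up, z away from camera) to pixels.

    Parameters
    ----------
    points3d_world : (..., 3) array
    camera : CameraModel

    Returns
    -------
    (..., 2) array of (u, v) pixels; points at or behind the camera plane
    come back NaN.
    """
    pts = np.asarray(points3d_world, dtype=float)
    x = pts[..., 0]
    y = pts[..., 1] - camera.cam_height_m
    z = pts[..., 2]
    th = camera.pitch_rad
    # camera axes in world coords: right (1,0,0); down (0,-cos,-sin);
    # forward (0,-sin,cos) for a downward pitch.
    xc = x
    yc = -math.cos(th) * y - math.sin(th) * z
    zc = -math.sin(th) * y + math.cos(th) * z
    f = camera.focal_px
    with np.errstate(divide="ignore", invalid="ignore"):
        u = camera.cx + f * xc / zc
        v = camera.cy + f * yc / zc
    behind = ~(zc > 0)
    u = np.where(behind, np.nan, u)
    v = np.where(behind, np.nan, v)
    return np.stack([u, v], axis=-1)


def ground_depth_from_pixel(v_pixel, camera: CameraModel):
    """Metric ground depth of a floor-contact pixel (v-coordinate only).

    Returns the horizontal ground distance Z from the camera foot-point.
    Scalar input raises :class:`HorizonError` when the viewing ray does not
    intersect the floor (angle at or above the horizon); array input
    propagates such frames as NaN.
    """
    v = np.asarray(v_pixel, dtype=float)
    angle = camera.pitch_rad + np.arctan((v - camera.cy) / camera.focal_px)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(angle > 0, camera.cam_height_m / np.tan(angle), np.nan)
    if np.ndim(v_pixel) == 0:
        z = float(z)
        if not np.isfinite(z):
            raise HorizonError(
                f"pixel v={float(v):.1f} views at or above the horizon "
                f"(ray angle {math.degrees(float(angle)):.2f} deg)"
            )
        return z
    return z


def height_above_floor(v_pixel, depth_m, camera: CameraModel):
    """Height of a point at known ground distance from its pixel v-coordinate."""
    v = np.asarray(v_pixel, dtype=float)
    elev = np.arctan((camera.cy - v) / camera.focal_px) - camera.pitch_rad
    h = camera.cam_height_m + np.asarray(depth_m) * np.tan(elev)
    return float(h) if np.ndim(v_pixel) == 0 else h


def back_project_height(
    v_ankle_mid: float, v_head: float, camera: CameraModel, min_depth_m: float = 0.2
) -> float:
    """Estimate standing body height from ankle-midpoint and head pixels.

    The ankle midpoint anchors the ground distance via the ground-plane
    constraint; the head ray is intersected with the vertical line at that
    distance.  This is the back-projection map whose mismatch with the known
    subject height drives self-calibration.
    """
    if not (np.isfinite(v_ankle_mid) and np.isfinite(v_head)):
        raise DegenerateGeometryError("ankle or head pixel is not finite")
    z = ground_depth_from_pixel(float(v_ankle_mid), camera)
    if z < min_depth_m:
        raise DegenerateGeometryError(
            f"subject at ground distance {z:.3f} m is too close to the camera"
        )
    return height_above_floor(float(v_head), z, camera)
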