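"""Noise-adaptive fusion of geometric depth with the 3D-pose depth prior.

The ground-plane depth track ``Z_geo`` is metric but inherits keypoint
jitter, amplified quadratically with distance; the 3D-pose depth ``Z_dl``
is temporally smooth but scale-ambiguous.  Fusion proceeds in four steps:

1. jitter level ``eta(t)``: windowed mean absolute residual of ``Z_geo``
   around a robust moving-median baseline;
2. confidence weight ``w(t)``: piecewise-linear transfer of ``eta`` between
   a stable threshold (w=1) and a jitter threshold, with a 0.1 floor that
   preserves weak metric anchoring under severe jitter;
3. scale alignment ``s = std(Z_geo)/std(Z_dl)`` over stable frames;
4. blend ``Z_final = w*Z_geo + (1-w)*Z_dl'`` where the prior is first
   affinely anchored (scaled AND mean-shifted onto ``Z_geo`` over stable
   frames — the camera-centered prior carries an arbitrary offset, so a
   pure scale product would corrupt the metric track).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegeneratePriorError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    """Thresholds and window for jitter quantification and weighting.

    Defaults: the stable threshold is of the order of the per-frame depth
    resolution at mid-range; the jitter threshold sits an order of magnitude
    higher so the floor engages only for genuine detector glitches.
    """

    window_frames: int = 15  # W, odd; 0.5 s at 30 fps
    tau_stable: float = 0.05  # m
    tau_jitter: float = 0.15  # m
    weight_floor: float = 0.1
    baseline_method: str = "moving_median"  # or "lowpass"
    lowpass_cutoff_hz: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_stable < self.tau_jitter:
            raise ParameterError("need 0 < tau_stable < tau_jitter")
        if not 0 < self.weight_floor < 1:
            raise ParameterError("weight_floor must be in (0, 1)")
        if self.window_frames < 3 or self.window_frames % 2 == 0:
            raise ParameterError("window_frames must be odd and >= 3")
        if self.baseline_method not in ("moving_median", "lowpass"):
            raise ParameterError(f"unknown baseline {self.baseline_method!r}")


@dataclass
class DepthTrack:
    """Per-foot fused depth streams with their fusion byproducts."""

    fps: float
    z_geo_left: np.ndarray
    z_geo_right: np.ndarray
    z_final_left: np.ndarray
    z_final_right: np.ndarray
    eta_left: np.ndarray
    eta_right: np.ndarray
    w_left: np.ndarray
    w_right: np.ndarray
    scale: float
    offset: float

    @property
    def z_final_root(self) -> np.ndarray:
        return 0.5 * (self.z_final_left + self.z_final_right)

    @property
    def z_geo_root(self) -> np.ndarray:
        return 0.5 * (self.z_geo_left + self.z_geo_right)

    def to_frame(self) -> pd.DataFrame:
        """CSV-friendly dump for plotting/debugging."""
        t = np.arange(len(self.z_geo_left)) / self.fps
        return pd.DataFrame(
            {
                "t": t,
                "z_geo_L": self.z_geo_left,
                "z_geo_R": self.z_geo_right,
                "z_final_L": self.z_final_left,
                "z_final_R": self.z_final_right,
                "eta": 0.5 * (self.eta_left + self.eta_right),
                "w": 0.5 * (self.w_left + self.w_right),
            }
        )


def _baseline(z: np.ndarray, config: FusionConfig, fps: float | None) -> np.ndarray:
    if config.baseline_method == "moving_median":
        return (
            pd.Series(z)
            .rolling(config.window_frames, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    from .io import lowpass_smooth  # lazy: avoids import cycle at module load

    if fps is None:
        raise ParameterError("lowpass baseline requires fps")
    return lowpass_smooth(z, fps, cutoff_hz=config.lowpass_cutoff_hz)


def jitter_level(
    z_geo: np.ndarray, config: FusionConfig | None = None, fps: float | None = None
) -> np.ndarray:
    """Windowed mean absolute residual of the geometric depth (eta).

    The baseline is a centered moving median (robust to the very spikes
    being measured); edges use truncated windows.
    """
    config = config or FusionConfig()
    z = np.asarray(z_geo, dtype=float)
    if len(z) < config.window_frames:
        raise ParameterError(
            f"series of length {len(z)} shorter than window {config.window_frames}"
        )
    if not np.all(np.isfinite(z)):
        raise ParameterError("z_geo contains NaN; interpolate gaps first")
    resid = np.abs(z - _baseline(z, config, fps))
    return (
        pd.Series(resid)
        .rolling(config.window_frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def confidence_weight(eta: np.ndarray, config: FusionConfig | None = None) -> np.ndarray:
    """Piecewise-linear confidence transfer: 1 when stable, floor when jittery."""
    config = config or FusionConfig()
    eta = np.asarray(eta, dtype=float)
    w = (config.tau_jitter - eta) / (config.tau_jitter - config.tau_stable)
    w = np.where(eta <= config.tau_stable, 1.0, w)
    w = np.where(eta >= config.tau_jitter, config.weight_floor, w)
    return np.clip(w, config.weight_floor, 1.0)


def scale_factor(
    z_geo: np.ndarray, z_dl: np.ndarray, frames_mask: np.ndarray | None = None
) -> float:
    """Scale alignment factor: population-std ratio of the two depth streams."""
    z_geo = np.asarray(z_geo, dtype=float)
    z_dl = np.asarray(z_dl, dtype=float)
    if frames_mask is not None:
        z_geo = z_geo[frames_mask]
        z_dl = z_dl[frames_mask]
    if len(np.unique(z_dl[np.isfinite(z_dl)])) < 2:
        raise DegeneratePriorError("depth prior has no variance; cannot align scale")
    if len(np.unique(z_geo[np.isfinite(z_geo)])) < 2:
        raise DegeneratePriorError("geometric depth has no variance; cannot align scale")
    return float(np.std(z_geo) / np.std(z_dl))


def fuse(
    z_geo: np.ndarray,
    z_dl: np.ndarray,
    w: np.ndarray,
    s: float,
    config: FusionConfig | None = None,
) -> np.ndarray:
    """Blend geometric depth with the affinely anchored prior.

    Anchoring uses stable frames (w == 1): the prior is scaled by ``s`` about
    its stable-frame mean and shifted onto the stable-frame mean of
    ``Z_geo``.  When no frame is stable, full-series means are used (logged).
    """
    config = config or FusionConfig()
    z_geo = np.asarray(z_geo, dtype=float)
    z_dl = np.asarray(z_dl, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(z_geo) == len(z_dl) == len(w)):
        raise ParameterError("z_geo, z_dl and w must share length")
    stable = w >= 1.0 - 1e-9
    if not stable.any():
        logger.warning("no stable frames for prior anchoring; using full-series means")
        stable = np.ones_like(w, dtype=bool)
    mu_dl = float(np.mean(z_dl[stable]))
    mu_geo = float(np.mean(z_geo[stable]))
    z_dl_anchored = s * (z_dl - mu_dl) + mu_geo
    return w * z_geo + (1.0 - w) * z_dl_anchored


def fuse_track(
    z_geo_left: np.ndarray,
    z_geo_right: np.ndarray,
    z_dl_left: np.ndarray,
    z_dl_right: np.ndarray,
    fps: float,
    config: FusionConfig | None = None,
    scale_mask: np.ndarray | None = None,
) -> DepthTrack:
    """Run the full fusion chain per foot and assemble a :class:`DepthTrack`.

    The scale factor is shared between feet and computed from the root
    (two-foot mean) depth; jitter and weights are computed per foot.  The
    default scale mask is the stable (w == 1) frame set of the root track.
    """
    config = config or FusionConfig()
    z_geo_root = 0.5 * (np.asarray(z_geo_left, float) + np.asarray(z_geo_right, float))
    z_dl_root = 0.5 * (np.asarray(z_dl_left, float) + np.asarray(z_dl_right, float))

    eta_l = jitter_level(z_geo_left, config, fps)
    eta_r = jitter_level(z_geo_right, config, fps)
    w_l = confidence_weight(eta_l, config)
    w_r = confidence_weight(eta_r, config)

    if scale_mask is None:
        w_root = confidence_weight(jitter_level(z_geo_root, config, fps), config)
        scale_mask = w_root >= 1.0 - 1e-9
        if not scale_mask.any():
            scale_mask = None  # fall back to all frames
    s = scale_factor(z_geo_root, z_dl_root, scale_mask)

    z_fin_l = fuse(z_geo_left, z_dl_left, w_l, s, config)
    z_fin_r = fuse(z_geo_right, z_dl_right, w_r, s, config)

    stable_root = (w_l >= 1 - 1e-9) & (w_r >= 1 - 1e-9)
    if not stable_root.any():
        stable_root = np.ones_like(w_l, dtype=bool)
    offset = float(np.mean(z_geo_root[stable_root]) - s * np.mean(z_dl_root[stable_root]))

    return DepthTrack(
        fps=fps,
        z_geo_left=np.asarray(z_geo_left, float),
        z_geo_right=np.asarray(z_geo_right, float),
        z_final_left=z_fin_l,
        z_final_right=z_fin_r,
        eta_left=eta_l,
        eta_right=eta_r,
        w_left=w_l,
        w_right=w_r,
        scale=s,
        offset=offset,
    )


def align_prior(z_dl: np.ndarray, s: float, offset: float) -> np.ndarray:
    """Map a scale-ambiguous prior series into meters with a fitted (s, b).

    Used for joints with no ground contact (e.g. shoulders), where the
    ground-plane back-projection is invalid but the aligned prior preserves
    relative depth.
    """
    return s * np.asarray(z_dl, dtype=float) + offset
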