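"""Keypoint stream and cohort-table I/O.

Two time-indexed containers are defined here and used throughout the
pipeline:

* :class:`Keypoints2DSequence` — per-frame pixel keypoints ``(u, v)`` with
  image origin at the top-left corner and ``v`` increasing downward.
* :class:`Keypoints3DSequence` — per-frame camera-centered 3D keypoints
  ``(x, y, z)`` in arbitrary (scale-ambiguous) units, ``z`` increasing away
  from the camera and ``y`` increasing upward.

External joint conventions (e.g. the 17-joint COCO skeleton emitted by
common pose detectors) are mapped onto a fixed canonical ordering of the
eight joints the pipeline consumes; any extra joints are carried through
opaquely after the canonical block.  Two canonical joints are synthesized
when absent: ``head`` from the ``nose`` alias and ``pelvis`` from the hip
midpoint.

Temporal smoothing (zero-phase Butterworth low-pass) and gap interpolation
live here as well, since they are applied at load time before any geometry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import (
    EmptySignalError,
    FormatError,
    PairingError,
    ParameterError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Fixed internal ordering of the joints the pipeline consumes.
CANONICAL_JOINTS: tuple[str, ...] = (
    "head",
    "left_shoulder",
    "right_shoulder",
    "pelvis",
    "left_hip",
    "right_hip",
    "left_ankle",
    "right_ankle",
)

#: External-name -> canonical-name alias table (case-insensitive lookup).
JOINT_ALIASES: dict[str, str] = {
    "nose": "head",
    "head_top": "head",
    "top_head": "head",
    "mid_hip": "pelvis",
    "midhip": "pelvis",
    "hip": "pelvis",
    "root": "pelvis",
    "l_shoulder": "left_shoulder",
    "r_shoulder": "right_shoulder",
    "l_hip": "left_hip",
    "r_hip": "right_hip",
    "l_ankle": "left_ankle",
    "r_ankle": "right_ankle",
}

#: Condition labels accepted in cohort tables.
COHORT_LABELS = ("N", "M", "P")

#: Column order of a cohort CSV (feature block mirrors the state vector).
COHORT_COLUMNS = (
    "subject_id",
    "trial_id",
    "label",
    "T_total",
    "V_walk",
    "T_turn",
    "T_sts",
    "N_total",
    "N_walk",
    "SL_mean",
    "CV",
)


def _canonical_name(name: str) -> str:
    low = name.strip().lower()
    return JOINT_ALIASES.get(low, low)


def _canonicalize(
    joints: Sequence[str], coords: np.ndarray, confidence: np.ndarray | None
) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Reorder joints so the canonical eight come first, synthesizing
    ``head`` (nose alias) and ``pelvis`` (hip midpoint) when absent."""
    names = [_canonical_name(j) for j in joints]
    index = {n: i for i, n in enumerate(names)}

    ncomp = coords.shape[-1]
    frames = coords.shape[0]
    out_names: list[str] = []
    cols: list[np.ndarray] = []
    conf_cols: list[np.ndarray] = []

    for canon in CANONICAL_JOINTS:
        if canon in index:
            i = index[canon]
            cols.append(coords[:, i, :])
            if confidence is not None:
                conf_cols.append(confidence[:, i])
        elif canon == "pelvis" and "left_hip" in index and "right_hip" in index:
            li, ri = index["left_hip"], index["right_hip"]
            cols.append(0.5 * (coords[:, li, :] + coords[:, ri, :]))
            if confidence is not None:
                conf_cols.append(
                    np.minimum(confidence[:, li], confidence[:, ri])
                )
        else:
            raise SchemaError(
                f"canonical joint {canon!r} is neither present nor derivable "
                f"from the provided joints {sorted(names)}"
            )
        out_names.append(canon)

    canonical_set = set(CANONICAL_JOINTS)
    for i, n in enumerate(names):
        if n in canonical_set or n in out_names:
            continue
        out_names.append(n)
        cols.append(coords[:, i, :])
        if confidence is not None:
            conf_cols.append(confidence[:, i])

    new_coords = np.stack(cols, axis=1).reshape(frames, len(out_names), ncomp)
    new_conf = (
        np.stack(conf_cols, axis=1) if confidence is not None else None
    )
    return out_names, new_coords, new_conf


@dataclass
class Keypoints2DSequence:
    """Per-frame 2D pixel keypoints in canonical joint order.

    Coordinates use the image convention: origin top-left, ``v`` increasing
    downward.  Missing detections are NaN.
    """

    fps: float
    width: int
    height: int
    joints: list[str]
    coords: np.ndarray  # (frames, J, 2) float64, (u, v)
    confidence: np.ndarray | None = None  # (frames, J) in [0, 1]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 2:
            raise FormatError(
                f"2D coords must have shape (frames, J, 2), got {self.coords.shape}"
            )
        if self.frames < 1:
            raise FormatError("sequence must contain at least one frame")
        if not self.fps > 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if len(self.joints) != self.coords.shape[1]:
            raise FormatError("joint-name list does not match coords width")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.coords.shape[:2]:
                raise FormatError("confidence shape mismatch")

    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    def joint_index(self, name: str) -> int:
        try:
            return self.joints.index(name)
        except ValueError:
            raise SchemaError(f"joint {name!r} not present") from None

    def joint(self, name: str) -> np.ndarray:
        """(frames, 2) pixel track of one joint."""
        return self.coords[:, self.joint_index(name), :]

    def ankle_midpoint(self) -> np.ndarray:
        """(frames, 2) midpoint of the two ankle pixels."""
        return 0.5 * (self.joint("left_ankle") + self.joint("right_ankle"))


@dataclass
class Keypoints3DSequence:
    """Per-frame camera-centered 3D keypoints, scale-ambiguous units.

    Convention: ``z`` increases away from the camera, ``y`` increases upward.
    """

    fps: float
    joints: list[str]
    coords: np.ndarray  # (frames, J, 3) float64, (x, y, z)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise FormatError(
                f"3D coords must have shape (frames, J, 3), got {self.coords.shape}"
            )
        if self.frames < 1:
            raise FormatError("sequence must contain at least one frame")
        if not self.fps > 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if len(self.joints) != self.coords.shape[1]:
            raise FormatError("joint-name list does not match coords width")

    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    def joint_index(self, name: str) -> int:
        try:
            return self.joints.index(name)
        except ValueError:
            raise SchemaError(f"joint {name!r} not present") from None

    def joint(self, name: str) -> np.ndarray:
        """(frames, 3) track of one joint."""
        return self.coords[:, self.joint_index(name), :]


def check_paired(kp2d: Keypoints2DSequence, kp3d: Keypoints3DSequence) -> None:
    """Validate that a 2D and a 3D stream describe the same session."""
    if kp2d.frames != kp3d.frames:
        raise PairingError(
            f"frame-count mismatch: 2D has {kp2d.frames}, 3D has {kp3d.frames}"
        )
    if kp2d.fps != kp3d.fps:
        raise PairingError(
            f"fps mismatch: 2D at {kp2d.fps}, 3D at {kp3d.fps}"
        )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("json", "csv"):
            raise FormatError(f"unknown dialect {dialect!r}")
        return dialect
    return "csv" if path.suffix.lower() == ".csv" else "json"


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def _nan_to_none(arr: np.ndarray) -> list:
    return [
        [None if not np.isfinite(x) else float(x) for x in row] for row in arr
    ]


def load_keypoints2d(path: str | Path, dialect: str | None = None) -> Keypoints2DSequence:
    """Load a 2D keypoint stream from JSON or CSV and canonicalize joints."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        with open(path) as fh:
            doc = json.load(fh)
        for key in ("fps", "width", "height", "joints", "frames"):
            if key not in doc:
                raise FormatError(f"{path}: missing required field {key!r}")
        joints = list(doc["joints"])
        raw = []
        conf = []
        has_conf = False
        for fr in doc["frames"]:
            kp = np.asarray(
                [[np.nan if c is None else c for c in row] for row in fr["kp2d"]],
                dtype=float,
            )
            if kp.shape[1] == 3:
                has_conf = True
                conf.append(kp[:, 2])
                kp = kp[:, :2]
            raw.append(kp)
        coords = np.stack(raw, axis=0)
        confidence = np.stack(conf, axis=0) if has_conf else None
    else:
        meta_path = _sidecar(path)
        if not meta_path.exists():
            raise FormatError(f"CSV dialect requires sidecar metadata {meta_path}")
        with open(meta_path) as fh:
            meta = json.load(fh)
        for key in ("fps", "width", "height", "joints"):
            if key not in meta:
                raise FormatError(f"{meta_path}: missing required field {key!r}")
        df = pd.read_csv(path, float_precision="round_trip")
        joints = list(meta["joints"])
        coords = np.stack(
            [df[[f"{j}_u", f"{j}_v"]].to_numpy(dtype=float) for j in joints],
            axis=1,
        )
        confidence = None
        doc = meta
    names, coords, confidence = _canonicalize(joints, coords, confidence)
    return Keypoints2DSequence(
        fps=float(doc["fps"]),
        width=int(doc["width"]),
        height=int(doc["height"]),
        joints=names,
        coords=coords,
        confidence=confidence,
    )


def save_keypoints2d(seq: Keypoints2DSequence, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        frames = []
        for t in range(seq.frames):
            if seq.confidence is not None:
                kp = [
                    [*pt, c]
                    for pt, c in zip(
                        _nan_to_none(seq.coords[t]), seq.confidence[t].tolist()
                    )
                ]
            else:
                kp = _nan_to_none(seq.coords[t])
            frames.append({"kp2d": kp})
        doc = {
            "fps": seq.fps,
            "width": seq.width,
            "height": seq.height,
            "joints": seq.joints,
            "frames": frames,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        cols = {}
        for i, j in enumerate(seq.joints):
            cols[f"{j}_u"] = seq.coords[:, i, 0]
            cols[f"{j}_v"] = seq.coords[:, i, 1]
        pd.DataFrame(cols).to_csv(path, index=False)
        with open(_sidecar(path), "w") as fh:
            json.dump(
                {
                    "fps": seq.fps,
                    "width": seq.width,
                    "height": seq.height,
                    "joints": seq.joints,
                },
                fh,
            )


def load_keypoints3d(path: str | Path, dialect: str | None = None) -> Keypoints3DSequence:
    """Load a scale-ambiguous 3D keypoint stream (JSON or CSV)."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        with open(path) as fh:
            doc = json.load(fh)
        for key in ("fps", "joints", "frames"):
            if key not in doc:
                raise FormatError(f"{path}: missing required field {key!r}")
        joints = list(doc["joints"])
        coords = np.stack(
            [
                np.asarray(
                    [
                        [np.nan if c is None else c for c in row]
                        for row in fr["kp3d"]
                    ],
                    dtype=float,
                )
                for fr in doc["frames"]
            ],
            axis=0,
        )
    else:
        meta_path = _sidecar(path)
        if not meta_path.exists():
            raise FormatError(f"CSV dialect requires sidecar metadata {meta_path}")
        with open(meta_path) as fh:
            meta = json.load(fh)
        if "fps" not in meta or "joints" not in meta:
            raise FormatError(f"{meta_path}: missing fps or joints")
        df = pd.read_csv(path, float_precision="round_trip")
        joints = list(meta["joints"])
        coords = np.stack(
            [
                df[[f"{j}_x", f"{j}_y", f"{j}_z"]].to_numpy(dtype=float)
                for j in joints
            ],
            axis=1,
        )
        doc = meta
    names, coords, _ = _canonicalize(joints, coords, None)
    return Keypoints3DSequence(fps=float(doc["fps"]), joints=names, coords=coords)


def save_keypoints3d(seq: Keypoints3DSequence, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        doc = {
            "fps": seq.fps,
            "joints": seq.joints,
            "frames": [
                {"kp3d": _nan_to_none(seq.coords[t])} for t in range(seq.frames)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        cols = {}
        for i, j in enumerate(seq.joints):
            for k, ax in enumerate("xyz"):
                cols[f"{j}_{ax}"] = seq.coords[:, i, k]
        pd.DataFrame(cols).to_csv(path, index=False)
        with open(_sidecar(path), "w") as fh:
            json.dump({"fps": seq.fps, "joints": seq.joints}, fh)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def load_cohort(path: str | Path) -> pd.DataFrame:
    """Load a labeled cohort feature table (one row per trial)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    bad = set(df["label"].unique()) - set(COHORT_LABELS)
    if bad:
        raise FormatError(f"cohort labels must be in {COHORT_LABELS}, got {sorted(bad)}")
    if df.duplicated(subset=["subject_id", "trial_id"]).any():
        raise FormatError("duplicate (subject_id, trial_id) rows in cohort table")
    return df[list(COHORT_COLUMNS)].copy()


def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df[list(COHORT_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# temporal smoothing and gap handling
# ---------------------------------------------------------------------------

def lowpass_smooth(
    series: np.ndarray, fps: float, cutoff_hz: float = 6.0, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Applied along axis 0.  The default 6 Hz cutoff at 30 fps preserves gait
    harmonics (below ~5 Hz) while attenuating keypoint-detector jitter.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < cutoff_hz < fps / 2:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist={fps / 2} Hz), got {cutoff_hz}"
        )
    if series.shape[0] <= 3 * order:
        raise ParameterError(
            f"series of length {series.shape[0]} too short for order {order}"
        )
    if not np.all(np.isfinite(series)):
        raise ParameterError("series contains NaN; interpolate gaps first")
    sos = _signal.butter(order, cutoff_hz, btype="low", fs=fps, output="sos")
    return _signal.sosfiltfilt(sos, series, axis=0)


def smooth_with_gaps(
    series: np.ndarray, fps: float, cutoff_hz: float = 6.0, order: int = 4
) -> np.ndarray:
    """Low-pass a 1-D series that may contain NaN runs.

    Each contiguous finite run long enough for the filter is smoothed
    independently; short runs and NaNs pass through unchanged.
    """
    series = np.asarray(series, dtype=float)
    out = series.copy()
    finite = np.isfinite(series)
    if not finite.any():
        return out
    # contiguous finite runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], finite.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start > 3 * order:
            out[start:stop] = lowpass_smooth(
                series[start:stop], fps, cutoff_hz, order
            )
    return out


def find_gaps(series: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of NaN runs."""
    isnan = ~np.isfinite(np.asarray(series, dtype=float))
    edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    return [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]


def interpolate_gaps(series: np.ndarray, max_gap_frames: int) -> np.ndarray:
    """Fill NaN runs of length <= ``max_gap_frames`` by linear interpolation.

    Interior gaps are bridged linearly; gaps touching an end are held at the
    nearest finite value.  Longer gaps are left as NaN and reported via a
    warning so downstream stages can treat them as missing data.
    """
    series = np.asarray(series, dtype=float)
    if not np.isfinite(series).any():
        raise EmptySignalError("series is entirely NaN")
    out = series.copy()
    n = out.shape[0]
    long_gaps = []
    for start, stop in find_gaps(series):
        if stop - start > max_gap_frames:
            long_gaps.append((start, stop))
            continue
        left = start - 1
        right = stop
        if left < 0 and right >= n:
            continue
        if left < 0:
            out[start:stop] = out[right]
        elif right >= n:
            out[start:stop] = out[left]
        else:
            out[start:stop] = np.interp(
                np.arange(start, stop), [left, right], [out[left], out[right]]
            )
    if long_gaps:
        logger.warning(
            "left %d gap(s) longer than %d frames unfilled: %s",
            len(long_gaps),
            max_gap_frames,
            long_gaps,
        )
    return out


def preprocess_sequence(
    seq: Keypoints2DSequence | Keypoints3DSequence,
    max_gap_frames: int = 10,
    cutoff_hz: float = 6.0,
    order: int = 4,
):
    """Gap-fill then low-pass every joint coordinate track of a sequence.

    Returns a new sequence of the same type; long gaps remain NaN.
    """
    coords = seq.coords.copy()
    for j in range(coords.shape[1]):
        for c in range(coords.shape[2]):
            track = coords[:, j, c]
            if not np.isfinite(track).any():
                continue
            track = interpolate_gaps(track, max_gap_frames)
            coords[:, j, c] = smooth_with_gaps(track, seq.fps, cutoff_hz, order)
    kwargs = {k: getattr(seq, k) for k in ("fps", "joints")}
    if isinstance(seq, Keypoints2DSequence):
        return Keypoints2DSequence(
            width=seq.width,
            height=seq.height,
            coords=coords,
            confidence=seq.confidence,
            **kwargs,
        )
    return Keypoints3DSequence(coords=coords, **kwargs)
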