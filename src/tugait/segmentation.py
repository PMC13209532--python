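"""TUG phase segmentation by vertical displacement and torso rotation.

A TUG session decomposes into Sit, Sit-to-Stand, Walk-1, Turn-1, Walk-2,
Turn-2, Stand-to-Sit, Sit.  Two signals drive the state machine:

* ``h_foot(t)`` — vertical distance between the ankle midpoint and the
  pelvis (root) from the 3D pose stream.  It is scale-free: the subject-
  specific thresholds ``T_high`` / ``T_low`` are fractions of its observed
  range, so the arbitrary pose-stream scale cancels.  The Sit-to-Stand
  phase ends when ``h_foot >= T_high``; Stand-to-Sit begins when
  ``h_foot <= T_low``.
* ``dZ_shoulder(t)`` — absolute depth difference between the shoulders in
  meters (from the scale-aligned pose prior).  Near zero while the torso
  faces the camera, it rises to the full shoulder breadth at the 90-degree
  instant of a turn, so each 180-degree turn appears as a prominent peak.

Intervals are half-open ``[start, end)`` with 0-based frames and tile the
analyzed span.  Canonical phase names are ``Walk1``/``Walk2``; the
camera-relative aliases ``Walk_Away``/``Walk_Back`` are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .errors import ParameterError, SchemaError, SegmentationError, StateMachineError
from .io import Keypoints3DSequence, lowpass_smooth

PHASE_ORDER = (
    "Sit1",
    "SitToStand",
    "Walk1",
    "Turn1",
    "Walk2",
    "Turn2",
    "StandToSit",
    "Sit2",
)

#: Camera-relative labels used in some reports, mapped to canonical names.
PHASE_ALIASES = {"Walk_Away": "Walk1", "Walk_Back": "Walk2"}


@dataclass
class SegmentationConfig:
    high_frac: float = 0.8  # T_high = min + high_frac * range
    low_frac: float = 0.3  # T_low = min + low_frac * range
    turn_min_prominence: float = 0.15  # m, about a shoulder half-width
    turn_min_duration_s: float = 0.3
    min_phase_duration_s: float = 0.1
    min_range_frac: float = 0.05  # h_foot range must exceed this x its max
    range_percentile: float = 5.0  # robust range: [p, 100-p] percentiles
    settle_tol_frac: float = 0.15  # Stand-to-Sit end: mean deviation from final value
    settle_duration_s: float = 0.5  # ... sustained this long

    def __post_init__(self) -> None:
        if not 0 < self.low_frac < self.high_frac < 1:
            raise ParameterError("need 0 < low_frac < high_frac < 1")


@dataclass
class TorsoSignals:
    """The two segmentation drivers, aligned in time."""

    h_foot: np.ndarray  # pose-stream units
    dz_shoulder: np.ndarray  # meters

    def __post_init__(self) -> None:
        if len(self.h_foot) != len(self.dz_shoulder):
            raise ParameterError("torso signals must share length")
        if np.nanmin(self.dz_shoulder) < -1e-9:
            raise ParameterError("dz_shoulder must be non-negative")


@dataclass
class PhaseSegmentation:
    """Ordered, non-overlapping, contiguous labeled intervals."""

    fps: float
    intervals: dict  # name -> (start_frame, end_frame), half-open

    def __post_init__(self) -> None:
        prev_end = None
        for name in PHASE_ORDER:
            if name not in self.intervals:
                raise StateMachineError(f"missing phase {name}")
            s, e = self.intervals[name]
            if e < s:
                raise StateMachineError(f"phase {name} has end < start")
            if prev_end is not None and s != prev_end:
                raise StateMachineError(
                    f"phase {name} starts at {s}, expected {prev_end} (gap/overlap)"
                )
            prev_end = e

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.intervals[PHASE_ALIASES.get(name, name)]

    def duration_s(self, name: str) -> float:
        s, e = self[name]
        return (e - s) / self.fps

    def walking_mask(self, n_frames: int) -> np.ndarray:
        """Boolean mask of frames inside Walk1 or Walk2."""
        mask = np.zeros(n_frames, dtype=bool)
        for name in ("Walk1", "Walk2"):
            s, e = self[name]
            mask[s:e] = True
        return mask

    def to_records(self) -> list[dict]:
        return [
            {
                "phase": name,
                "start_frame": int(self.intervals[name][0]),
                "end_frame": int(self.intervals[name][1]),
                "duration_s": self.duration_s(name),
            }
            for name in PHASE_ORDER
        ]


def vertical_signal(kp3d: Keypoints3DSequence, smooth: bool = True) -> np.ndarray:
    """``h_foot(t)``: |y_pelvis - mean(y_ankles)| from the 3D pose stream."""
    for j in ("pelvis", "left_ankle", "right_ankle"):
        if j not in kp3d.joints:
            raise SchemaError(f"vertical signal requires joint {j!r}")
    y_pelvis = kp3d.joint("pelvis")[:, 1]
    y_ankle = 0.5 * (kp3d.joint("left_ankle")[:, 1] + kp3d.joint("right_ankle")[:, 1])
    h = np.abs(y_pelvis - y_ankle)
    if smooth and len(h) > 12:
        h = lowpass_smooth(h, kp3d.fps)
    return h


def shoulder_depth_signal(
    kp3d: Keypoints3DSequence, scale: float = 1.0, smooth: bool = True
) -> np.ndarray:
    """``dZ_shoulder(t)`` in meters, given the prior's fitted scale factor."""
    for j in ("left_shoulder", "right_shoulder"):
        if j not in kp3d.joints:
            raise SchemaError(f"shoulder signal requires joint {j!r}")
    dz = np.abs(kp3d.joint("left_shoulder")[:, 2] - kp3d.joint("right_shoulder")[:, 2])
    dz = dz * scale
    if smooth and len(dz) > 12:
        dz = np.abs(lowpass_smooth(dz, kp3d.fps))
    return dz


def sts_thresholds(
    h_foot: np.ndarray, config: SegmentationConfig | None = None
) -> tuple[float, float]:
    """Subject-specific postural thresholds from the static range of motion.

    The range uses robust percentile extremes: the seated and standing
    plateaus each occupy well over ``range_percentile`` percent of a TUG
    recording, so clean signals are unaffected while noise excursions
    cannot inflate the thresholds.
    """
    config = config or SegmentationConfig()
    h = np.asarray(h_foot, dtype=float)
    p = config.range_percentile
    lo, hi = (float(v) for v in np.nanpercentile(h, [p, 100.0 - p]))
    rng = hi - lo
    if rng <= config.min_range_frac * max(abs(hi), 1e-12):
        raise SegmentationError(
            f"h_foot range {rng:.4g} shows no postural change; cannot derive thresholds"
        )
    t_high = lo + config.high_frac * rng
    t_low = lo + config.low_frac * rng
    return t_high, t_low


def detect_turns(
    dz_shoulder: np.ndarray,
    config: SegmentationConfig | None = None,
    fps: float = 30.0,
) -> list[tuple[int, int]]:
    """Locate the two 180-degree turns as the two most prominent peaks.

    Each turn interval is the contiguous region above half-prominence around
    its peak.  Raises if fewer than two qualifying peaks exist.
    """
    config = config or SegmentationConfig()
    dz = np.asarray(dz_shoulder, dtype=float)
    min_dist = max(1, int(round(config.turn_min_duration_s * fps)))
    peaks, props = find_peaks(
        dz, prominence=config.turn_min_prominence, distance=min_dist
    )
    if len(peaks) < 2:
        raise SegmentationError(
            f"found {len(peaks)} turn peak(s) with prominence >= "
            f"{config.turn_min_prominence} m (at frames {peaks.tolist()}); need 2"
        )
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    top2 = np.sort(top2)
    widths, _, lips, rips = peak_widths(dz, top2, rel_height=0.5)
    intervals = []
    for width, lip, rip in zip(widths, lips, rips):
        if width / fps < config.turn_min_duration_s:
            raise SegmentationError(
                f"turn of {width / fps:.2f} s shorter than "
                f"{config.turn_min_duration_s} s"
            )
        intervals.append((int(np.floor(lip)), int(np.ceil(rip)) + 1))
    return intervals


def _first_sustained(
    h: np.ndarray, start: int, target: float, tol: float, run: int
) -> int | None:
    """First index from which the forward window of ``run`` frames deviates
    from ``target`` by at most ``tol`` on average (robust to single-frame
    noise excursions)."""
    dev = np.abs(h - target)
    for i in range(start, len(h)):
        window = dev[i : i + run]
        if float(np.mean(window)) <= tol:
            return i
    return None


def segment_phases(
    h_foot: np.ndarray,
    dz_shoulder: np.ndarray,
    config: SegmentationConfig | None = None,
    fps: float = 30.0,
) -> PhaseSegmentation:
    """Run the full vertical-displacement / torso-rotation state machine."""
    config = config or SegmentationConfig()
    h = np.asarray(h_foot, dtype=float)
    dz = np.asarray(dz_shoulder, dtype=float)
    if len(h) != len(dz):
        raise ParameterError("h_foot and dz_shoulder must share length")
    n = len(h)
    t_high, t_low = sts_thresholds(h, config)

    above = np.flatnonzero(h >= t_high)
    if len(above) == 0:
        raise StateMachineError("subject never reaches a standing posture")
    sts_end = int(above[0])
    below_before = np.flatnonzero(h[:sts_end] <= t_low)
    if len(below_before) == 0:
        raise StateMachineError("no seated posture precedes the first stand")
    sts_start = int(below_before[-1])

    (t1s, t1e), (t2s, t2e) = detect_turns(dz, config, fps)
    if t1s < sts_end:
        raise StateMachineError(
            f"first turn (frame {t1s}) precedes the sit-to-stand end ({sts_end})"
        )
    if t2s < t1e:
        raise StateMachineError("second turn overlaps the first")

    below_after = np.flatnonzero(h[t2s:] <= t_low)
    if len(below_after) == 0:
        raise StateMachineError("subject never sits back down after the final turn")
    crossing = t2s + int(below_after[0])
    # turn-and-sit: the descent may begin during the turn; the two phases
    # share a boundary but never overlap.
    stsit_start = max(crossing, t2e)
    turn2_end = stsit_start

    run = max(1, int(round(config.settle_duration_s * fps)))
    final_value = float(np.median(h[max(0, n - run):]))
    rng = float(np.nanmax(h) - np.nanmin(h))
    settle = _first_sustained(
        h, stsit_start, final_value, config.settle_tol_frac * rng, run
    )
    stsit_end = int(settle) if settle is not None else n
    stsit_end = max(stsit_end, stsit_start + 1)
    stsit_end = min(stsit_end, n)

    intervals = {
        "Sit1": (0, sts_start),
        "SitToStand": (sts_start, sts_end),
        "Walk1": (sts_end, t1s),
        "Turn1": (t1s, t1e),
        "Walk2": (t1e, t2s),
        "Turn2": (t2s, turn2_end),
        "StandToSit": (stsit_start, stsit_end),
        "Sit2": (stsit_end, n),
    }
    # StandToSit is exempt: its detected extent (T_low crossing to settle)
    # is definitionally brief and may legitimately collapse to a few frames.
    min_frames = int(round(config.min_phase_duration_s * fps))
    for name in ("SitToStand", "Walk1", "Turn1", "Walk2", "Turn2"):
        s, e = intervals[name]
        if e - s < min_frames:
            raise StateMachineError(
                f"phase {name} lasts {e - s} frames, below the "
                f"{min_frames}-frame minimum"
            )
    return PhaseSegmentation(fps=fps, intervals=intervals)


def segment_session(
    kp3d: Keypoints3DSequence,
    scale: float,
    config: SegmentationConfig | None = None,
) -> tuple[PhaseSegmentation, TorsoSignals]:
    """Convenience wrapper: signals from a 3D stream, then the state machine."""
    h = vertical_signal(kp3d)
    dz = shoulder_depth_signal(kp3d, scale)
    seg = segment_phases(h, dz, config, kp3d.fps)
    return seg, TorsoSignals(h_foot=h, dz_shoulder=dz)
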