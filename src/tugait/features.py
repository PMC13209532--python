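"""Step-event detection and the eight-component gait state vector.

The fused foot depth-difference signal ``D(t) = Z_left(t) - Z_right(t)``
oscillates quasi-sinusoidally during steady walking: each prominent peak or
valley marks a step event, and ``|D|`` at the event frame is a stride-length
*proxy* — the depth separation of the feet, standing in for anatomical
stride length.  Events are detected over the whole session (``S_all``) and
then restricted to the walking phases (``S_walk``), so turn shuffles and
pre-seat adjustments never contaminate the stride statistics.

The session is summarized by the state vector

    x = [T_total, V_walk, T_turn, T_sts, N_total, N_walk, SL_mean, CV]

where CV is the coefficient of variation (percent) of the walking stride
proxies — a gait-automaticity/variability biomarker — and the walking speed
is the accumulated stride distance divided by the *full* TUG duration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    EmptySignalError,
    PairingError,
    SegmentationError,
    UndefinedStatisticError,
)
from .segmentation import PhaseSegmentation

#: Clinical report rows: (attribute, display label, symbol, unit).
REPORT_ROWS = (
    ("T_total", "Total Time", "Ttotal", "s"),
    ("N_total", "Step Count (Total)", "Ntotal", "1"),
    ("N_walk", "Step Count (Walk)", "Nwalk", "1"),
    ("SL_mean", "Avg Stride", "SL_mean", "m"),
    ("CV", "Stride CV", "CV", "%"),
    ("T_turn", "Turn Duration", "Tturn", "s"),
    ("T_sts", "Sit-Stand Duration", "Tsts", "s"),
)


@dataclass
class StepEvents:
    """Detected step candidates on the foot depth-difference signal."""

    d_signal: np.ndarray  # D(t), meters
    all_events: np.ndarray  # frame indices, strictly increasing
    walk_events: np.ndarray  # subset inside Walk1/Walk2

    def __post_init__(self) -> None:
        self.all_events = np.asarray(self.all_events, dtype=int)
        self.walk_events = np.asarray(self.walk_events, dtype=int)
        if not np.all(np.diff(self.all_events) > 0):
            raise SegmentationError("step events must be strictly increasing")
        if not np.isin(self.walk_events, self.all_events).all():
            raise SegmentationError("walk events must be a subset of all events")

    @property
    def n_total(self) -> int:
        return len(self.all_events)

    @property
    def n_walk(self) -> int:
        return len(self.walk_events)

    def stride_proxies(self, walking_only: bool = True) -> np.ndarray:
        """|D| at the event frames (meters)."""
        idx = self.walk_events if walking_only else self.all_events
        return np.abs(self.d_signal[idx])

    def to_frame(self, fps: float) -> pd.DataFrame:
        """Per-step table (time, stride proxy, valid-walk flag)."""
        walk = np.isin(self.all_events, self.walk_events)
        return pd.DataFrame(
            {
                "frame": self.all_events,
                "t_s": self.all_events / fps,
                "stride_m": np.abs(self.d_signal[self.all_events]),
                "valid_walk": walk,
            }
        )


@dataclass
class GaitStateVector:
    """Eight spatiotemporal descriptors of one TUG session."""

    T_total: float  # s
    V_walk: float  # m/s
    T_turn: float  # s
    T_sts: float  # s
    N_total: int
    N_walk: int
    SL_mean: float  # m
    CV: float  # percent

    FEATURES = ("T_total", "V_walk", "T_turn", "T_sts", "N_total", "N_walk", "SL_mean", "CV")

    def __post_init__(self) -> None:
        if self.N_walk > self.N_total:
            raise SegmentationError("N_walk cannot exceed N_total")
        for name in self.FEATURES:
            if getattr(self, name) < 0:
                raise SegmentationError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FEATURES], dtype=float)

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.FEATURES}
        d["N_total"] = int(d["N_total"])
        d["N_walk"] = int(d["N_walk"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaitStateVector":
        return cls(**{f: d[f] for f in cls.FEATURES})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GaitStateVector":
        return cls.from_dict(json.loads(s))

    def to_table(self) -> pd.DataFrame:
        """Clinical report table with standard labels and units."""
        return pd.DataFrame(
            [
                {
                    "Parameter": label,
                    "Label": symbol,
                    "Unit": unit,
                    "Value": getattr(self, attr),
                }
                for attr, label, symbol, unit in REPORT_ROWS
            ]
        )


def foot_depth_difference(z_final_left: np.ndarray, z_final_right: np.ndarray) -> np.ndarray:
    """D(t) = Z_left(t) - Z_right(t), element-wise, meters."""
    zl = np.asarray(z_final_left, dtype=float)
    zr = np.asarray(z_final_right, dtype=float)
    if zl.shape != zr.shape:
        raise PairingError(f"foot tracks differ in shape: {zl.shape} vs {zr.shape}")
    return zl - zr


def extrema_events(
    d: np.ndarray, prominence: float, distance: int, min_abs: float | None = None
) -> np.ndarray:
    """Prominent peaks and valleys of a signal with a shared refractory gap.

    Peaks of ``d`` and of ``-d`` are pooled and thinned by non-maximum
    suppression: of two extrema closer than ``distance`` frames only the
    more prominent survives — successive heel events cannot physically occur
    faster than the cadence bound.  ``min_abs`` additionally rejects extrema
    where |d| is small: the signal's magnitude at a step event is the foot
    separation, and a near-zero separation marks a stance crossing or a
    transitional shuffle, not a step.
    """
    if prominence <= 0:
        return np.array([], dtype=int)
    peaks, pprops = find_peaks(d, prominence=prominence, distance=distance)
    valleys, vprops = find_peaks(-d, prominence=prominence, distance=distance)
    cand = np.concatenate([peaks, valleys])
    proms = np.concatenate([pprops["prominences"], vprops["prominences"]])
    if min_abs is not None:
        big = np.abs(d[cand]) >= min_abs
        cand, proms = cand[big], proms[big]
    keep: list[int] = []
    for j in np.argsort(-proms):  # most prominent first
        t = int(cand[j])
        if all(abs(t - k) >= distance for k in keep):
            keep.append(t)
    return np.unique(np.asarray(keep, dtype=int))


def detect_steps(
    d_signal: np.ndarray,
    phases: PhaseSegmentation,
    fps: float,
    min_step_interval_s: float = 0.36,
    prominence_frac: float = 0.5,
) -> StepEvents:
    """Detect step events as prominent peaks AND valleys of D(t).

    Candidate events need a prominence of at least ``prominence_frac`` times
    the standard deviation of D over the walking phases (the gait amplitude
    scale — noise floors outside the walks must not dilute it) and a minimum
    temporal separation.  The separation is enforced across polarities by
    non-maximum suppression: of two events closer than the interval, only
    the more prominent survives — successive heel events cannot physically
    occur faster than the cadence bound.  Valid walking steps are the
    candidates inside Walk1 or Walk2.
    """
    d = np.asarray(d_signal, dtype=float)
    if d.size == 0 or not np.isfinite(d).any():
        raise EmptySignalError("empty foot depth-difference signal")
    walk = phases.walking_mask(len(d))
    ref = d[walk & np.isfinite(d)]
    if ref.size < 2:
        ref = d[np.isfinite(d)]
    prominence = prominence_frac * float(np.std(ref))
    distance = max(1, int(round(min_step_interval_s * fps)))
    all_events = extrema_events(d, prominence, distance, min_abs=prominence)
    mask = phases.walking_mask(len(d))
    walk_events = all_events[mask[all_events]] if len(all_events) else all_events
    return StepEvents(d_signal=d, all_events=all_events, walk_events=walk_events)


def stride_stats(
    step_events: StepEvents, ddof: int = 0
) -> tuple[float, float]:
    """Mean stride proxy (m) and its coefficient of variation (percent).

    The CV uses the population standard deviation by default (``ddof=0``).
    """
    sl = step_events.stride_proxies(walking_only=True)
    if len(sl) == 0:
        raise UndefinedStatisticError("no valid walking steps; SL_mean undefined")
    sl_mean = float(np.mean(sl))
    if len(sl) < 2:
        raise UndefinedStatisticError("CV requires at least two walking steps")
    if sl_mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean stride")
    cv = 100.0 * float(np.std(sl, ddof=ddof)) / sl_mean
    return sl_mean, cv


def temporal_params(phases: PhaseSegmentation, fps: float) -> tuple[float, float, float]:
    """(T_total, T_turn, T_sts) in seconds from the segmented boundaries."""
    try:
        sts_start = phases["SitToStand"][0]
        stsit_end = phases["StandToSit"][1]
        t_turn = phases.duration_s("Turn1")
        t_sts = phases.duration_s("SitToStand")
    except KeyError as exc:
        raise SegmentationError(f"missing phase for temporal parameters: {exc}")
    t_total = (stsit_end - sts_start) / fps
    return t_total, t_turn, t_sts


def walking_speed(sl_mean: float, n_walk: int, t_total: float) -> float:
    """Accumulated walking distance over the full TUG duration (m/s)."""
    if t_total <= 0:
        raise UndefinedStatisticError("T_total must be positive for walking speed")
    return sl_mean * n_walk / t_total


def build_state_vector(
    step_events: StepEvents, phases: PhaseSegmentation, fps: float, ddof: int = 0
) -> GaitStateVector:
    """Assemble the eight-component state vector for one session."""
    sl_mean, cv = stride_stats(step_events, ddof=ddof)
    t_total, t_turn, t_sts = temporal_params(phases, fps)
    v_walk = walking_speed(sl_mean, step_events.n_walk, t_total)
    return GaitStateVector(
        T_total=t_total,
        V_walk=v_walk,
        T_turn=t_turn,
        T_sts=t_sts,
        N_total=step_events.n_total,
        N_walk=step_events.n_walk,
        SL_mean=sl_mean,
        CV=cv,
    )
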