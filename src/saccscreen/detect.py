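"""Velocity-threshold saccade detection on 1000-Hz gaze traces.

Detection follows the classical scheme: differentiate each axis with central
differences, smooth the resulting speed with a short centered moving average,
and mark saccades as maximal runs where the smoothed speed exceeds 30 deg/s
(onset = first sample above threshold, offset = first return below).  Runs
separated by very short gaps are merged, and sub-duration or sub-amplitude
runs are discarded as jitter.  The differentiation/smoothing scheme and the
noise-rejection margins are conventional choices for 1000-Hz recordings and
are exposed as parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from saccscreen.paradigm import TrialStimulus, target_position
from saccscreen.simulate import GazeTrace

DEFAULT_THRESHOLD_DEG_S = 30.0
DEFAULT_SMOOTH_WINDOW_MS = 5
DEFAULT_MIN_DURATION_MS = 10.0
DEFAULT_MERGE_GAP_MS = 20.0
DEFAULT_MIN_AMPLITUDE_DEG = 0.3

PRIMARY_WINDOW_MS = (80.0, 600.0)
PRIMARY_MIN_AMPLITUDE_DEG = 1.0
PRIMARY_MAX_DIRECTION_ERR_DEG = 90.0


@dataclass(frozen=True)
class VelocityTrace:
    """Smoothed 2-D speed magnitude aligned to its parent trace."""

    t_ms: np.ndarray
    speed_deg_s: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t_ms) != len(self.speed_deg_s):
            raise ValueError("velocity trace arrays must have equal length")


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected saccade with trace-derived kinematics."""

    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    start_xy_deg: tuple
    end_xy_deg: tuple
    direction_deg: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def compute_velocity(trace: GazeTrace, smooth_window_ms: int = DEFAULT_SMOOTH_WINDOW_MS) -> VelocityTrace:
    """Central-difference speed with centered moving-average smoothing.

    Boundary samples use one-sided differences.  ``smooth_window_ms`` must be
    odd; a window of 1 disables smoothing.
    """
    n = len(trace.t_ms)
    if n < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if smooth_window_ms < 1 or smooth_window_ms % 2 == 0:
        raise ValueError("smoothing window must be a positive odd number of samples")
    dt_s = 1.0 / trace.sampling_rate_hz
    vx = np.gradient(trace.x_deg, dt_s)  # central differences, one-sided at ends
    vy = np.gradient(trace.y_deg, dt_s)
    speed = np.hypot(vx, vy)
    if smooth_window_ms > 1:
        kernel = np.full(smooth_window_ms, 1.0 / smooth_window_ms)
        pad = smooth_window_ms // 2
        padded = np.pad(speed, pad, mode="edge")
        speed = np.convolve(padded, kernel, mode="valid")
    return VelocityTrace(t_ms=trace.t_ms, speed_deg_s=speed)


def _above_threshold_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as [start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.r_[False, above, False].astype(np.int8)))
    return list(zip(idx[::2], idx[1::2]))


def detect_saccades(
    vel: VelocityTrace,
    trace: GazeTrace,
    threshold_deg_s: float = DEFAULT_THRESHOLD_DEG_S,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
    min_amplitude_deg: float = DEFAULT_MIN_AMPLITUDE_DEG,
) -> list[SaccadeEvent]:
    """Threshold the smoothed speed and return cleaned saccade events.

    Runs separated by less than ``merge_gap_ms`` are merged; events shorter
    than ``min_duration_ms`` or smaller than ``min_amplitude_deg`` are
    discarded.  Events are ordered by onset and never overlap.
    """
    if len(vel.t_ms) != len(trace.t_ms) or not np.array_equal(vel.t_ms, trace.t_ms):
        raise ValueError("velocity trace is not aligned with the gaze trace")
    runs = _above_threshold_runs(vel.speed_deg_s > threshold_deg_s)
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and (vel.t_ms[start] - vel.t_ms[merged[-1][1] - 1]) < merge_gap_ms:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    events = []
    for start, stop in merged:
        # onset: first sample above threshold; offset: first sample back below
        last = min(stop, len(trace.t_ms) - 1)
        onset, offset = float(vel.t_ms[start]), float(vel.t_ms[last])
        if offset - onset < min_duration_ms:
            continue
        # start position read one sample before onset (last quiescent sample)
        # so the sub-threshold takeoff displacement is not lost
        pre = max(start - 1, 0)
        sx, sy = float(trace.x_deg[pre]), float(trace.y_deg[pre])
        ex, ey = float(trace.x_deg[last]), float(trace.y_deg[last])
        amplitude = math.hypot(ex - sx, ey - sy)
        if amplitude < min_amplitude_deg:
            continue
        events.append(
            SaccadeEvent(
                onset_ms=onset,
                offset_ms=offset,
                amplitude_deg=amplitude,
                peak_velocity_deg_s=float(np.max(vel.speed_deg_s[start:stop])),
                start_xy_deg=(sx, sy),
                end_xy_deg=(ex, ey),
                direction_deg=math.degrees(math.atan2(ey - sy, ex - sx)),
            )
        )
    return events


def _angle_diff_deg(a: float, b: float) -> float:
    """Absolute angular difference in [0, 180]."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def primary_saccade(
    events: list[SaccadeEvent],
    stim: TrialStimulus,
    reference_ms: float,
) -> SaccadeEvent | None:
    """Select the trial's primary target-directed saccade, if any.

    The primary saccade is the first event with onset within
    [reference + 80 ms, reference + 600 ms], amplitude >= 1 deg, and direction
    within +/-90 deg of the instantaneous target direction at its onset.
    Returns ``None`` when no event qualifies (trial marked invalid).
    """
    lo = reference_ms + PRIMARY_WINDOW_MS[0]
    hi = reference_ms + PRIMARY_WINDOW_MS[1]
    for ev in events:
        if not lo <= ev.onset_ms <= hi:
            continue
        if ev.amplitude_deg < PRIMARY_MIN_AMPLITUDE_DEG:
            continue
        tx, ty = target_position(stim, max(ev.onset_ms, stim.target_onset_ms))
        target_dir = math.degrees(math.atan2(ty - ev.start_xy_deg[1], tx - ev.start_xy_deg[0]))
        if _angle_diff_deg(ev.direction_deg, target_dir) <= PRIMARY_MAX_DIRECTION_ERR_DEG:
            return ev
    return None
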