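"""Trial schedules and target kinematics for the two oculomotor tasks.

Two paradigms are modelled:

* **static** -- after a 1000-1500 ms central fixation, a target appears at one
  of eight polar angles (0deg, 45deg, ..., 315deg) at 10deg eccentricity and stays for
  1000 ms.  A session holds 64 trials, 8 per location, pseudo-randomized so
  that no two consecutive trials share a location.
* **moving** -- after fixation, a target appears at 15deg eccentricity on one of
  three motion axes and moves centripetally at 5, 10 or 15 deg/s, continuing
  through the centre to the opposite side.  The fixation cross disappears
  200 ms after motion onset.  A session holds 72 trials, 8 per speed x axis
  cell, in fully randomized order.

All times are on a per-trial clock with t = 0 at fixation onset; the target
appears at ``target_onset_ms`` (= the fixation duration).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np

STATIC_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
STATIC_ECCENTRICITY_DEG = 10.0
STATIC_TRIALS_PER_ANGLE = 8
STATIC_TARGET_VISIBLE_MS = 1000.0

MOVING_AXES_DEG = (0.0, 120.0, 240.0)  # unnamed in the protocol; symmetric choice
MOVING_ECCENTRICITY_DEG = 15.0
MOVING_SPEEDS_DEG_S = (5.0, 10.0, 15.0)
MOVING_TRIALS_PER_CELL = 8
MOVING_TRACE_AFTER_ONSET_MS = 3000.0
GAP_AFTER_MOTION_ONSET_MS = 200.0  # fixation cross offset relative to motion onset

FIXATION_RANGE_MS = (1000.0, 1500.0)
SAMPLING_RATE_HZ = 1000.0

Task = Literal["static", "moving"]


@dataclass(frozen=True)
class TrialStimulus:
    """Geometry and timing of a single trial.

    ``target_angle_deg`` is the polar angle of the target location (static) or
    of the motion axis (moving), 0deg rightward, counterclockwise positive.
    ``fixation_offset_ms`` is set only for moving trials (gap paradigm).
    """

    trial_id: int
    task: Task
    fixation_duration_ms: float
    target_angle_deg: float
    eccentricity_deg: float
    speed_deg_s: float
    target_onset_ms: float
    target_visible_ms: float
    fixation_offset_ms: float | None = None

    def __post_init__(self) -> None:
        if self.task == "static":
            if self.speed_deg_s != 0.0:
                raise ValueError("static trials have speed 0")
            if self.eccentricity_deg != STATIC_ECCENTRICITY_DEG:
                raise ValueError("static trials use 10 deg eccentricity")
        elif self.task == "moving":
            if self.speed_deg_s not in MOVING_SPEEDS_DEG_S:
                raise ValueError(f"moving speed must be one of {MOVING_SPEEDS_DEG_S}")
            if self.eccentricity_deg != MOVING_ECCENTRICITY_DEG:
                raise ValueError("moving trials use 15 deg eccentricity")
        else:
            raise ValueError(f"unknown task {self.task!r}")
        if not (FIXATION_RANGE_MS[0] <= self.fixation_duration_ms <= FIXATION_RANGE_MS[1]):
            raise ValueError("fixation duration outside [1000, 1500] ms")

    @property
    def trace_end_ms(self) -> float:
        """Length of the simulated/recorded trace for this trial."""
        if self.task == "static":
            # target visible 1000 ms; keep 200 ms extra for corrective chains
            return self.target_onset_ms + STATIC_TARGET_VISIBLE_MS + 200.0
        return self.target_onset_ms + MOVING_TRACE_AFTER_ONSET_MS


def _draw_fixation(rng: np.random.Generator) -> float:
    return float(rng.uniform(*FIXATION_RANGE_MS))


def _shuffle_no_repeat(items: list, rng: np.random.Generator, key) -> list:
    """Uniform shuffle repaired so no two consecutive items share ``key``."""
    order = list(rng.permutation(len(items)))
    seq = [items[i] for i in order]
    for _ in range(1000):
        bad = [i for i in range(1, len(seq)) if key(seq[i]) == key(seq[i - 1])]
        if not bad:
            return seq
        i = bad[0]
        # swap the offender with any position where both neighbourhoods stay legal
        candidates = [
            j
            for j in range(len(seq))
            if j != i
            and key(seq[j]) != key(seq[i - 1])
            and (i + 1 >= len(seq) or key(seq[j]) != key(seq[i + 1]))
            and (key(seq[i]) != key(seq[j - 1]) if j > 0 else True)
            and (j + 1 >= len(seq) or key(seq[i]) != key(seq[j + 1]))
        ]
        if not candidates:
            # restart from a fresh permutation (rare)
            order = list(rng.permutation(len(items)))
            seq = [items[i] for i in order]
            continue
        j = candidates[int(rng.integers(len(candidates)))]
        seq[i], seq[j] = seq[j], seq[i]
    raise RuntimeError("failed to build a no-repeat sequence")  # pragma: no cover


def build_static_session(seed: int) -> list[TrialStimulus]:
    """64 static trials, 8 per location, no immediate location repeats."""
    rng = np.random.default_rng(seed)
    angles = [a for a in STATIC_ANGLES_DEG for _ in range(STATIC_TRIALS_PER_ANGLE)]
    ordered = _shuffle_no_repeat(angles, rng, key=lambda a: a)
    trials = []
    for i, angle in enumerate(ordered):
        fix = _draw_fixation(rng)
        trials.append(
            TrialStimulus(
                trial_id=i,
                task="static",
                fixation_duration_ms=fix,
                target_angle_deg=float(angle),
                eccentricity_deg=STATIC_ECCENTRICITY_DEG,
                speed_deg_s=0.0,
                target_onset_ms=fix,
                target_visible_ms=STATIC_TARGET_VISIBLE_MS,
            )
        )
    return trials


def build_moving_session(seed: int) -> list[TrialStimulus]:
    """72 moving trials, 8 per (speed, axis) cell, fully randomized order."""
    rng = np.random.default_rng(seed)
    cells = [
        (speed, axis)
        for speed in MOVING_SPEEDS_DEG_S
        for axis in MOVING_AXES_DEG
        for _ in range(MOVING_TRIALS_PER_CELL)
    ]
    order = rng.permutation(len(cells))
    trials = []
    for i, idx in enumerate(order):
        speed, axis = cells[int(idx)]
        fix = _draw_fixation(rng)
        trials.append(
            TrialStimulus(
                trial_id=i,
                task="moving",
                fixation_duration_ms=fix,
                target_angle_deg=float(axis),
                eccentricity_deg=MOVING_ECCENTRICITY_DEG,
                speed_deg_s=float(speed),
                target_onset_ms=fix,
                target_visible_ms=MOVING_TRACE_AFTER_ONSET_MS,
                fixation_offset_ms=fix + GAP_AFTER_MOTION_ONSET_MS,
            )
        )
    return trials


def target_position(stim: TrialStimulus, t_ms: float | np.ndarray) -> tuple:
    """Cartesian target position (deg) at time ``t_ms`` on the trial clock.

    Static targets are fixed at ecc*(cos th, sin th).  Moving targets travel
    radially inward from 15 deg, through the centre and out the opposite side:
    d(t) = 15 - speed*(t - onset)/1000 along the axis th (d may go negative).

    Raises ``ValueError`` for query times before target onset.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < stim.target_onset_ms - 1e-9):
        raise ValueError("target position queried before target onset")
    th = math.radians(stim.target_angle_deg)
    if stim.task == "static":
        d = np.full_like(t, stim.eccentricity_deg)
    else:
        d = stim.eccentricity_deg - stim.speed_deg_s * (t - stim.target_onset_ms) / 1000.0
    x = d * math.cos(th)
    y = d * math.sin(th)
    if np.isscalar(t_ms) or np.ndim(t_ms) == 0:
        return float(x), float(y)
    return x, y


def session_to_json(trials: Sequence[TrialStimulus], **metadata) -> str:
    """Serialize a session schedule (plus metadata) to a JSON string."""
    payload = {"metadata": metadata, "trials": [asdict(t) for t in trials]}
    return json.dumps(payload, indent=1)


def session_from_json(text: str) -> tuple[list[TrialStimulus], dict]:
    payload = json.loads(text)
    trials = [TrialStimulus(**t) for t in payload["trials"]]
    return trials, payload.get("metadata", {})
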