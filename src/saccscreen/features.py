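"""Per-trial saccadic parameters and subject-level feature aggregation.

For every trial the primary saccade (first target-directed event in the
80-600 ms latency window) yields: latency relative to target appearance /
motion onset, amplitude, gain (amplitude / target eccentricity), peak
velocity, duration, and the task-appropriate accuracy measure -- endpoint
error (static: Euclidean distance from the saccade endpoint to the target)
or intercept error (moving: distance from the endpoint to the target's
position at saccade completion).  Trials without a qualifying primary saccade
are marked invalid and excluded from aggregation.

Subject-level vectors are arithmetic means over valid trials, with the
moving-task latency and intercept error additionally broken out per target
speed (5/10/15 deg/s), since the higher speeds discriminate best between
groups.  Subjects with fewer than half of their trials valid are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from saccscreen.detect import (
    DEFAULT_MERGE_GAP_MS,
    DEFAULT_MIN_AMPLITUDE_DEG,
    DEFAULT_MIN_DURATION_MS,
    DEFAULT_SMOOTH_WINDOW_MS,
    DEFAULT_THRESHOLD_DEG_S,
    SaccadeEvent,
    compute_velocity,
    detect_saccades,
    primary_saccade,
)
from saccscreen.paradigm import TrialStimulus, target_position
from saccscreen.simulate import SubjectData

MIN_VALID_STATIC = 32  # half of 64
MIN_VALID_MOVING = 36  # half of 72

#: subject-level feature columns used by the classifier (corrective-saccade
#: rate is extracted but excluded by default)
CLASSIFIER_FEATURES = [
    "static_latency_mean",
    "static_gain_mean",
    "static_peakvel_mean",
    "static_endpoint_err_mean",
    "static_duration_mean",
    "moving_latency_mean",
    "moving_latency_5",
    "moving_latency_10",
    "moving_latency_15",
    "intercept_err_mean",
    "intercept_err_5",
    "intercept_err_10",
    "intercept_err_15",
]


@dataclass(frozen=True)
class TrialFeatures:
    trial_id: int
    task: str
    speed_deg_s: float
    valid: bool
    latency_ms: float | None = None
    amplitude_deg: float | None = None
    gain: float | None = None
    peak_velocity_deg_s: float | None = None
    duration_ms: float | None = None
    endpoint_error_deg: float | None = None
    intercept_error_deg: float | None = None
    n_corrective: int = 0


def latency_reference(stim: TrialStimulus) -> float:
    """Latency reference time: target appearance (static) / motion onset (moving).

    For moving trials the reference is motion onset, not the 200-ms-later
    fixation offset; referencing the gap cue would shift all moving-task
    latencies by the gap duration.
    """
    return stim.target_onset_ms


def endpoint_error(event: SaccadeEvent, stim: TrialStimulus) -> float:
    """Euclidean distance (deg) from the saccade endpoint to the static target."""
    if stim.task != "static":
        raise ValueError("endpoint error is defined for static trials only")
    tx, ty = target_position(stim, stim.target_onset_ms)
    return math.hypot(event.end_xy_deg[0] - tx, event.end_xy_deg[1] - ty)


def intercept_error(event: SaccadeEvent, stim: TrialStimulus) -> float:
    """Distance (deg) from the endpoint to the moving target at saccade completion."""
    if stim.task != "moving":
        raise ValueError("intercept error is defined for moving trials only")
    tx, ty = target_position(stim, event.offset_ms)
    return math.hypot(event.end_xy_deg[0] - tx, event.end_xy_deg[1] - ty)


def extract_trial_features(events: list[SaccadeEvent], stim: TrialStimulus) -> TrialFeatures:
    """Reduce one trial's detected events to the trial feature record."""
    ref = latency_reference(stim)
    primary = primary_saccade(events, stim, ref)
    if primary is None:
        return TrialFeatures(
            trial_id=stim.trial_id, task=stim.task, speed_deg_s=stim.speed_deg_s, valid=False
        )
    n_corrective = sum(1 for ev in events if ev.onset_ms > primary.offset_ms)
    err_static = endpoint_error(primary, stim) if stim.task == "static" else None
    err_moving = intercept_error(primary, stim) if stim.task == "moving" else None
    return TrialFeatures(
        trial_id=stim.trial_id,
        task=stim.task,
        speed_deg_s=stim.speed_deg_s,
        valid=True,
        latency_ms=primary.onset_ms - ref,
        amplitude_deg=primary.amplitude_deg,
        gain=primary.amplitude_deg / stim.eccentricity_deg,
        peak_velocity_deg_s=primary.peak_velocity_deg_s,
        duration_ms=primary.duration_ms,
        endpoint_error_deg=err_static,
        intercept_error_deg=err_moving,
        n_corrective=n_corrective,
    )


def aggregate_subject(trial_features: list[TrialFeatures], subject_meta: dict) -> dict:
    """Mean the valid trials of one subject into the feature vector.

    ``subject_meta`` must carry at least ``subject_id`` and ``group``; clinical
    covariates (md_db, rnfl_um) are passed through when present.  Raises on
    empty input.  The returned dict includes validity counts and an
    ``included`` flag (False when fewer than half of either task's trials are
    valid).
    """
    if not trial_features:
        raise ValueError("no trials to aggregate")
    static = [tf for tf in trial_features if tf.task == "static" and tf.valid]
    moving = [tf for tf in trial_features if tf.task == "moving" and tf.valid]

    def mean(records, attr):
        vals = [getattr(tf, attr) for tf in records]
        return float(np.mean(vals)) if vals else float("nan")

    row = dict(subject_meta)
    row.update(
        static_latency_mean=mean(static, "latency_ms"),
        static_gain_mean=mean(static, "gain"),
        static_peakvel_mean=mean(static, "peak_velocity_deg_s"),
        static_endpoint_err_mean=mean(static, "endpoint_error_deg"),
        static_duration_mean=mean(static, "duration_ms"),
        moving_latency_mean=mean(moving, "latency_ms"),
        intercept_err_mean=mean(moving, "intercept_error_deg"),
        corrective_rate_mean=mean([tf for tf in trial_features if tf.valid], "n_corrective"),
        n_valid_static=len(static),
        n_valid_moving=len(moving),
    )
    for speed in (5, 10, 15):
        sel = [tf for tf in moving if tf.speed_deg_s == speed]
        row[f"moving_latency_{speed}"] = mean(sel, "latency_ms")
        row[f"intercept_err_{speed}"] = mean(sel, "intercept_error_deg")
    row["included"] = len(static) >= MIN_VALID_STATIC and len(moving) >= MIN_VALID_MOVING
    return row


def subject_features(
    data: SubjectData,
    threshold_deg_s: float = DEFAULT_THRESHOLD_DEG_S,
    smooth_window_ms: int = DEFAULT_SMOOTH_WINDOW_MS,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
    min_amplitude_deg: float = DEFAULT_MIN_AMPLITUDE_DEG,
) -> tuple[dict, list[TrialFeatures]]:
    """Run detection + extraction over one simulated subject's sessions."""
    trial_feats: list[TrialFeatures] = []
    for task in ("static", "moving"):
        for stim, trace, _events in data.records(task):
            vel = compute_velocity(trace, smooth_window_ms)
            detected = detect_saccades(
                vel,
                trace,
                threshold_deg_s=threshold_deg_s,
                min_duration_ms=min_duration_ms,
                merge_gap_ms=merge_gap_ms,
                min_amplitude_deg=min_amplitude_deg,
            )
            trial_feats.append(extract_trial_features(detected, stim))
    meta = {
        "subject_id": data.params.subject_id,
        "group": data.params.group,
        "md_db": data.params.md_db,
        "rnfl_um": data.params.rnfl_um,
    }
    return aggregate_subject(trial_feats, meta), trial_feats


def cohort_feature_table(subjects, **detector_kwargs) -> pd.DataFrame:
    """Subject-per-row feature table from an iterable of SubjectData.

    Accepts a list or a streaming iterator (traces of each subject can be
    garbage-collected once its row is built).
    """
    rows = [subject_features(data, **detector_kwargs)[0] for data in subjects]
    if not rows:
        raise ValueError("empty cohort")
    return pd.DataFrame(rows)
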