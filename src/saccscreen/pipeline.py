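"""End-to-end pipeline: simulate -> detect -> features -> analyze.

Subjects are processed one at a time (traces are dropped once their rows are
written), so cohort size is limited by disk, not memory.  Every run writes a
manifest with a config hash, per-stage wall-clock and the file listing;
re-running the same config reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from saccscreen import __version__
from saccscreen.analyze import CONTRASTS, nested_cv_classify, pearson_r, summarize_groups
from saccscreen.config import PipelineConfig
from saccscreen.detect import compute_velocity, detect_saccades
from saccscreen.features import extract_trial_features, aggregate_subject
from saccscreen.paradigm import session_to_json
from saccscreen.simulate import GroundTruthEvent, iter_cohort

EVENT_COLUMNS = [
    "subject_id", "task", "trial_id", "event_index", "onset_ms", "offset_ms",
    "duration_ms", "amplitude_deg", "peak_velocity_deg_s",
    "start_x", "start_y", "end_x", "end_y", "direction_deg",
]
GROUND_TRUTH_COLUMNS = [
    "subject_id", "task", "trial_id", "event_index", "onset_ms", "offset_ms",
    "amplitude_deg", "peak_velocity_deg_s", "kind",
]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {seconds, files}
    detection_report: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def match_events(detected, truth: list[GroundTruthEvent], tol_ms: float = 20.0):
    """Greedy one-to-one matching of detected events to ground truth.

    A pair matches when the detected onset lies within the truth movement
    interval extended by ``tol_ms``.  Returns (n_matched, n_truth, n_detected).
    """
    used = set()
    matched = 0
    for ev in detected:
        for i, gt in enumerate(truth):
            if i in used:
                continue
            if gt.onset_ms - tol_ms <= ev.onset_ms <= gt.offset_ms + tol_ms:
                used.add(i)
                matched += 1
                break
    return matched, len(truth), len(detected)


def _check_schema(df: pd.DataFrame, columns: list[str], name: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise RuntimeError(f"stage output {name} missing columns {missing}")
    return df[columns]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full study pipeline and write all artifact tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config), package_version=__version__, seed=config.seed
    )
    profiles = config.load_profiles()
    det = config.detector

    t0 = time.time()
    gt_rows, event_rows, trial_rows, subject_rows = [], [], [], []
    recall_hits = recall_total = precision_total = matched_all = 0
    traces_dir = out / "traces"
    for si, data in enumerate(iter_cohort(config.n_per_group, profiles, config.seed)):
        trial_feats = []
        persist = si < config.persist_trace_subjects
        if persist:
            sdir = traces_dir / data.params.subject_id
            sdir.mkdir(parents=True, exist_ok=True)
        for task in ("static", "moving"):
            if persist:
                (sdir / f"{task}_session.json").write_text(
                    session_to_json(
                        data.static_trials if task == "static" else data.moving_trials,
                        task=task, subject_id=data.params.subject_id, seed=config.seed,
                    )
                )
            for stim, trace, truth in data.records(task):
                vel = compute_velocity(trace, det.smooth_window_ms)
                events = detect_saccades(
                    vel, trace,
                    threshold_deg_s=det.threshold_deg_s,
                    min_duration_ms=det.min_duration_ms,
                    merge_gap_ms=det.merge_gap_ms,
                    min_amplitude_deg=det.min_amplitude_deg,
                )
                trial_feats.append(extract_trial_features(events, stim))
                m_all, _, nd = match_events(events, truth)
                matched_all += m_all
                precision_total += nd
                primaries = [gt for gt in truth if gt.kind == "primary"]
                m, nt, _ = match_events(events, primaries)
                recall_hits += m
                recall_total += nt
                base = {"subject_id": data.params.subject_id, "task": task, "trial_id": stim.trial_id}
                for gt in truth:
                    gt_rows.append({**base, "event_index": gt.event_index,
                                    "onset_ms": gt.onset_ms, "offset_ms": gt.offset_ms,
                                    "amplitude_deg": gt.amplitude_deg,
                                    "peak_velocity_deg_s": gt.peak_velocity_deg_s,
                                    "kind": gt.kind})
                for k, ev in enumerate(events):
                    event_rows.append({**base, "event_index": k,
                                       "onset_ms": ev.onset_ms, "offset_ms": ev.offset_ms,
                                       "duration_ms": ev.duration_ms,
                                       "amplitude_deg": ev.amplitude_deg,
                                       "peak_velocity_deg_s": ev.peak_velocity_deg_s,
                                       "start_x": ev.start_xy_deg[0], "start_y": ev.start_xy_deg[1],
                                       "end_x": ev.end_xy_deg[0], "end_y": ev.end_xy_deg[1],
                                       "direction_deg": ev.direction_deg})
                if persist:
                    pd.DataFrame(
                        {"t_ms": trace.t_ms, "x_deg": trace.x_deg, "y_deg": trace.y_deg}
                    ).to_csv(sdir / f"{task}_{stim.trial_id:03d}.csv", index=False)
        meta = {"subject_id": data.params.subject_id, "group": data.params.group,
                "md_db": data.params.md_db, "rnfl_um": data.params.rnfl_um}
        subject_rows.append(aggregate_subject(trial_feats, meta))
        for tf in trial_feats:
            trial_rows.append({"subject_id": data.params.subject_id, **asdict(tf)})

    _check_schema(pd.DataFrame(gt_rows), GROUND_TRUTH_COLUMNS, "ground_truth").to_csv(
        out / "ground_truth.csv", index=False
    )
    _check_schema(pd.DataFrame(event_rows), EVENT_COLUMNS, "events").to_csv(
        out / "events.csv", index=False
    )
    pd.DataFrame(trial_rows).to_csv(out / "trial_features.csv", index=False)
    features = pd.DataFrame(subject_rows)
    features.to_csv(out / "subject_features.csv", index=False)
    manifest.detection_report = {
        # recall over injected primary saccades; precision over all detections
        "recall": recall_hits / max(recall_total, 1),
        "precision": matched_all / max(precision_total, 1),
        "n_primary_ground_truth": recall_total,
        "n_detected": precision_total,
    }
    manifest.stages["simulate_detect_features"] = {
        "seconds": round(time.time() - t0, 2),
        "files": ["ground_truth.csv", "events.csv", "trial_features.csv", "subject_features.csv"],
    }

    t0 = time.time()
    gs = summarize_groups(features)
    gs.summary.to_csv(out / "group_summary.csv", index=False)
    gs.contrasts.to_csv(out / "group_contrasts.csv", index=False)
    r_md = pearson_r(features["intercept_err_mean"], features["md_db"])
    r_rnfl = pearson_r(features["intercept_err_mean"], features["rnfl_um"])
    reports = {}
    for contrast in CONTRASTS:
        rep = nested_cv_classify(
            features, contrast,
            outer_folds=config.cv.outer_folds, inner_folds=config.cv.inner_folds,
            seed=config.seed, n_boot=config.cv.n_boot,
            importance_repeats=config.cv.importance_repeats,
        )
        rep.roc.points.to_csv(out / f"roc_{contrast}.csv", index=False)
        reports[contrast] = {
            "auc": rep.auc, "ci": [rep.roc.ci_low, rep.roc.ci_high],
            "sensitivity": rep.roc.sensitivity, "specificity": rep.roc.specificity,
            "threshold": rep.roc.threshold, "fold_aucs": rep.fold_aucs,
            "fold_auc_sd": rep.fold_auc_sd, "fold_params": rep.fold_params,
            "importances": rep.importances.to_dict(),
        }
    (out / "classification.json").write_text(json.dumps({
        "contrasts": reports,
        "correlations": {
            "intercept_err_vs_md": {"r": r_md[0], "p": r_md[1]},
            "intercept_err_vs_rnfl": {"r": r_rnfl[0], "p": r_rnfl[1]},
        },
    }, indent=1))
    manifest.stages["analyze"] = {
        "seconds": round(time.time() - t0, 2),
        "files": ["group_summary.csv", "group_contrasts.csv", "classification.json"]
        + [f"roc_{c}.csv" for c in CONTRASTS],
    }
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
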