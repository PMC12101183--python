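"""Simulate the study cohort: 16 subjects per group, both oculomotor tasks.

Writes the ground-truth event sidecar, the trial schedules and example raw
traces for one subject per group under results/cohort/, plus a short summary
of the generating subject parameters.  Later steps (02-05) re-derive
everything measurable from the traces alone.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from saccscreen.profiles import default_profiles, profiles_to_yaml
from saccscreen.simulate import iter_cohort

OUT = Path("results/cohort")
SEED = 20210301  # study data collection began March 2021
N_PER_GROUP = 16

OUT.mkdir(parents=True, exist_ok=True)
(OUT / "profiles.yaml").write_text(profiles_to_yaml(default_profiles()))

rows, gt_rows = [], []
examples_written = set()
for data in iter_cohort(N_PER_GROUP, default_profiles(), seed=SEED):
    p = data.params
    rows.append({
        "subject_id": p.subject_id, "group": p.group, "severity_z": p.latent_severity_z,
        "static_latency_mean_ms": p.static_latency_mean_ms,
        "moving_latency_mean_ms": p.moving_latency_mean_ms,
        "gain": p.gain, "peakvel_deg_s": p.peakvel_at_group_amp_deg_s,
        "endpoint_err_deg": p.endpoint_err_mean_deg,
        "intercept_err_deg": p.intercept_err_mean_deg,
        "md_db": p.md_db, "rnfl_um": p.rnfl_um,
    })
    for task in ("static", "moving"):
        for stim, trace, truth in data.records(task):
            for ev in truth:
                gt_rows.append({
                    "subject_id": p.subject_id, "task": task, "trial_id": stim.trial_id,
                    "event_index": ev.event_index, "onset_ms": ev.onset_ms,
                    "offset_ms": ev.offset_ms, "amplitude_deg": ev.amplitude_deg,
                    "peak_velocity_deg_s": ev.peak_velocity_deg_s, "kind": ev.kind,
                })
    if p.group not in examples_written:
        examples_written.add(p.group)
        stim, trace, _ = data.static_records[0]
        pd.DataFrame({"t_ms": trace.t_ms, "x_deg": trace.x_deg, "y_deg": trace.y_deg}).to_csv(
            OUT / f"example_trace_{p.group}.csv", index=False
        )

params = pd.DataFrame(rows)
params.to_csv(OUT / "subject_params.csv", index=False)
pd.DataFrame(gt_rows).to_csv(OUT / "ground_truth.csv", index=False)

summary = params.groupby("group")[["static_latency_mean_ms", "gain", "intercept_err_deg", "md_db"]].mean()
print(f"simulated {len(params)} subjects x 136 trials (seed {SEED})")
print(summary.round(3))
(OUT / "meta.json").write_text(json.dumps({"seed": SEED, "n_per_group": N_PER_GROUP}))
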