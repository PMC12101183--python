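"""Group comparisons of the saccadic parameters and clinical correlations.

Welch t tests on subject means with Holm-Bonferroni adjustment across the
three pairwise group contrasts per feature, plus Pearson correlations of the
moving-task intercept error with visual-field mean deviation and RNFL
thickness.  Writes group_summary.csv, group_contrasts.csv, correlations.json.
"""

import json
from pathlib import Path

import pandas as pd

from saccscreen.analyze import pearson_r, summarize_groups

OUT = Path("results/cohort")
features = pd.read_csv(OUT / "subject_features.csv")

gs = summarize_groups(features)
gs.summary.to_csv(OUT / "group_summary.csv", index=False)
gs.contrasts.to_csv(OUT / "group_contrasts.csv", index=False)

corrs = {}
for covariate in ("md_db", "rnfl_um"):
    r, p = pearson_r(features["intercept_err_mean"], features[covariate])
    corrs[f"intercept_err_vs_{covariate}"] = {"r": round(r, 3), "p": float(p)}
(OUT / "correlations.json").write_text(json.dumps(corrs, indent=1))

key = gs.contrasts[gs.contrasts.feature.isin(["moving_latency_mean", "intercept_err_mean"])]
print("pairwise contrasts (moving task):")
print(key[["feature", "group_a", "group_b", "diff", "p_adj"]].round(4).to_string(index=False))
print("correlations with clinical severity:", json.dumps(corrs))
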