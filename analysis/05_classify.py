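"""Nested cross-validated Random Forest classification of glaucoma status.

For each binary contrast against controls (any glaucoma, moderate,
preperimetric): stratified 10-fold outer CV, inner grid search (trees
100/200/500, depth 3-10, min split 2-10) by inner-CV accuracy, pooled
out-of-fold probabilities -> rank AUC with bootstrap CI and Youden operating
point, plus permutation importances.  At the study's own size (16 per group)
AUC estimates are noisy; the acceptance script reruns this protocol at 100
per group.  Writes classification.json and roc_<contrast>.csv.
"""

import json
from pathlib import Path

import pandas as pd

from saccscreen.analyze import CONTRASTS, nested_cv_classify

OUT = Path("results/cohort")
features = pd.read_csv(OUT / "subject_features.csv")

report = {}
for contrast in CONTRASTS:
    rep = nested_cv_classify(features, contrast, seed=11, importance_repeats=50)
    rep.roc.points.to_csv(OUT / f"roc_{contrast}.csv", index=False)
    report[contrast] = {
        "auc": round(rep.auc, 3),
        "ci95": [round(rep.roc.ci_low, 3), round(rep.roc.ci_high, 3)],
        "sensitivity": round(rep.roc.sensitivity, 3),
        "specificity": round(rep.roc.specificity, 3),
        "fold_auc_sd": round(rep.fold_auc_sd, 3),
        "top_features": list(rep.importances.index[:4]),
    }
    print(f"{contrast}: AUC {report[contrast]['auc']} "
          f"(95% CI {report[contrast]['ci95'][0]}-{report[contrast]['ci95'][1]}), "
          f"sens {report[contrast]['sensitivity']}, spec {report[contrast]['specificity']}")
    print(f"  top features: {', '.join(report[contrast]['top_features'])}")
(OUT / "classification.json").write_text(json.dumps(report, indent=1))
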