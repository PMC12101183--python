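"""Group statistics, ROC analysis and nested cross-validated classification.

Analysis operates on the subject-level feature table (subjects are the unit
of analysis throughout; folds never split a subject's trials).  Three binary
contrasts against the control group are evaluated: both patient groups pooled
("any glaucoma"), moderate only, and preperimetric only.

The classifier protocol is a Random Forest with nested cross-validation:
stratified 10-fold outer loop for performance estimation and a stratified
inner loop that grid-searches trees {100, 200, 500} x max depth {3, 5, 7, 10}
x min samples per split {2, 5, 10} by inner-CV accuracy.  Out-of-fold class
probabilities are pooled for a single ROC per contrast (rank AUC, stratified
percentile-bootstrap CI, Youden operating point), and feature importance is
permutation importance: the mean drop in out-of-fold AUC when one feature
column is shuffled, averaged over repeats and outer folds.

Group comparisons use Welch t tests on subject means with Holm-Bonferroni
adjustment across the three pairwise contrasts per feature.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from saccscreen.features import CLASSIFIER_FEATURES
from saccscreen.profiles import GROUPS

N_ESTIMATORS_GRID = (100, 200, 500)
MAX_DEPTH_GRID = (3, 5, 7, 10)
MIN_SPLIT_GRID = (2, 5, 10)

CONTRASTS = {
    "any_glaucoma_vs_control": ("preperimetric", "moderate"),
    "moderate_vs_control": ("moderate",),
    "preperimetric_vs_control": ("preperimetric",),
}


# ---------------------------------------------------------------------------
# Group summaries

@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptives and Holm-adjusted pairwise Welch contrasts."""

    summary: pd.DataFrame  # feature, group, n, mean, sd
    contrasts: pd.DataFrame  # feature, group_a, group_b, diff, t, p, p_adj


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, bounded at 1)."""
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def summarize_groups(features: pd.DataFrame, columns: list[str] | None = None) -> GroupSummary:
    """Descriptives plus pairwise Welch tests for every feature column."""
    columns = columns or [c for c in CLASSIFIER_FEATURES if c in features.columns]
    counts = features.groupby("group").size()
    for g in GROUPS:
        if counts.get(g, 0) < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")
    srows, crows = [], []
    for col in columns:
        for g in GROUPS:
            vals = features.loc[features["group"] == g, col].to_numpy(dtype=float)
            srows.append(
                {"feature": col, "group": g, "n": len(vals),
                 "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1))}
            )
        pvals = []
        for ga, gb in itertools.combinations(GROUPS, 2):
            a = features.loc[features["group"] == ga, col].to_numpy(dtype=float)
            b = features.loc[features["group"] == gb, col].to_numpy(dtype=float)
            t, p = stats.ttest_ind(b, a, equal_var=False)
            crows.append(
                {"feature": col, "group_a": ga, "group_b": gb,
                 "diff": float(np.mean(b) - np.mean(a)), "t": float(t), "p": float(p)}
            )
            pvals.append(float(p))
        adj = _holm(np.asarray(pvals))
        for k in range(3):
            crows[-3 + k]["p_adj"] = float(adj[k])
    return GroupSummary(summary=pd.DataFrame(srows), contrasts=pd.DataFrame(crows))


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC primitives

def auc_rank(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Stratified percentile bootstrap 95% CI for the rank AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    lab = np.r_[np.ones(len(pos), int), np.zeros(len(neg), int)]
    for i in range(n_boot):
        sample = np.r_[rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
        aucs[i] = auc_rank(sample, lab)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC: one row per candidate threshold (score >= thr positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    rows = []
    n1 = labels.sum()
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    for thr in thresholds:
        pred = scores >= thr
        tpr = float((pred & (labels == 1)).sum() / n1)
        fpr = float((pred & (labels == 0)).sum() / n0)
        rows.append({"threshold": float(thr), "tpr": tpr, "fpr": fpr})
    return pd.DataFrame(rows)


def youden_point(roc: pd.DataFrame) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing J = sens + spec - 1.

    Ties are broken toward higher sensitivity.
    """
    if len(roc) == 0:
        raise ValueError("empty ROC")
    j = roc["tpr"].to_numpy() - roc["fpr"].to_numpy()
    best = np.flatnonzero(j == j.max())
    idx = best[np.argmax(roc["tpr"].to_numpy()[best])]
    row = roc.iloc[idx]
    return float(row["threshold"]), float(row["tpr"]), float(1.0 - row["fpr"])


@dataclass(frozen=True)
class RocResult:
    contrast: str
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    points: pd.DataFrame


def roc_analysis(scores, labels, contrast: str = "", n_boot: int = 2000, seed: int = 0) -> RocResult:
    pts = roc_points(scores, labels)
    thr, sens, spec = youden_point(pts)
    lo, hi = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    return RocResult(
        contrast=contrast,
        auc=auc_rank(scores, labels),
        ci_low=lo,
        ci_high=hi,
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        points=pts,
    )


# ---------------------------------------------------------------------------
# Nested cross-validated Random Forest

@dataclass
class CvReport:
    contrast: str
    feature_columns: list
    subject_ids: list
    labels: np.ndarray
    oof_scores: np.ndarray  # out-of-fold P(class 1), one per subject
    fold_assignments: np.ndarray
    fold_params: list  # chosen hyperparameters per outer fold
    fold_aucs: list
    roc: RocResult = None
    importances: pd.Series = None

    @property
    def auc(self) -> float:
        return self.roc.auc

    @property
    def fold_auc_sd(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))


def _staged_forest_accuracy(X_tr, y_tr, X_va, y_va, depth, min_split, seeds) -> list:
    """Validation accuracy of a random forest at each n_estimators stage.

    Grows one bootstrap forest (sqrt feature subsampling, averaged class
    probabilities -- the standard random-forest recipe) tree by tree with
    bare DecisionTree estimators, scoring at 100/200/500 trees; one 500-tree
    build therefore prices all three grid stages.
    """
    rng = np.random.default_rng(int(seeds[0]))
    tree_seeds = seeds[1:]
    n_tr = len(y_tr)
    proba = np.zeros(len(y_va))
    accs = []
    for t in range(N_ESTIMATORS_GRID[-1]):
        counts = np.bincount(rng.integers(0, n_tr, n_tr), minlength=n_tr).astype(float)
        tree = DecisionTreeClassifier(
            max_depth=depth, min_samples_split=min_split, max_features="sqrt",
            random_state=int(tree_seeds[t]),
        )
        tree.fit(X_tr, y_tr, sample_weight=counts, check_input=False)
        p = tree.predict_proba(X_va, check_input=False)
        proba += p[:, 1] if p.shape[1] == 2 else float(tree.classes_[0])
        if t + 1 in N_ESTIMATORS_GRID:
            accs.append(((proba / (t + 1) >= 0.5).astype(int) == y_va).mean())
    return accs


def _inner_grid_select(X, y, inner_folds: int, seed: int) -> dict:
    """Grid search by inner-CV accuracy with staged forest evaluation.

    Ties break toward the earliest cell in (n_estimators, max_depth,
    min_samples_split) grid order.
    """
    skf = StratifiedKFold(inner_folds, shuffle=True, random_state=seed % (2**31))
    acc = np.zeros((len(N_ESTIMATORS_GRID), len(MAX_DEPTH_GRID), len(MIN_SPLIT_GRID)))
    splits = list(skf.split(X, y))
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    seeds = np.random.SeedSequence(seed % (2**31)).generate_state(
        1 + N_ESTIMATORS_GRID[-1]
    )
    with sklearn.config_context(skip_parameter_validation=True):
        for tr, va in splits:
            X_tr = np.ascontiguousarray(X32[tr])
            X_va = np.ascontiguousarray(X32[va])
            for di, depth in enumerate(MAX_DEPTH_GRID):
                for mi, msplit in enumerate(MIN_SPLIT_GRID):
                    stage_accs = _staged_forest_accuracy(
                        X_tr, y[tr], X_va, y[va], depth, msplit, seeds
                    )
                    for ni, a in enumerate(stage_accs):
                        acc[ni, di, mi] += a
    acc /= len(splits)
    ni, di, mi = np.unravel_index(int(np.argmax(acc)), acc.shape)
    return {
        "n_estimators": N_ESTIMATORS_GRID[ni],
        "max_depth": MAX_DEPTH_GRID[di],
        "min_samples_split": MIN_SPLIT_GRID[mi],
    }


def contrast_frame(features: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Rows of the feature table entering one binary contrast, labelled 0/1."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    positives = CONTRASTS[contrast]
    sel = features[features["group"].isin(("control",) + positives)].copy()
    sel["label"] = sel["group"].isin(positives).astype(int)
    return sel


def nested_cv_classify(
    features: pd.DataFrame,
    contrast: str,
    outer_folds: int = 10,
    inner_folds: int = 2,
    seed: int = 0,
    feature_columns: list | None = None,
    n_boot: int = 2000,
    importance_repeats: int = 50,
) -> CvReport:
    """Nested CV Random Forest for one binary contrast.

    Subjects are the CV unit; outer folds are stratified by class.  Returns
    pooled out-of-fold scores with ROC/AUC/Youden summaries, per-fold chosen
    hyperparameters, fold AUCs, and permutation importances.  Deterministic
    given ``seed``.
    """
    feature_columns = feature_columns or [c for c in CLASSIFIER_FEATURES if c in features.columns]
    sel = contrast_frame(features, contrast)
    X = sel[feature_columns].to_numpy(dtype=float)
    y = sel["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(zlib.crc32(contrast.encode()) % 2**16,)
    )
    fold_seeds = ss.generate_state(outer_folds + 2)
    outer = StratifiedKFold(outer_folds, shuffle=True, random_state=int(fold_seeds[0] % 2**31))
    oof = np.full(len(y), np.nan)
    fold_assign = np.full(len(y), -1)
    fold_params, fold_aucs, models = [], [], []
    for fi, (tr, te) in enumerate(outer.split(X, y)):
        if len(np.unique(y[tr])) < 2:  # pragma: no cover - stratified folds
            raise ValueError("a class is absent from an outer training fold")
        best = _inner_grid_select(X[tr], y[tr], inner_folds, int(fold_seeds[fi + 1]))
        model = RandomForestClassifier(
            **best, random_state=int(fold_seeds[fi + 1] % 2**31), n_jobs=1
        ).fit(X[tr], y[tr])
        oof[te] = model.predict_proba(X[te])[:, 1]
        fold_assign[te] = fi
        fold_params.append(best)
        fold_aucs.append(auc_rank(oof[te], y[te]))
        models.append((model, te))
    report = CvReport(
        contrast=contrast,
        feature_columns=list(feature_columns),
        subject_ids=list(sel["subject_id"]),
        labels=y,
        oof_scores=oof,
        fold_assignments=fold_assign,
        fold_params=fold_params,
        fold_aucs=fold_aucs,
    )
    report.roc = roc_analysis(oof, y, contrast, n_boot=n_boot, seed=int(fold_seeds[-1] % 2**31))
    if importance_repeats > 0:
        report.importances = permutation_importance(
            models, X, y, n_repeats=importance_repeats,
            seed=int(fold_seeds[-1] % 2**31) + 1, feature_names=feature_columns,
        )
    return report


def permutation_importance(
    models, X, y, n_repeats: int = 50, seed: int = 0, feature_names: list | None = None
) -> pd.Series:
    """Mean out-of-fold AUC drop per permuted feature, over repeats and folds.

    ``models`` is a list of (fitted classifier, test index) pairs from the
    outer CV loop; each model is evaluated only on its own held-out subjects.
    """
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    names = feature_names or list(range(p))
    drops = np.zeros(p)
    n_folds = 0
    for model, te in models:
        if len(np.unique(y[te])) < 2:
            continue
        n_folds += 1
        base = auc_rank(model.predict_proba(X[te])[:, 1], y[te])
        for j in range(p):
            # evaluate all repeats in one predict call
            tiled = np.tile(X[te], (n_repeats, 1))
            for r in range(n_repeats):
                block = tiled[r * len(te) : (r + 1) * len(te)]
                block[:, j] = block[:, j][rng.permutation(len(te))]
            probs = model.predict_proba(tiled)[:, 1]
            rep_auc = [
                auc_rank(probs[r * len(te) : (r + 1) * len(te)], y[te]) for r in range(n_repeats)
            ]
            drops[j] += base - float(np.mean(rep_auc))
    if n_folds == 0:
        raise ValueError("no fold with both classes present")
    return pd.Series(drops / n_folds, index=names).sort_values(ascending=False)
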