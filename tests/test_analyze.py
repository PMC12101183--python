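import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from saccscreen.analyze import (
    _holm,
    auc_rank,
    bootstrap_auc_ci,
    contrast_frame,
    nested_cv_classify,
    pearson_r,
    permutation_importance,
    roc_points,
    summarize_groups,
    youden_point,
)


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# group summaries

def make_features(groups_values, column="static_latency_mean"):
    rows = []
    for g, vals in groups_values.items():
        for i, v in enumerate(vals):
            rows.append({"subject_id": f"{g}{i}", "group": g, column: v})
    return pd.DataFrame(rows)


def test_identical_groups_give_null_contrasts():
    vals = [1.0, 2.0, 3.0, 4.0]
    df = make_features({"control": vals, "preperimetric": vals, "moderate": vals})
    gs = summarize_groups(df, ["static_latency_mean"])
    assert np.allclose(gs.contrasts["diff"], 0.0)
    assert (gs.contrasts["p"] > 0.99).all()


def test_welch_statistic_matches_hand_formula():
    a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 10.0]
    df = make_features({"control": a, "preperimetric": b, "moderate": [1.0, 1.5, 2.0]})
    gs = summarize_groups(df, ["static_latency_mean"])
    row = gs.contrasts[(gs.contrasts.group_a == "control") & (gs.contrasts.group_b == "preperimetric")].iloc[0]
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    t_hand = (np.mean(b) - np.mean(a)) / math.sqrt(va / 3 + vb / 3)
    assert row["t"] == pytest.approx(t_hand, abs=1e-10)
    assert row["p_adj"] >= row["p"]


def test_holm_adjustment_hand_example():
    # step-down: 3*0.01=0.03; 2*0.03=0.06; 1*0.04=0.04 raised to 0.06 (monotone)
    adj = _holm(np.array([0.01, 0.04, 0.03]))
    assert adj == pytest.approx([0.03, 0.06, 0.06])


def test_group_with_single_subject_rejected():
    df = make_features({"control": [1.0], "preperimetric": [1.0, 2.0], "moderate": [1.0, 2.0]})
    with pytest.raises(ValueError):
        summarize_groups(df, ["static_latency_mean"])


# ---------------------------------------------------------------------------
# correlation

def test_pearson_exact_cases():
    x = np.arange(10.0)
    r, p = pearson_r(x, -x)
    assert r == pytest.approx(-1.0)
    # 6-point hand-computed dataset via the direct formula
    x6 = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 11.0])
    y6 = np.array([2.0, 1.0, 5.0, 3.0, 11.0, 8.0])
    r_hand = np.sum((x6 - x6.mean()) * (y6 - y6.mean())) / math.sqrt(
        np.sum((x6 - x6.mean()) ** 2) * np.sum((y6 - y6.mean()) ** 2)
    )
    assert pearson_r(x6, y6)[0] == pytest.approx(r_hand, abs=1e-12)


def test_pearson_null_case_and_errors():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=10000), rng.normal(size=10000)
    r, _ = pearson_r(x, y)
    assert abs(r) < 0.05
    with pytest.raises(ValueError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson_r([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# AUC / ROC primitives

def test_auc_perfect_and_tied():
    assert auc_rank([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auc_rank([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    with pytest.raises(ValueError):
        auc_rank([0.1, 0.2], [1, 1])


@settings(max_examples=200, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), st.integers(0, 1)),
        min_size=2,
        max_size=8,
    )
)
def test_auc_matches_pair_counting_oracle(data):
    scores = [d[0] for d in data]
    labels = [d[1] for d in data]
    if len(set(labels)) < 2:
        return
    assert auc_rank(scores, labels) == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


def test_auc_equals_trapezoid_area_for_tie_free_scores():
    rng = np.random.default_rng(1)
    scores = rng.permutation(np.linspace(0, 1, 40))
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    pts = roc_points(scores, labels).sort_values("fpr")
    area = np.trapezoid(pts["tpr"], pts["fpr"])
    assert auc_rank(scores, labels) == pytest.approx(area, abs=1e-12)


def test_bootstrap_ci_deterministic_and_tight_when_separated():
    scores = np.r_[np.zeros(50), np.ones(50)]
    labels = np.r_[np.zeros(50, int), np.ones(50, int)]
    lo, hi = bootstrap_auc_ci(scores, labels, n_boot=500, seed=3)
    assert (lo, hi) == bootstrap_auc_ci(scores, labels, n_boot=500, seed=3)
    assert lo >= 0.99 and hi == 1.0


def test_bootstrap_ci_covers_null():
    """On label-independent scores the CI contains 0.5 in >= 93/100 replicates."""
    rng = np.random.default_rng(4)
    covered = 0
    labels = np.r_[np.zeros(100, int), np.ones(100, int)]
    for rep in range(100):
        scores = rng.normal(size=200)
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=400, seed=rep)
        covered += lo <= 0.5 <= hi
    assert covered >= 93


def exhaustive_youden_oracle(scores, labels):
    best = (-1.0, None)
    for thr in np.r_[np.inf, np.unique(scores)]:
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1.0
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and best[1] and sens > best[1][1]):
            best = (j, (thr, sens, spec))
    return best[1]


def test_youden_matches_exhaustive_scan():
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
    labels = np.array([0, 0, 1, 1, 0, 1])
    pts = roc_points(scores, labels)
    thr, sens, spec = youden_point(pts)
    o_thr, o_sens, o_spec = exhaustive_youden_oracle(scores, labels)
    assert (sens, spec) == pytest.approx((o_sens, o_spec))
    assert sens + spec - 1 == pytest.approx(o_sens + o_spec - 1)


def test_youden_degenerate_cases():
    scores = np.r_[np.zeros(5), np.ones(5)]
    labels = np.r_[np.zeros(5, int), np.ones(5, int)]
    _, sens, spec = youden_point(roc_points(scores, labels))
    assert sens == 1.0 and spec == 1.0
    flat = youden_point(roc_points(np.full(10, 0.5), labels))
    assert flat[1] + flat[2] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# nested CV

def synthetic_table(n_per_group, rng, informative=True):
    rows = []
    for g, shift in (("control", 0.0), ("preperimetric", 1.0), ("moderate", 2.0)):
        for i in range(n_per_group):
            feats = rng.normal(size=4)
            if informative:
                feats = feats + shift
            rows.append({
                "subject_id": f"{g}{i}", "group": g,
                **{f"f{k}": feats[k] for k in range(4)},
            })
    return pd.DataFrame(rows)


def test_contrast_frame_labels():
    df = synthetic_table(3, np.random.default_rng(0))
    sel = contrast_frame(df, "moderate_vs_control")
    assert set(sel["group"]) == {"control", "moderate"}
    assert sel["label"].sum() == 3
    with pytest.raises(ValueError):
        contrast_frame(df, "nope")


def test_nested_cv_perfect_feature_gives_auc_one():
    rng = np.random.default_rng(5)
    df = synthetic_table(15, rng, informative=False)
    df["f0"] = (df["group"] != "control").astype(float)
    rep = nested_cv_classify(
        df, "any_glaucoma_vs_control", outer_folds=5, seed=1,
        feature_columns=["f0", "f1", "f2", "f3"], n_boot=100, importance_repeats=5,
    )
    assert rep.auc == 1.0
    # every subject scored exactly once out-of-sample
    assert not np.isnan(rep.oof_scores).any()
    assert (rep.fold_assignments >= 0).all()
    # the only informative feature dominates the permutation importances
    assert rep.importances.index[0] == "f0"


def test_nested_cv_null_features_near_chance():
    rng = np.random.default_rng(6)
    df = synthetic_table(34, rng, informative=False)
    rep = nested_cv_classify(
        df, "preperimetric_vs_control", outer_folds=5, seed=2,
        feature_columns=["f0", "f1", "f2", "f3"], n_boot=100, importance_repeats=5,
    )
    assert 0.3 <= rep.auc <= 0.7
    assert rep.roc.ci_low <= rep.auc <= rep.roc.ci_high


def test_nested_cv_deterministic():
    rng = np.random.default_rng(7)
    df = synthetic_table(10, rng)
    kw = dict(outer_folds=4, seed=3, feature_columns=["f0", "f1", "f2", "f3"],
              n_boot=50, importance_repeats=3)
    a = nested_cv_classify(df, "moderate_vs_control", **kw)
    b = nested_cv_classify(df, "moderate_vs_control", **kw)
    np.testing.assert_array_equal(a.oof_scores, b.oof_scores)
    assert a.fold_params == b.fold_params
    assert a.roc.ci_low == b.roc.ci_low


def test_permutation_importance_constant_feature_is_null():
    from sklearn.ensemble import RandomForestClassifier

    rng = np.random.default_rng(8)
    X = rng.normal(size=(120, 3))
    y = (X[:, 0] > 0).astype(int)
    X[:, 2] = 1.0  # constant column
    model = RandomForestClassifier(n_estimators=100, random_state=0).fit(X[:80], y[:80])
    imp = permutation_importance([(model, np.arange(80, 120))], X, y,
                                 n_repeats=10, seed=0, feature_names=["a", "b", "c"])
    assert imp["c"] == pytest.approx(0.0, abs=1e-12)
    assert imp.index[0] == "a"
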