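"""Statistical machinery: BH, rank tests, selectors, ROC, LDA, qPCR."""

import numpy as np
import pandas as pd
import pytest

from pgcglycomics.stats import (
    GlmnetSelector,
    OOBPermutationForestSelector,
    WilksLda,
    benjamini_hochberg,
    differential_table,
    differential_test,
    lda,
    normalize_gene_expression,
    panel_scores,
    roc,
)


def profile_frame(arr, groups):
    idx = [f"s{i}" for i in range(len(arr))]
    return (
        pd.DataFrame(arr, index=idx, columns=[f"g{j}" for j in range(arr.shape[1])]),
        pd.Series(groups, index=idx),
    )


# -- BH ---------------------------------------------------------------------

def test_bh_hand_computed_step_up():
    """Step-up on p = {.001,.01,.02,.04,.05}, m = 5."""
    adjusted = benjamini_hochberg([0.001, 0.01, 0.02, 0.04, 0.05])
    assert adjusted == pytest.approx([0.005, 0.025, 1 / 30, 0.05, 0.05], abs=1e-9)


def test_bh_monotone_and_bounded():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=40)
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# -- differential test ------------------------------------------------------

def test_identical_groups_not_significant():
    rng = np.random.default_rng(1)
    block = rng.uniform(1, 5, size=(14, 6))
    data = np.vstack([block, block])
    df, groups = profile_frame(data, ["OC"] * 14 + ["PC"] * 14)
    results = differential_test(df, groups)
    assert all(r.p > 0.9 for r in results)


def test_constant_feature_flagged():
    data = np.column_stack([np.ones(12), np.random.default_rng(2).normal(size=12)])
    df, groups = profile_frame(data, ["A"] * 6 + ["B"] * 6)
    results = differential_test(df, groups)
    assert results[0].constant and results[0].p == 1.0


def test_shifted_glycan_attains_smallest_p_adj():
    """A 2-pooled-SD shift on one glycan (n = 14/14) ranks first in >= 95%
    of 200 seeds."""
    wins = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        data = rng.normal(10.0, 1.0, size=(28, 8))
        data[14:, 3] += 2.0
        df, groups = profile_frame(data, ["OC"] * 14 + ["PC"] * 14)
        results = differential_test(df, groups)
        best = min(results, key=lambda r: (r.p_adj, r.p))
        wins += best.glycan_id == "g3"
    assert wins / 200 >= 0.95


def test_three_group_kruskal_direction():
    rng = np.random.default_rng(3)
    data = rng.normal(5.0, 0.5, size=(20, 3))
    data[:7, 0] += 4.0
    groups = ["ovary"] * 7 + ["omentum"] * 7 + ["peritoneum"] * 6
    df, gs = profile_frame(data, groups)
    results = differential_test(df, gs)
    assert results[0].p < 0.01 and results[0].direction == "up_ovary"


def test_differential_table_columns():
    rng = np.random.default_rng(4)
    df, groups = profile_frame(rng.normal(size=(12, 2)), ["A"] * 6 + ["B"] * 6)
    table = differential_table(differential_test(df, groups))
    assert {"glycan_id", "p", "p_adj", "mean_A", "sd_B"} <= set(table.columns)


# -- selectors --------------------------------------------------------------

def test_glm_selects_separating_feature():
    """A perfectly separating feature among noise is selected in >= 95% of
    100 seeds."""
    wins = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(28, 10))
        y = np.array([0] * 14 + [1] * 14)
        X[:, 4] = y * 3.0 + rng.normal(0, 0.2, size=28)
        sel = GlmnetSelector(seed=seed).fit(X, y)
        wins += bool(sel.support_[4])
    assert wins / 100 >= 0.95


def test_glm_requires_two_classes():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError):
        GlmnetSelector().fit(X, np.zeros(10))


def test_rf_null_importances_centered_at_zero():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 8))
    y = rng.integers(0, 2, size=30)
    sel = OOBPermutationForestSelector(n_trees=300, seed=0).fit(X, y)
    assert abs(np.mean(sel.importances_)) < 0.02


def test_rf_planted_feature_ranked_first():
    """A 2-SD planted feature has the top importance in >= 90% of seeds."""
    wins = 0
    n_seeds = 60
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(28, 8))
        y = np.array([0] * 14 + [1] * 14)
        X[:, 2] += y * 2.0
        sel = OOBPermutationForestSelector(n_trees=300, seed=seed).fit(X, y)
        wins += sel.ranking_[0] == 2
    assert wins / n_seeds >= 0.90


def test_rf_seeded_run_reproducible():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(24, 6))
    y = np.array([0, 1] * 12)
    a = OOBPermutationForestSelector(n_trees=100, seed=5).fit(X, y)
    b = OOBPermutationForestSelector(n_trees=100, seed=5).fit(X, y)
    assert np.array_equal(a.importances_, b.importances_)


def test_rf_few_trees_warns():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(20, 4))
    y = np.array([0, 1] * 10)
    with pytest.warns(UserWarning):
        OOBPermutationForestSelector(n_trees=10, seed=0).fit(X, y)


# -- ROC --------------------------------------------------------------------

def test_perfect_separation_auc_1():
    scores = np.concatenate([np.zeros(5), np.ones(5)])
    labels = np.array(["neg"] * 5 + ["pos"] * 5)
    rr = roc(scores, labels, positive="pos")
    assert rr.auc == pytest.approx(1.0)
    assert rr.sensitivity == pytest.approx(100.0)
    assert rr.specificity == pytest.approx(100.0)


def test_auc_equals_u_statistic_oracle():
    """AUC = (pairwise wins + half ties) / (n1*n2) on 100 random instances."""
    rng = np.random.default_rng(12)
    for _ in range(100):
        n1, n2 = rng.integers(5, 20, size=2)
        pos = rng.normal(rng.uniform(0, 1), 1.0, size=n1)
        neg = rng.normal(0.0, 1.0, size=n2)
        scores = np.concatenate([neg, pos])
        labels = np.array([0] * n2 + [1] * n1)
        u = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        rr = roc(scores, labels, positive=1)
        assert rr.auc == pytest.approx(u / (n1 * n2), abs=1e-9)


def test_table1_operating_point_arithmetic():
    """15 vs 13 with 2 missed positives and 1 false positive at the chosen
    threshold gives sensitivity 86.7% and specificity 92.3%."""
    # positives: 13 high scores + 2 low; negatives: 12 low + 1 high
    scores = np.concatenate([
        np.full(13, 2.0), [0.4, 0.3],        # positives
        np.full(12, 0.5), [2.5],             # negatives
    ])
    labels = np.array([1] * 15 + [0] * 13)
    rr = roc(scores, labels, positive=1)
    assert rr.sensitivity == pytest.approx(100 * 13 / 15, abs=1e-6)
    assert rr.specificity == pytest.approx(100 * 12 / 13, abs=1e-6)


def test_roc_single_class_errors():
    with pytest.raises(ValueError):
        roc([1, 2, 3], ["A", "A", "A"])


def test_panel_scores_improve_separation():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(28, 4))
    y = np.array(["PC"] * 14 + ["OC"] * 14)
    X[14:, 0] += 1.2
    X[14:, 1] += 1.2
    df = pd.DataFrame(X, index=[f"s{i}" for i in range(28)],
                      columns=list("abcd"))
    groups = pd.Series(y, index=df.index)
    combo = roc(panel_scores(df, groups, ["a", "b"], positive="OC"),
                groups, positive="OC")
    single = roc(df["a"], groups, positive="OC")
    assert combo.auc >= single.auc


# -- LDA / Wilks ------------------------------------------------------------

def wilks_oracle(X, y):
    X = np.asarray(X, float)
    W = np.zeros((X.shape[1],) * 2)
    for cls in np.unique(y):
        Xc = X[y == cls]
        dev = Xc - Xc.mean(axis=0)
        W += dev.T @ dev
    dev = X - X.mean(axis=0)
    T = dev.T @ dev
    return np.linalg.det(W) / np.linalg.det(T)


def test_wilks_identical_means_near_one():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(40, 3))
    y = np.array([0, 1] * 20)
    model = WilksLda().fit(X, y)
    assert model.wilks_lambda_ > 0.8
    assert model.p_value_ > 0.1


def test_wilks_full_separation_near_zero():
    X = np.concatenate([np.zeros(10), np.ones(10)])[:, None]
    X = X + np.random.default_rng(15).normal(0, 0.01, size=X.shape)
    y = np.array([0] * 10 + [1] * 10)
    model = WilksLda().fit(X, y)
    assert model.wilks_lambda_ < 0.01


def test_wilks_matches_det_ratio_oracle():
    rng = np.random.default_rng(16)
    for _ in range(20):
        n = int(rng.integers(15, 30))
        p = int(rng.integers(1, 4))
        g = int(rng.integers(2, 4))
        X = rng.normal(size=(n, p))
        y = rng.integers(0, g, size=n)
        if len(np.unique(y)) < 2:
            continue
        model = WilksLda().fit(X, y)
        assert model.wilks_lambda_ == pytest.approx(wilks_oracle(X, y), rel=1e-8)


def test_wilks_matches_statsmodels_manova():
    """Independent cross-check against statsmodels MANOVA."""
    from statsmodels.multivariate.manova import MANOVA

    rng = np.random.default_rng(17)
    X = rng.normal(size=(30, 3))
    y = np.repeat(["a", "b", "c"], 10)
    X[10:20] += 0.8
    model = WilksLda().fit(X, y)
    frame = pd.DataFrame(X, columns=["x1", "x2", "x3"])
    frame["grp"] = y
    mv = MANOVA.from_formula("x1 + x2 + x3 ~ grp", data=frame)
    stat = mv.mv_test().results["grp"]["stat"]
    assert model.wilks_lambda_ == pytest.approx(
        float(stat.loc["Wilks' lambda", "Value"]), rel=1e-6
    )
    assert model.p_value_ == pytest.approx(
        float(stat.loc["Wilks' lambda", "Pr > F"]), rel=1e-4
    )


def test_lda_wrapper_projections_shape():
    rng = np.random.default_rng(18)
    df = pd.DataFrame(rng.normal(size=(28, 4)), index=[f"s{i}" for i in range(28)],
                      columns=list("abcd"))
    groups = pd.Series(["x"] * 14 + ["y"] * 7 + ["z"] * 7, index=df.index)
    res = lda(df, groups)
    assert res.projections.shape == (28, 2)
    assert 0 < res.wilks_lambda <= 1


# -- qPCR normalization -----------------------------------------------------

def test_qpcr_identical_samples_all_one():
    cq = pd.DataFrame(
        {"s1": [20.0, 21.0, 22.0, 25.0], "s2": [20.0, 21.0, 22.0, 25.0]},
        index=["ref1", "ref2", "ref3", "target"],
    )
    rel = normalize_gene_expression(cq, ["ref1", "ref2", "ref3"])
    assert np.allclose(rel.loc["target"], 1.0)


def test_qpcr_one_cycle_doubles_expression():
    cq = pd.DataFrame(
        {"s1": [20.0, 20.0, 20.0, 25.0], "s2": [20.0, 20.0, 20.0, 24.0]},
        index=["ref1", "ref2", "ref3", "target"],
    )
    rel = normalize_gene_expression(cq, ["ref1", "ref2", "ref3"])
    assert rel.loc["target", "s1"] == pytest.approx(1.0)
    assert rel.loc["target", "s2"] == pytest.approx(2.0)


def test_qpcr_missing_reference_errors():
    cq = pd.DataFrame({"s1": [20.0, 25.0]}, index=["ref1", "target"])
    with pytest.raises(ValueError):
        normalize_gene_expression(cq, ["ref1", "ref2", "ref3"])


def test_qpcr_fold_change_recovery_under_noise():
    """Simulated fold changes recovered within 5% under Cq noise sd 0.1
    (100 replicates)."""
    rng = np.random.default_rng(19)
    true_fold = 4.0  # two cycles
    ratios = []
    for _ in range(100):
        base = 25.0
        cq = pd.DataFrame(
            {
                "low": np.concatenate([20 + rng.normal(0, 0.1, 3), [base]]),
                "high": np.concatenate(
                    [20 + rng.normal(0, 0.1, 3), [base - np.log2(true_fold)]]
                ),
            },
            index=["ref1", "ref2", "ref3", "target"],
        )
        rel = normalize_gene_expression(cq, ["ref1", "ref2", "ref3"])
        ratios.append(rel.loc["target", "high"] / rel.loc["target", "low"])
    assert np.mean(ratios) == pytest.approx(true_fold, rel=0.05)
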