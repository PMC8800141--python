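"""Tree estimators: CART pruning, CTree tests, CHAID merging, random forest."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intersectprev import (
    fit_cart,
    fit_chaid,
    fit_ctree,
    fit_random_forest,
    predict_tree_intersections,
)
from intersectprev.config import InputType
from intersectprev.trees.chaid import bonferroni_multiplier, merge_categories
from intersectprev.trees.ctree import _best_subset_split


def _frame(rng, n, p_fn):
    df = pd.DataFrame({
        "x1": rng.integers(0, 4, n), "x2": rng.integers(0, 2, n),
        "x3": rng.integers(0, 2, n), "x4": rng.integers(0, 2, n),
        "x5": rng.integers(0, 2, n), "x6": rng.integers(0, 3, n),
    })
    df["y"] = (rng.random(n) < p_fn(df)).astype(int)
    df["intersection_id"] = 0
    return df


# ---------------------------------------------------------------- CART


def test_cart_single_perfect_separator(rng):
    df = _frame(rng, 2000, lambda d: (d["x3"] == 1).astype(float))
    model = fit_cart(df)
    assert model.variables_used == {"x3"}
    assert model.root.split_var == "x3"
    leaves = model.root.children
    assert {round(c.event_rate, 6) for c in leaves} == {0.0, 1.0}


def test_cart_prunes_to_root_on_noise(rng):
    df = _frame(rng, 1500, lambda d: np.full(len(d), 0.05))
    model = fit_cart(df)
    assert model.variables_used == set()
    assert model.root.is_leaf
    est = predict_tree_intersections(model, _DS(df))
    assert np.allclose(est.estimates.dropna(), df["y"].mean())


def test_cart_cv_selects_from_pruning_path(rng):
    df = _frame(rng, 1200,
                lambda d: 0.1 + 0.4 * (d["x3"] == 1) + 0.2 * (d["x2"] == 1))
    model = fit_cart(df, random_state=3)
    errs = np.array(model.tuning["cv_errors"])
    alphas = np.array(model.tuning["candidate_alphas"])
    chosen = model.tuning["ccp_alpha"]
    best = errs.min()
    # the selected penalty attains the minimal CV error, largest on ties
    attaining = alphas[errs <= best + 1e-12]
    assert chosen == pytest.approx(attaining.max())
    # refitting with the same seed reproduces the choice
    again = fit_cart(df, random_state=3)
    assert again.tuning["ccp_alpha"] == pytest.approx(chosen)


# ---------------------------------------------------------------- CTree


def test_ctree_always_splits_strong_predictor(rng):
    df = _frame(rng, 10000,
                lambda d: 0.1 + 0.5 * (d["x4"] == 1))
    model = fit_ctree(df, input_type=InputType.CATEGORICAL)
    assert model.root.split_var == "x4"


def test_ctree_null_familywise_error_near_alpha():
    """No real signal: a root split happens in at most ~alpha of replicates."""
    rng = np.random.default_rng(17)
    hits = 0
    reps = 300
    for _ in range(reps):
        df = _frame(rng, 400, lambda d: np.full(len(d), 0.3))
        hits += bool(fit_ctree(df, input_type=InputType.CATEGORICAL).variables_used)
    rate = hits / reps
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


def test_ctree_best_subset_matches_brute_force(rng):
    x = rng.integers(0, 4, 600)
    y = (rng.random(600) < 0.2 + 0.3 * (x == 2)).astype(int)
    subset, stat = _best_subset_split(x, y, minbucket=7)
    # brute force over all 7 binary partitions of 4 levels
    best = (-np.inf, None)
    for mask in range(1, 8):
        left = {l for l in range(4) if (mask >> l) & 1}
        n_l = np.isin(x, list(left)).sum()
        if min(n_l, len(x) - n_l) < 7:
            continue
        table = pd.crosstab(np.isin(x, list(left)), y).to_numpy()
        s = stats.chi2_contingency(table, correction=False)[0]
        if s > best[0]:
            best = (s, frozenset(left))
    assert stat == pytest.approx(best[0])
    assert subset in (best[1], frozenset(range(4)) - best[1])


def test_ctree_continuous_threshold(rng):
    n = 4000
    x1 = rng.standard_normal(n)
    df = pd.DataFrame({
        "x1": x1, "x2": rng.integers(0, 2, n), "x3": rng.integers(0, 2, n),
        "x4": rng.integers(0, 2, n), "x5": rng.integers(0, 2, n),
        "x6": rng.standard_normal(n),
    })
    df["y"] = (rng.random(n) < np.where(x1 > 0.5, 0.6, 0.2)).astype(int)
    model = fit_ctree(df, input_type=InputType.MIXED)
    assert model.root.split_var == "x1"
    assert model.root.split_kind == "threshold"
    assert model.root.threshold == pytest.approx(0.5, abs=0.15)


# ---------------------------------------------------------------- CHAID


def test_chaid_merges_identical_categories(rng):
    x = rng.integers(0, 3, 3000)
    # categories 0 and 1 share an event rate; 2 differs
    y = (rng.random(3000) < np.where(x == 2, 0.5, 0.2)).astype(int)
    groups, p_adj = merge_categories(x, y)
    assert sorted(map(sorted, groups)) == [[0, 1], [2]]
    assert p_adj < 0.05


def test_chaid_hand_computed_chi_square_accepts_split():
    """A 2x2 node table with chi-square p below alpha yields a split."""
    x = np.repeat([0, 1], 100)
    y = np.concatenate([np.ones(50), np.zeros(50), np.ones(30), np.zeros(70)])
    # hand chi-square: n(ad-bc)^2 / (r1 r2 c1 c2)
    stat = 200 * (50 * 70 - 50 * 30) ** 2 / (100 * 100 * 80 * 120)
    p_hand = float(stats.chi2.sf(stat, 1))
    assert p_hand < 0.05
    df = pd.DataFrame({
        "x1": x, "x2": 0, "x3": 0, "x4": 0, "x5": 0, "x6": 0,
        "y": y.astype(int), "intersection_id": 0,
    })
    model = fit_chaid(df)
    assert model.root.split_var == "x1"
    assert model.root.p_value == pytest.approx(p_hand, rel=1e-6)


def test_chaid_refuses_continuous_inputs(rare_mixed_mid):
    with pytest.raises(ValueError, match="categorical"):
        fit_chaid(rare_mixed_mid)


def test_chaid_bonferroni_multiplier_enumeration():
    """Kass multiplier equals brute-force enumeration of set partitions."""
    from itertools import product as iproduct

    def brute(c, r):
        count = 0
        for assign in iproduct(range(r), repeat=c):
            if len(set(assign)) == r:
                count += 1
        import math

        return count // math.factorial(r)

    for c in range(2, 6):
        for r in range(2, c + 1):
            assert bonferroni_multiplier(c, r) == pytest.approx(brute(c, r))


def test_chaid_greedy_merge_never_merges_significant_pair(rng):
    """On enumerable 3-category data the merged pair is the least distinct."""
    for _ in range(20):
        x = rng.integers(0, 3, 400)
        y = (rng.random(400) < 0.15 + 0.1 * x).astype(int)
        groups, _ = merge_categories(x, y)
        if len(groups) == 3:
            continue
        merged = next(g for g in groups if len(g) > 1)
        rates = {l: y[x == l].mean() for l in range(3)}
        pairs = [(abs(rates[a] - rates[b]), {a, b})
                 for a, b in [(0, 1), (0, 2), (1, 2)]]
        # the greedily merged pair is never the most-different pair
        most_different = max(pairs)[1]
        if len(merged) == 2:
            assert set(merged) != most_different


# ---------------------------------------------------------- random forest


def test_forest_constant_feature_has_zero_importance(rng):
    df = _frame(rng, 800, lambda d: 0.2 + 0.3 * (d["x3"] == 1))
    df["x6"] = 1
    model, vim = fit_random_forest(df, n_trees=60, n_permutations=0, seed=0)
    assert vim.impurity_vim["x6"] == 0.0
    assert "x6" not in model.variables_used


def test_forest_dominant_predictor_tops_impurity_vim():
    wins = 0
    for seed in range(8):
        rng = np.random.default_rng(seed)
        df = _frame(rng, 800, lambda d: 0.1 + 0.6 * (d["x4"] == 1))
        _, vim = fit_random_forest(df, n_trees=60, n_permutations=0, seed=seed)
        wins += vim.impurity_vim.idxmax() == "x4"
    assert wins >= 7


def test_forest_oob_tuning_selects_minimum(rng):
    df = _frame(rng, 600, lambda d: 0.2 + 0.2 * (d["x2"] == 1))
    model, _ = fit_random_forest(df, n_trees=40, n_permutations=0, seed=2)
    oob = model.tuning["oob_brier"]
    assert oob[model.tuning["mtry"]] == min(oob.values())


def test_forest_permutation_pvalues_flag_signal_not_noise(rng):
    n = 1200
    df = pd.DataFrame({
        "x1": rng.standard_normal(n), "x2": rng.integers(0, 2, n),
        "x3": rng.integers(0, 2, n), "x4": rng.integers(0, 2, n),
        "x5": rng.integers(0, 2, n), "x6": rng.standard_normal(n),
    })
    df["y"] = (rng.random(n) < 0.15 + 0.45 * (df["x3"] == 1)).astype(int)
    df["intersection_id"] = 0
    _, vim = fit_random_forest(df, n_trees=40, n_permutations=30, seed=4)
    p = vim.permutation_vim["p_value"]
    assert p["x3"] < 0.05
    assert p["x6"] > 0.05  # continuous null variable stays non-significant


def test_ensemble_predictions_in_unit_interval(rng):
    df = _frame(rng, 500, lambda d: 0.1 + 0.2 * (d["x2"] == 1))
    model, _ = fit_random_forest(df, n_trees=30, n_permutations=0, seed=1)
    est = predict_tree_intersections(model, _DS(df))
    vals = est.estimates.dropna()
    assert ((vals >= 0) & (vals <= 1)).all()


def test_deep_tree_reproduces_cross_classification(rng):
    """A partition that isolates intersections equals the raw proportions."""
    from intersectprev import cross_classify

    df = _frame(rng, 5000, lambda d: 0.05 + 0.3 * (d["x3"] == 1)
                * (d["x4"] == 1))
    df["intersection_id"] = (df["x3"] * 2 + df["x4"]).astype(int)
    model = fit_ctree(df, input_type=InputType.CATEGORICAL, alpha=1.0,
                      minsplit=2, minbucket=1, max_depth=4,
                      features=["x3", "x4"], continuous=set())
    est = predict_tree_intersections(model, _DS(df))
    cc = cross_classify(df).estimates.reindex(est.estimates.index)
    pd.testing.assert_series_equal(est.estimates, cc, atol=1e-12,
                                   check_names=False)


class _DS:
    def __init__(self, df):
        self.data = df
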