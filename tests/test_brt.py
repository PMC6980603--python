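"""Boosted regression tree core: loss, trees, boosting, interpretation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from windstrike.brt import (
    BRTConfig,
    BRTModel,
    RegressionTree,
    bernoulli_deviance,
    boost,
    evaluate,
    fit_tree,
    gbm_step,
    interaction_size,
    model_from_json,
    model_to_json,
    partial_dependence,
    predict,
    relative_influence,
    roc_auc,
    simplify,
)


def make_leaf_tree(value):
    return RegressionTree(
        feature=np.array([-1]),
        threshold=np.array([np.nan]),
        left=np.array([-1]),
        right=np.array([-1]),
        value=np.array([float(value)]),
        improvement=np.array([0.0]),
    )


def make_stump(feature, threshold, left_value, right_value, improvement=1.0):
    return RegressionTree(
        feature=np.array([feature, -1, -1]),
        threshold=np.array([threshold, np.nan, np.nan]),
        left=np.array([1, -1, -1]),
        right=np.array([2, -1, -1]),
        value=np.array([0.0, left_value, right_value]),
        improvement=np.array([improvement, 0.0, 0.0]),
    )


def toy_model(trees, var_names=("x0", "x1"), intercept=0.0, lr=0.5, X=None):
    if X is None:
        X = np.array([[-1.0, -1.0], [1.0, 1.0], [2.0, -2.0], [-2.0, 2.0]])
    return BRTModel(
        intercept=intercept,
        trees=trees,
        lr=lr,
        nt=len(trees),
        var_names=tuple(var_names),
        config=BRTConfig(tc=1),
        metadata={"X": X, "y": np.array([0, 1, 1, 0])},
    )


class TestBernoulliDeviance:
    def test_half_probability_closed_form(self):
        assert bernoulli_deviance([0, 1, 0, 1], [0.5] * 4) == pytest.approx(
            -2 * np.log(0.5), abs=1e-12
        )

    def test_perfect_clamped_predictions_near_zero(self):
        with pytest.warns(UserWarning, match="clamped"):
            d = bernoulli_deviance([0, 1], [0.0, 1.0])
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        p = rng.uniform(0.01, 0.99, 100)
        oracle = -2 * sum(
            yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for yi, pi in zip(y, p)
        ) / len(y)
        assert bernoulli_deviance(y, p) == pytest.approx(oracle, rel=1e-12)


class TestFitTree:
    def test_zero_residuals_give_single_leaf_value_zero(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]] * 10)
        r = np.zeros(40)
        h = np.full(40, 0.25)
        tree = fit_tree(X, r, np.arange(40), tc=3, min_node=2, hessian=h)
        assert tree.n_splits == 0
        assert tree.value[0] == 0.0

    def test_constant_features_give_single_leaf(self):
        X = np.ones((40, 3))
        r = np.random.default_rng(1).normal(size=40)
        tree = fit_tree(X, r, np.arange(40), tc=3, min_node=2)
        assert tree.n_splits == 0

    def test_binary_informative_feature_found_by_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        n = 60
        X = rng.normal(size=(n, 3))
        X[:, 1] = np.where(np.arange(n) < 30, -2.0, 2.0)
        r = np.where(np.arange(n) < 30, -1.0, 1.0) + rng.normal(0, 0.01, n)

        # oracle: exhaustive scan of every (feature, midpoint) split
        best = (-np.inf, None, None)
        for j in range(3):
            xs = np.sort(np.unique(X[:, j]))
            for a, b in zip(xs[:-1], xs[1:]):
                t = (a + b) / 2
                left = X[:, j] <= t
                if left.sum() < 5 or (~left).sum() < 5:
                    continue
                gain = (
                    r[left].sum() ** 2 / left.sum()
                    + r[~left].sum() ** 2 / (~left).sum()
                    - r.sum() ** 2 / n
                )
                if gain > best[0]:
                    best = (gain, j, t)

        tree = fit_tree(X, r, np.arange(n), tc=1, min_node=5)
        assert tree.feature[0] == best[1] == 1
        assert tree.threshold[0] == pytest.approx(best[2])
        assert tree.improvement[0] == pytest.approx(best[0])

    def test_split_count_bounded_by_tc(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 5))
        r = rng.normal(size=200)
        for tc in (1, 3, 7):
            tree = fit_tree(X, r, np.arange(200), tc=tc, min_node=5)
            assert tree.n_splits <= tc


class TestBoost:
    @staticmethod
    def separable_data(n=200, seed=4):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 1))
        y = (x[:, 0] > 0).astype(int)
        return x, y

    def test_intercept_only_predicts_prevalence(self):
        X, y = self.separable_data()
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, bf=1.0, seed=0), nt_fixed=0)
        p = predict(model, X)
        assert np.allclose(p, y.mean())

    def test_full_bag_training_deviance_decreases(self):
        X, y = self.separable_data()
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, bf=1.0, seed=0), nt_fixed=50)
        devs = []
        link = np.full(len(y), model.intercept)
        devs.append(bernoulli_deviance(y, expit(link)))
        for tree in model.trees:
            link = link + model.lr * tree.predict(X)
            devs.append(bernoulli_deviance(y, expit(link)))
        assert all(b < a for a, b in zip(devs, devs[1:]))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(ValueError, match="single class"):
            boost((X, np.ones(30)), BRTConfig(tc=1), nt_fixed=5)

    def test_same_seed_identical_model(self):
        X, y = self.separable_data()
        cfg = BRTConfig(tc=2, lr=0.1, bf=0.5, seed=7)
        a = boost((X, y), cfg, nt_fixed=20)
        b = boost((X, y), cfg, nt_fixed=20)
        assert np.allclose(predict(a, X, "link"), predict(b, X, "link"))


class TestPredict:
    def test_probability_in_open_interval(self):
        X, y = TestBoost.separable_data()
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, seed=1), nt_fixed=30)
        p = predict(model, X)
        assert ((p > 0) & (p < 1)).all()

    def test_matches_manual_traversal_on_two_tree_model(self):
        t1 = make_stump(0, 0.0, -1.0, 1.0)
        t2 = make_stump(1, 0.5, 0.2, -0.4)
        model = toy_model([t1, t2], intercept=0.3, lr=0.5)
        X = np.array([[-1.0, 0.0], [1.0, 1.0]])
        # manual: intercept + lr * (tree1 + tree2)
        expected = 0.3 + 0.5 * np.array([(-1.0) + 0.2, 1.0 + (-0.4)])
        assert np.allclose(predict(model, X, "link"), expected)
        assert np.allclose(predict(model, X), expit(expected))

    def test_missing_column_named(self):
        model = toy_model([make_stump(0, 0.0, -1.0, 1.0)])
        df = pd.DataFrame({"x0": [0.0]})
        with pytest.raises(KeyError, match="x1"):
            predict(model, df)


class TestRelativeInfluence:
    def test_sums_to_hundred(self):
        X, y = TestBoost.separable_data()
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, seed=2), nt_fixed=30)
        assert relative_influence(model).sum() == pytest.approx(100.0, abs=1e-6)

    def test_unsplit_variable_has_zero_influence(self):
        t = make_stump(0, 0.0, -1.0, 1.0)
        model = toy_model([t])
        infl = relative_influence(model)
        assert infl["x0"] == pytest.approx(100.0)
        assert infl["x1"] == 0.0

    def test_informative_variable_dominates_noise(self):
        rng = np.random.default_rng(5)
        n = 400
        X = rng.normal(0, 1, size=(n, 12))
        y = (X[:, 3] + rng.normal(0, 0.3, n) > 0).astype(int)
        model = boost((X, y), BRTConfig(tc=3, lr=0.05, seed=5), nt_fixed=100)
        infl = relative_influence(model)
        assert infl["x3"] > 50.0

    def test_intercept_only_model_rejected(self):
        model = toy_model([make_leaf_tree(0.0)])
        with pytest.raises(ValueError, match="no splits"):
            relative_influence(model)

    def test_permutation_equivariance_under_column_reordering(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 4))
        y = (X[:, 0] + 0.5 * X[:, 2] + rng.normal(0, 0.5, 300) > 0).astype(int)
        cfg = BRTConfig(tc=3, lr=0.05, bf=1.0, seed=6)
        a = relative_influence(boost((X, y, ("a", "b", "c", "d")), cfg, 60))
        perm = [2, 0, 3, 1]
        b = relative_influence(
            boost((X[:, perm], y, ("c", "a", "d", "b")), cfg, 60)
        )
        for name in "abcd":
            assert a[name] == pytest.approx(b[name], abs=1e-9)


class TestPartialDependence:
    def test_intercept_only_model_is_flat(self):
        model = toy_model([make_leaf_tree(0.0)], intercept=0.7)
        curve = partial_dependence(model, "x0", n_grid=10)
        assert np.allclose(curve.values, 0.7)

    def test_single_stump_gives_step_at_threshold(self):
        model = toy_model([make_stump(0, 0.0, -1.0, 1.0)], lr=1.0)
        curve = partial_dependence(model, "x0", n_grid=50)
        below = curve.grid <= 0.0
        assert np.allclose(curve.values[below], -1.0)
        assert np.allclose(curve.values[~below], 1.0)

    def test_invariant_to_training_row_order(self):
        X, y = TestBoost.separable_data()
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, seed=3), nt_fixed=20)
        a = partial_dependence(model, "x0", n_grid=20)
        model.metadata["X"] = model.metadata["X"][::-1].copy()
        b = partial_dependence(model, "x0", n_grid=20)
        assert np.allclose(a.values, b.values)

    def test_unknown_variable_rejected(self):
        model = toy_model([make_stump(0, 0.0, -1.0, 1.0)])
        with pytest.raises(KeyError, match="zz"):
            partial_dependence(model, "zz")


class TestInteractionSize:
    def test_additive_model_has_zero_interaction(self):
        trees = [make_stump(0, 0.0, -1.0, 1.0), make_stump(1, 0.0, 0.5, -0.5)]
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 2))
        model = toy_model(trees, X=X)
        assert interaction_size(model, "x0", "x1", grid_size=8) < 1e-6

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 3))
        y = ((X[:, 0] * X[:, 1] > 0) ^ (rng.random(200) < 0.1)).astype(int)
        model = boost((X, y), BRTConfig(tc=3, lr=0.1, seed=9), nt_fixed=60)
        names = model.var_names
        a = interaction_size(model, names[0], names[1], grid_size=8)
        b = interaction_size(model, names[1], names[0], grid_size=8)
        assert a == pytest.approx(b, rel=1e-9)

    def test_same_variable_rejected(self):
        model = toy_model([make_stump(0, 0.0, -1.0, 1.0)])
        with pytest.raises(ValueError, match="distinct"):
            interaction_size(model, "x0", "x0")

    def test_product_effect_pair_beats_noise_pairs(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 200
            X = rng.normal(size=(n, 4))
            z = 2.0 * X[:, 0] * X[:, 1]
            y = (rng.random(n) < expit(z)).astype(int)
            model = boost(
                (X, y), BRTConfig(tc=3, lr=0.1, bf=0.7, seed=seed), nt_fixed=120
            )
            names = model.var_names
            driver = interaction_size(model, names[0], names[1], grid_size=8)
            noise = interaction_size(model, names[2], names[3], grid_size=8)
            hits += driver > noise
        assert hits >= 8


class TestGbmStepAndSimplify:
    def test_too_few_rows_rejected(self):
        X = np.random.default_rng(0).normal(size=(3, 2))
        y = np.array([0, 1, 0])
        with pytest.raises(ValueError, match="too few"):
            gbm_step((X, y), BRTConfig(k_folds=2))

    def test_noise_labels_give_near_null_cv_deviance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(200, 4))
        y = rng.integers(0, 2, 200)
        cfg = BRTConfig(
            tc=2, bf=0.5, k_folds=5, lr_candidates=(0.01,), min_trees=1,
            step_size=25, max_trees=300, seed=12,
        )
        model = gbm_step((X, y), cfg)
        null = bernoulli_deviance(y, np.full(200, y.mean()))
        assert model.metadata["cv_deviance"] <= null * 1.05

    def test_max_drop_must_leave_variables(self):
        X = np.random.default_rng(0).normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, seed=1), nt_fixed=20)
        with pytest.raises(ValueError, match="max_drop"):
            simplify(model, (X, y), max_drop=3)

    def test_zero_drop_keeps_variable_set(self):
        X = np.random.default_rng(0).normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, seed=1), nt_fixed=20)
        simplified, report = simplify(model, (X, y), max_drop=0)
        assert simplified.var_names == model.var_names
        assert len(report) == 0


class TestEvaluate:
    def test_perfect_ranking_gives_auc_one(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_auc_matches_concordance_oracle(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 50)
        s = np.round(rng.uniform(0, 1, 50), 1)  # ties on purpose
        pos = s[y == 1]
        neg = s[y == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(y, s) == pytest.approx(conc / (len(pos) * len(neg)))

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(15)
        y = rng.integers(0, 2, 200)
        s = np.round(rng.uniform(0, 1, 200), 2)
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_independent_labels_give_chance_auc(self):
        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, 2000)
        s = rng.uniform(0, 1, 2000)
        assert 0.45 <= roc_auc(y, s) <= 0.55

    def test_single_class_heldout_rejected(self):
        X, y = TestBoost.separable_data()
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, seed=3), nt_fixed=10)
        with pytest.raises(ValueError, match="single class"):
            evaluate(model, (X[:5], np.ones(5)))

    def test_youden_threshold_separates_separable_data(self):
        X, y = TestBoost.separable_data()
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, bf=1.0, seed=3), nt_fixed=80)
        report = evaluate(model, (X, y))
        assert report.auc > 0.99
        assert report.sensitivity > 0.95
        assert report.one_minus_specificity < 0.05


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        X, y = TestBoost.separable_data()
        model = boost((X, y), BRTConfig(tc=2, lr=0.1, seed=4), nt_fixed=25)
        path = tmp_path / "model.json"
        model_to_json(model, path)
        loaded = model_from_json(path)
        assert loaded.nt == model.nt
        assert np.allclose(predict(loaded, X, "link"), predict(model, X, "link"))
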