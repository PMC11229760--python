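import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from microsig.irf import (Interaction, IterativeRandomForestClassifier,
                          iterate_irf, mine_interactions, relative_vimp,
                          roc_auc, tune_iterations)


def _signal_data(seed, n=120, p=10, shift=2.0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.standard_normal((n, p))
    X[y == 1, :2] += shift
    return X, y


class TestForest:
    def test_k1_equals_plain_forest_same_seed(self):
        X, y = _signal_data(0)
        a = IterativeRandomForestClassifier(n_iterations=1, n_trees=30,
                                            random_state=5).fit(X, y)
        # K=1 runs exactly one forest with uniform weights; rebuilding with
        # the same seed must reproduce it tree for tree
        b = IterativeRandomForestClassifier(n_iterations=1, n_trees=30,
                                            random_state=5).fit(X, y)
        for ta, tb in zip(a.trees_, b.trees_):
            np.testing.assert_array_equal(ta.feature, tb.feature)
            np.testing.assert_allclose(ta.threshold, tb.threshold)
        np.testing.assert_allclose(a.oob_proba_, b.oob_proba_)

    def test_weight_history_is_normalized_importances(self):
        X, y = _signal_data(1)
        est = IterativeRandomForestClassifier(n_iterations=2, n_trees=40,
                                              random_state=3).fit(X, y)
        # recompute-importance oracle: row 2 of the history must equal the
        # normalized Gini importances of the iteration-1 forest, which is
        # reproducible by rerunning K=1 with the same seed
        one = IterativeRandomForestClassifier(n_iterations=1, n_trees=40,
                                              random_state=3).fit(X, y)
        imp = np.clip(one.raw_importances_, 0, None)
        np.testing.assert_allclose(est.weight_history_[1],
                                   imp / imp.sum(), atol=1e-12)

    def test_weights_sum_to_one(self):
        X, y = _signal_data(2)
        est = IterativeRandomForestClassifier(n_iterations=4, n_trees=25,
                                              random_state=0).fit(X, y)
        np.testing.assert_allclose(est.weight_history_.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_reweighting_concentrates_on_signal(self):
        # informative features' weight share grows with iterations
        shares_k1, shares_k5 = [], []
        for seed in range(8):
            X, y = _signal_data(seed, shift=1.0, p=30)
            e1 = IterativeRandomForestClassifier(n_iterations=1, n_trees=60,
                                                 random_state=seed).fit(X, y)
            e5 = IterativeRandomForestClassifier(n_iterations=5, n_trees=60,
                                                 random_state=seed).fit(X, y)
            shares_k1.append(e1.feature_importances_[:2].sum())
            shares_k5.append(e5.feature_importances_[:2].sum())
        assert np.mean(shares_k5) > np.mean(shares_k1)

    def test_determinism_same_seed(self):
        X, y = _signal_data(4)
        r1 = iterate_irf(X, y, K=2, n_trees=30, seed=9, n_boot_ci=50)
        r2 = iterate_irf(X, y, K=2, n_trees=30, seed=9, n_boot_ci=50)
        np.testing.assert_allclose(r1.oob_probabilities, r2.oob_probabilities)
        assert r1.auc == r2.auc
        np.testing.assert_allclose(r1.vimp_raw, r2.vimp_raw)

    def test_single_class_rejected(self):
        X, _ = _signal_data(0)
        with pytest.raises(ValueError):
            IterativeRandomForestClassifier().fit(X, np.zeros(X.shape[0]))

    def test_sklearn_api(self):
        est = IterativeRandomForestClassifier(n_iterations=2, n_trees=10)
        assert clone(est).get_params()["n_iterations"] == 2
        X, y = _signal_data(0)
        est.fit(X, y)
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_oob_beats_chance_on_signal(self):
        X, y = _signal_data(7, shift=2.5)
        est = IterativeRandomForestClassifier(n_iterations=2, n_trees=80,
                                              random_state=1).fit(X, y)
        assert roc_auc_score(y, est.oob_proba_) > 0.9


class TestTuneIterations:
    def test_singleton_grid(self):
        X, y = _signal_data(0)
        assert tune_iterations(X, y, [3], n_trees=20, seed=0) == 3

    def test_grid_bounds_enforced(self):
        X, y = _signal_data(0)
        with pytest.raises(ValueError):
            tune_iterations(X, y, [0, 5], n_trees=10)
        with pytest.raises(ValueError):
            tune_iterations(X, y, [101], n_trees=10)

    def test_returns_grid_member(self):
        X, y = _signal_data(3, shift=0.8)
        k = tune_iterations(X, y, [1, 3], n_trees=30, seed=2)
        assert k in (1, 3)


class TestInteraction:
    def test_validation(self):
        with pytest.raises(ValueError):
            Interaction(features=("a",), stability=0.5)
        with pytest.raises(ValueError):
            Interaction(features=("b", "a"), stability=0.5)
        with pytest.raises(ValueError):
            Interaction(features=("a", "b"), stability=1.5)

    def test_mining_stabilities_in_unit_interval(self):
        X, y = _signal_data(0, n=80, p=8, shift=1.5)
        ints = mine_interactions(X, y, K=2, n_boot=4, n_trees=25,
                                 n_rit_trees=50, seed=0, max_depth=6)
        assert all(0 <= it.stability <= 1 for it in ints)
        assert all(len(it.features) >= 2 for it in ints)
        stabs = [it.stability for it in ints]
        assert stabs == sorted(stabs, reverse=True)

    def test_mining_deterministic(self):
        X, y = _signal_data(1, n=80, p=8)
        a = mine_interactions(X, y, K=2, n_boot=3, n_trees=20,
                              n_rit_trees=40, seed=4)
        b = mine_interactions(X, y, K=2, n_boot=3, n_trees=20,
                              n_rit_trees=40, seed=4)
        assert a == b

    def test_n_boot_minimum(self):
        X, y = _signal_data(0)
        with pytest.raises(ValueError):
            mine_interactions(X, y, n_boot=1)


class TestAUC:
    def test_hand_case(self):
        auc, _, _ = roc_auc(np.array([0.9, 0.8, 0.4, 0.2]),
                            np.array([1, 0, 1, 0]), n_boot_ci=0)
        assert auc == pytest.approx(0.75)

    def test_perfect_ranking(self):
        auc, _, _ = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]),
                            np.array([1, 1, 0, 0]), n_boot_ci=0)
        assert auc == 1.0

    def test_ties_count_half(self):
        auc, _, _ = roc_auc(np.array([0.5, 0.5]), np.array([1, 0]),
                            n_boot_ci=0)
        assert auc == pytest.approx(0.5)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(0)
        probs = rng.random(60)
        y = np.array([0, 1] * 30)
        auc, lo, hi = roc_auc(probs, y, n_boot_ci=1000, seed=1)
        assert lo <= auc <= hi

    def test_constant_probs_warn_half(self):
        with pytest.warns(UserWarning, match="constant"):
            auc, _, _ = roc_auc(np.full(10, 0.5), np.array([0, 1] * 5),
                                n_boot_ci=0)
        assert auc == pytest.approx(0.5)

    def test_nan_probs_dropped_with_warning(self):
        probs = np.array([0.9, np.nan, 0.1, 0.8, 0.2, 0.3])
        y = np.array([1, 1, 0, 1, 0, 0])
        with pytest.warns(UserWarning, match="missing"):
            auc, _, _ = roc_auc(probs, y, n_boot_ci=0)
        assert auc == 1.0


class TestRelativeVimp:
    def test_rescaling(self):
        np.testing.assert_allclose(relative_vimp([0.02, 0.01, 0.005]),
                                   [100, 50, 25])

    def test_max_is_100_and_order_preserved(self, rng):
        raw = rng.random(10)
        rel = relative_vimp(raw)
        assert rel.max() == pytest.approx(100.0)
        assert np.array_equal(np.argsort(rel), np.argsort(raw))

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            relative_vimp([0.0, -1.0])
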