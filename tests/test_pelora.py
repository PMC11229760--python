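import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression

from microsig.pelora import (PeloraClassifier, fit_pelora, fit_ridge_logistic,
                             penalized_nll, tune_penalty)


def _design(cols):
    cols = np.column_stack(cols)
    return np.column_stack([np.ones(cols.shape[0]), cols])


class TestPenalizedNLL:
    def test_zero_beta_gives_n_log2(self):
        y = np.array([1.0, 0, 1, 0, 1])
        X = _design([np.arange(5.0)])
        assert penalized_nll(y, X, np.zeros(2), 3.7) == pytest.approx(
            5 * np.log(2))

    def test_hand_evaluated_case(self):
        # y=(1,0), slope column (1,-1), beta=(0,1), lambda=1:
        # 2*ln(1+e^-1) + 1
        y = np.array([1.0, 0.0])
        X = _design([np.array([1.0, -1.0])])
        val = penalized_nll(y, X, np.array([0.0, 1.0]), 1.0)
        assert val == pytest.approx(2 * np.log(1 + np.exp(-1)) + 1, abs=1e-10)

    def test_strictly_increasing_in_lambda(self):
        y = np.array([1.0, 0, 1, 0])
        X = _design([np.array([0.5, -0.5, 1.0, -1.0])])
        beta = np.array([0.1, 0.8])
        vals = [penalized_nll(y, X, beta, lam) for lam in (0.0, 0.5, 2.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            penalized_nll(np.array([1.0]), _design([np.array([1.0])]),
                          np.zeros(2), -1)


class TestRidgeLogistic:
    def test_huge_lambda_shrinks_to_prevalence(self, rng):
        X = _design([rng.standard_normal(50)])
        y = (rng.random(50) < 0.3).astype(float)
        beta = fit_ridge_logistic(X, y, 1e6)
        assert beta[1] == pytest.approx(0.0, abs=1e-3)
        prev = y.mean()
        assert beta[0] == pytest.approx(np.log(prev / (1 - prev)), abs=1e-3)

    def test_gradient_vanishes_at_optimum(self, rng):
        X = _design([rng.standard_normal(40), rng.standard_normal(40)])
        y = (rng.random(40) < 0.5).astype(float)
        lam = 0.7
        beta = fit_ridge_logistic(X, y, lam)
        # numeric gradient oracle
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            g = (penalized_nll(y, X, beta + e, lam)
                 - penalized_nll(y, X, beta - e, lam)) / (2 * eps)
            assert abs(g) < 1e-4

    def test_one_slope_matches_scalar_brute_force(self, rng):
        x = rng.standard_normal(60)
        y = (rng.random(60) < 1 / (1 + np.exp(-1.2 * x))).astype(float)
        lam = 0.5
        X = _design([x])

        def prof(b1):
            # profile out the intercept by an inner scalar minimization
            inner = minimize_scalar(
                lambda b0: penalized_nll(y, X, np.array([b0, b1]), lam),
                bounds=(-10, 10), method="bounded",
                options={"xatol": 1e-10})
            return inner.fun

        outer = minimize_scalar(prof, bounds=(-10, 10), method="bounded",
                                options={"xatol": 1e-10})
        beta = fit_ridge_logistic(X, y, lam)
        assert beta[1] == pytest.approx(outer.x, abs=1e-6)

    def test_lambda_zero_matches_sklearn_unpenalized(self, rng):
        x = rng.standard_normal(80)
        y = (rng.random(80) < 1 / (1 + np.exp(-x))).astype(float)
        beta = fit_ridge_logistic(_design([x]), y, 0.0)
        sk = LogisticRegression(penalty=None, tol=1e-10, max_iter=1000)
        sk.fit(x[:, None], y)
        assert beta[0] == pytest.approx(sk.intercept_[0], abs=1e-6)
        assert beta[1] == pytest.approx(sk.coef_[0, 0], abs=1e-6)


def forward_search_oracle(Z, y, lam, tol=1e-6, max_steps=None):
    """Independent exhaustive forward search for cluster 1: at each step
    evaluate every remaining feature by full refit and keep the best,
    stopping when no addition improves the criterion by > tol."""
    n, p = Z.shape
    members: list[int] = []
    crit = penalized_nll(y, np.ones((n, 1)),
                         fit_ridge_logistic(np.ones((n, 1)), y, lam), lam)
    trace = []
    while True:
        if max_steps and len(members) >= max_steps:
            break
        best = None
        for j in range(p):
            if j in members:
                continue
            cent = Z[:, members + [j]].mean(axis=1)
            X = _design([cent])
            beta = fit_ridge_logistic(X, y, lam)
            val = penalized_nll(y, X, beta, lam)
            if best is None or val < best[0]:
                best = (val, j)
        if best is None or crit - best[0] <= tol:
            break
        crit = best[0]
        members.append(best[1])
        trace.append(crit)
    return members, trace


class TestFitPelora:
    def _cohort(self, seed, n=40, p=6, shift=1.0):
        rng = np.random.default_rng(seed)
        g = np.array([0] * (n // 2) + [1] * (n - n // 2))
        Z = rng.standard_normal((n, p))
        Z[g == 1, :2] += shift
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        return Z, g

    def test_first_member_is_single_feature_minimizer(self):
        Z, y = self._cohort(3)
        lam = 1 / 32
        # exhaustive single-feature oracle
        best = min(range(Z.shape[1]), key=lambda j: penalized_nll(
            y, _design([Z[:, j]]),
            fit_ridge_logistic(_design([Z[:, j]]), y, lam), lam))
        est = PeloraClassifier(lam=lam, max_clusters=1).fit(Z, y)
        assert est.clusters_[0][0] == f"f{best}"

    def test_greedy_matches_forward_search(self):
        for seed in range(5):
            Z, y = self._cohort(seed, p=7)
            lam = 0.1
            members, trace = forward_search_oracle(Z, y, lam)
            est = PeloraClassifier(lam=lam, max_clusters=1).fit(Z, y)
            assert est.clusters_[0] == [f"f{j}" for j in members]
            np.testing.assert_allclose(est.criterion_trace_, trace, rtol=1e-8)

    def test_trace_non_increasing(self):
        Z, y = self._cohort(11, p=10)
        est = PeloraClassifier(lam=0.05, max_clusters=2).fit(Z, y)
        assert np.all(np.diff(est.criterion_trace_) <= 1e-12)

    def test_max_clusters_respected(self):
        Z, y = self._cohort(5, p=10)
        fit = fit_pelora(Z, y, lam=0.01, max_clusters=2)
        assert len(fit.clusters) <= 2

    def test_clusters_disjoint(self):
        Z, y = self._cohort(9, p=10)
        fit = fit_pelora(Z, y, lam=0.01, max_clusters=2)
        flat = [m for c in fit.clusters for m in c]
        assert len(flat) == len(set(flat))

    def test_single_class_rejected(self):
        Z, _ = self._cohort(0)
        with pytest.raises(ValueError, match="both classes"):
            PeloraClassifier().fit(Z, np.zeros(Z.shape[0]))

    def test_lambda_zero_single_feature_reduces_to_logistic(self, rng):
        x = rng.standard_normal(60)
        y = (rng.random(60) < 1 / (1 + np.exp(-2 * x))).astype(int)
        df = pd.DataFrame({"only": (x - x.mean()) / x.std(ddof=1)})
        est = PeloraClassifier(lam=0.0, max_clusters=1).fit(df, y)
        sk = LogisticRegression(penalty=None, tol=1e-10, max_iter=1000)
        sk.fit(df[["only"]].to_numpy(), y)
        assert est.coef_[0] == pytest.approx(sk.coef_[0, 0], abs=1e-5)

    def test_sklearn_api_clone_and_predict(self):
        Z, y = self._cohort(2, shift=2.0)
        est = PeloraClassifier(lam=0.1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.fit(Z, y)
        proba = est.predict_proba(Z)
        assert proba.shape == (Z.shape[0], 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert (est.predict(Z) == y).mean() > 0.7


class TestTunePenalty:
    def test_single_element_grid(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((30, 4))
        y = np.array([0, 1] * 15)
        Z[y == 1, 0] += 2
        search = tune_penalty(Z, y, lambda_grid=[0.3], n_boot=3, seed=1)
        assert search.chosen == 0.3

    def test_tie_breaks_to_larger_lambda(self, monkeypatch):
        import microsig.pelora as mp
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((24, 3))
        y = np.array([0, 1] * 12)
        Z[y == 1, 0] += 4  # separable: all small lambdas tie at rate 0

        search = tune_penalty(Z, y, lambda_grid=[1e-3, 1e-2, 1e-1],
                              n_boot=5, seed=0)
        tied = [lam for lam, m in zip(search.lambda_grid, search.median_rates)
                if m == min(search.median_rates)]
        assert search.chosen == max(tied)

    def test_separable_data_zero_median_rate(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((40, 4))
        y = np.array([0, 1] * 20)
        Z[y == 1, 0] += 5
        search = tune_penalty(Z, y, lambda_grid=[1e-3, 1e-2], n_boot=5, seed=2)
        assert min(search.median_rates) == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_penalty(np.zeros((4, 2)), np.array([0, 1, 0, 1]),
                         lambda_grid=[], n_boot=2)
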