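"""PELORA: supervised clustering by penalized logistic regression.

Groups of features (taxa, on the pooled logit Z-score scale) are grown
greedily, one feature at a time.  The covariate carried by a group is its
centroid — the per-sample unweighted mean of member Z columns — and the
fitting criterion is the L2 ("ridge") penalized negative Bernoulli
log-likelihood of a logistic model on all current centroids:

    J(beta) = -sum_i [ y_i log pi_i + (1 - y_i) log(1 - pi_i) ]
              + lambda * sum_{j>=1} beta_j^2,        pi = logistic(X beta)

with the intercept unpenalized.  At each step the candidate feature whose
inclusion (recompute the growing group's centroid, refit the logistic
model) most decreases J is added; growth stops when no candidate improves
J by more than ``tol``.  A finished group is frozen, its centroid remains
in the design, and the next group is grown the same way, up to
``max_clusters`` groups (two by default, for interpretability).

The penalty is tuned by bootstrap resampling: for each candidate lambda
the model is refit on resamples and scored by out-of-bag 0/1
misclassification; the lambda with the lowest median rate wins, with ties
resolved toward the larger (more regularized) value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .transforms import ZScoreMatrix

__all__ = [
    "PeloraFit",
    "PenaltySearch",
    "PeloraClassifier",
    "penalized_nll",
    "fit_ridge_logistic",
    "fit_pelora",
    "tune_penalty",
    "DEFAULT_LAMBDA_GRID",
]

logger = logging.getLogger(__name__)

#: 13 log-spaced penalty values, 1e-3 ... 1e3.
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 13))

_PROB_CLIP = 1e-12


@dataclass
class PeloraFit:
    """Fitted supervised clustering: ordered clusters of ordered members."""

    clusters: list[list[str]]
    lam: float
    intercept: float
    coefficients: np.ndarray  # one slope per cluster centroid
    criterion_trace: list[float]
    centroids: pd.DataFrame  # samples x clusters

    def predict_proba_from_centroids(self, centroids: np.ndarray) -> np.ndarray:
        eta = self.intercept + centroids @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class PenaltySearch:
    lambda_grid: list[float]
    median_rates: list[float]
    rates: list[list[float]]  # per lambda, per bootstrap
    chosen: float


def penalized_nll(y: np.ndarray, X: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """L2-penalized negative Bernoulli log-likelihood (intercept in column 0
    of X is unpenalized).  Probabilities are clipped at 1e-12."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    if np.any(pi <= _PROB_CLIP) or np.any(pi >= 1 - _PROB_CLIP):
        logger.debug("clipping fitted probabilities at %g", _PROB_CLIP)
    pi = np.clip(pi, _PROB_CLIP, 1 - _PROB_CLIP)
    nll = -np.sum(y * np.log(pi) + (1 - y) * np.log1p(-pi))
    return float(nll + lam * np.sum(beta[1:] ** 2))


def fit_ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Minimize the penalized NLL by damped Newton (IRLS) iterations.

    X must carry an intercept column of ones in position 0; that
    coefficient is not penalized.  Converges to gradient norm < tol."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("X must have an intercept column of ones first")
    pen = np.ones(p)
    pen[0] = 0.0
    beta = np.zeros(p)
    obj = penalized_nll(y, X, beta, lam)
    trace = [obj]
    for _ in range(max_iter):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (pi - y) + 2.0 * lam * pen * beta
        gnorm = np.linalg.norm(grad)
        if gnorm < tol:
            return beta
        w = np.clip(pi * (1.0 - pi), 1e-10, None)
        H = (X * w[:, None]).T @ X + 2.0 * lam * np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped: halve until the criterion does not increase
        t = 1.0
        for _ in range(50):
            cand = beta - t * step
            new_obj = penalized_nll(y, X, cand, lam)
            if new_obj <= obj + 1e-12:
                break
            t *= 0.5
        beta = beta - t * step
        obj = penalized_nll(y, X, beta, lam)
        trace.append(obj)
    # final check: separable data with lam ~ 0 can stall at tiny gradients
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ (pi - y) + 2.0 * lam * pen * beta
    if np.linalg.norm(grad) < 1e-6:
        return beta
    raise RuntimeError(
        f"IRLS did not converge in {max_iter} iterations; criterion trace: "
        f"{trace[:3]} ... {trace[-3:]}"
    )


def _design(centroids: np.ndarray) -> np.ndarray:
    n = centroids.shape[0]
    return np.column_stack([np.ones(n), centroids])


class PeloraClassifier(ClassifierMixin, BaseEstimator):
    """Supervised clustering of Z-scored features via penalized logistic
    regression, in the sklearn estimator idiom.

    Parameters
    ----------
    lam : float
        Ridge penalty on centroid slopes (intercept unpenalized); the
        default 1/32 follows the reference PELORA implementation.
    max_clusters : int
        Maximum number of clusters grown (default 2).
    tol : float
        Minimum criterion decrease for accepting a feature addition.
    sign_flip : bool
        If True, each candidate may also enter a centroid negated; off by
        default (centroids are plain means of member Z columns).
    max_cluster_size : int or None
        Optional cap on members per cluster.

    Attributes
    ----------
    clusters_ : list of list of feature names.
    intercept_, coef_ : fitted logistic coefficients on cluster centroids.
    criterion_trace_ : penalized-NLL value after each accepted addition.
    centroids_ : DataFrame of training-sample centroids, one column per cluster.
    signs_ : per-cluster member signs (+1/-1; all +1 unless sign_flip).
    """

    def __init__(self, lam: float = 1 / 32, max_clusters: int = 2, tol: float = 1e-6,
                 sign_flip: bool = False, max_cluster_size: int | None = None):
        self.lam = lam
        self.max_clusters = max_clusters
        self.tol = tol
        self.sign_flip = sign_flip
        self.max_cluster_size = max_cluster_size

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, fixed_covariates: np.ndarray | None = None):
        X = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("y must contain both classes")
        self.classes_ = classes.astype(int)
        names = list(X.columns)
        Z = X.to_numpy(dtype=float)
        n = Z.shape[0]
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")

        fixed = (np.empty((n, 0)) if fixed_covariates is None
                 else np.asarray(fixed_covariates, dtype=float))
        clusters: list[list[int]] = []
        signs: list[list[int]] = []
        centroid_cols: list[np.ndarray] = []
        used: set[int] = set()
        trace: list[float] = []

        def criterion(cols: list[np.ndarray]) -> tuple[float, np.ndarray]:
            mat = np.column_stack([fixed] + cols) if (cols or fixed.size) else np.empty((n, 0))
            Xd = _design(mat)
            beta = fit_ridge_logistic(Xd, y, self.lam)
            return penalized_nll(y, Xd, beta, self.lam), beta

        current, _ = criterion(centroid_cols)
        for _ in range(self.max_clusters):
            members: list[int] = []
            member_signs: list[int] = []
            sum_col = np.zeros(n)
            improved_any = False
            while True:
                if self.max_cluster_size and len(members) >= self.max_cluster_size:
                    break
                best = None  # (crit, feat, sign, beta)
                sign_options = (1, -1) if self.sign_flip else (1,)
                for j in range(Z.shape[1]):
                    if j in used:
                        continue
                    for s in sign_options:
                        cand_centroid = (sum_col + s * Z[:, j]) / (len(members) + 1)
                        crit, beta = criterion(centroid_cols + [cand_centroid])
                        if best is None or crit < best[0]:
                            best = (crit, j, s, beta)
                if best is None or current - best[0] <= self.tol:
                    break
                crit, j, s, _ = best
                members.append(j)
                member_signs.append(s)
                used.add(j)
                sum_col = sum_col + s * Z[:, j]
                current = crit
                trace.append(crit)
                improved_any = True
            if not improved_any:
                break
            clusters.append(members)
            signs.append(member_signs)
            centroid_cols.append(sum_col / len(members))

        if not clusters:
            raise ValueError("no cluster could be grown: no feature decreases "
                             "the criterion by more than tol")
        final_crit, beta = criterion(centroid_cols)
        n_fixed = fixed.shape[1]
        self.clusters_ = [[names[j] for j in mem] for mem in clusters]
        self.signs_ = signs
        self.intercept_ = float(beta[0])
        self.fixed_coef_ = beta[1:1 + n_fixed].copy()
        self.coef_ = beta[1 + n_fixed:].copy()
        self.criterion_trace_ = trace
        self.criterion_ = final_crit
        self.centroids_ = pd.DataFrame(
            np.column_stack(centroid_cols), index=X.index,
            columns=[f"cluster_{k + 1}" for k in range(len(clusters))],
        )
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    # -------------------------------------------------------------- predict
    def _centroids_of(self, X) -> np.ndarray:
        X = self._as_frame(X)
        cols = []
        for mem, sgn in zip(self.clusters_, self.signs_):
            mat = X[mem].to_numpy(dtype=float) * np.asarray(sgn, dtype=float)
            cols.append(mat.mean(axis=1))
        return np.column_stack(cols)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "clusters_")
        c = self._centroids_of(X)
        return self.intercept_ + c @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, ZScoreMatrix):
            return X.values
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])


def fit_pelora(
    z: ZScoreMatrix | pd.DataFrame | np.ndarray,
    y: np.ndarray,
    lam: float = 1 / 32,
    max_clusters: int = 2,
    tol: float = 1e-6,
    sign_flip: bool = False,
) -> PeloraFit:
    """Functional wrapper over :class:`PeloraClassifier`."""
    est = PeloraClassifier(lam=lam, max_clusters=max_clusters, tol=tol,
                           sign_flip=sign_flip).fit(z, y)
    return PeloraFit(
        clusters=est.clusters_,
        lam=lam,
        intercept=est.intercept_,
        coefficients=est.coef_,
        criterion_trace=est.criterion_trace_,
        centroids=est.centroids_,
    )


def tune_penalty(
    z: ZScoreMatrix | pd.DataFrame | np.ndarray,
    y: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_boot: int = 50,
    max_clusters: int = 2,
    seed: int | None = None,
    max_cluster_size: int | None = None,
) -> PenaltySearch:
    """Choose the penalty with the lowest median out-of-bag
    misclassification rate over bootstrap resamples (ties -> larger
    lambda).  Resamples that miss a class are redrawn (logged)."""
    grid = list(lambda_grid)
    if not grid:
        raise ValueError("empty lambda grid")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    frame = PeloraClassifier._as_frame(z)
    y = np.asarray(y, dtype=float)
    n = frame.shape[0]
    rng = np.random.default_rng(seed)

    # shared resamples across lambdas: a paired comparison
    resamples = []
    while len(resamples) < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.unique(y[idx]).size < 2:
            logger.info("bootstrap resample with a single class redrawn")
            continue
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        resamples.append((idx, oob))

    rates: list[list[float]] = []
    for lam in grid:
        lam_rates = []
        for idx, oob in resamples:
            try:
                est = PeloraClassifier(lam=lam, max_clusters=max_clusters,
                                       max_cluster_size=max_cluster_size)
                est.fit(frame.iloc[idx], y[idx])
                pred = est.predict(frame.iloc[oob])
                lam_rates.append(float(np.mean(pred != y[oob])))
            except ValueError:
                # no cluster grew at this penalty on this resample:
                # predict the majority class
                maj = float(np.mean(y[idx]) >= 0.5)
                lam_rates.append(float(np.mean(maj != y[oob])))
        rates.append(lam_rates)
    medians = [float(np.median(r)) for r in rates]
    best_rate = min(medians)
    chosen = max(lam for lam, m in zip(grid, medians) if m == best_rate)
    return PenaltySearch(lambda_grid=grid, median_rates=medians, rates=rates,
                         chosen=float(chosen))
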