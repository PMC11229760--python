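"""Iterative Random Forest (iRF) with Random Intersection Trees.

The iRF procedure refits a random forest K times, feeding the Gini
importances of iteration k back as split-candidate sampling weights for
iteration k+1: iteration 1 uses uniform weights, so K = 1 is an ordinary
random forest.  The soft re-weighting concentrates splits on the features
that matter, which stabilizes the decision paths that interaction mining
consumes.

Interactions are mined by generalized Random Intersection Trees (RIT):
every class-1 leaf of the final forest contributes the set of distinct
features on its root-to-leaf path, weighted by the leaf's sample count;
RIT repeatedly intersects randomly drawn itemsets and keeps the surviving
sets.  Repeating the whole pipeline over bootstrap perturbations of the
data yields a *stability score* per interaction — the fraction of
bootstraps in which it is recovered (0 = never, 1 = always).

Model quality is summarized by the AUC of the out-of-bag probabilities,
with a percentile confidence interval from stratified bootstrap
replicates, and by variable importances rescaled so the maximum is 100%.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._tree import Tree, grow_tree

__all__ = [
    "IrfResult",
    "Interaction",
    "IterativeRandomForestClassifier",
    "iterate_irf",
    "tune_iterations",
    "mine_interactions",
    "roc_auc",
    "relative_vimp",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Interaction:
    """A feature tuple (order >= 2) with its bootstrap stability score."""

    features: tuple[str, ...]
    stability: float

    def __post_init__(self):
        if len(self.features) < 2:
            raise ValueError("interactions have order >= 2")
        if tuple(sorted(self.features)) != self.features:
            raise ValueError("feature tuple must be sorted")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in interaction")
        if not 0.0 <= self.stability <= 1.0:
            raise ValueError("stability must lie in [0, 1]")


@dataclass
class IrfResult:
    n_iterations: int
    weight_history: np.ndarray  # (K, p); row k used by iteration k+1's forest
    n_trees: int
    mtry: int
    seed: int | None
    feature_names: list[str]
    oob_probabilities: np.ndarray
    vimp_raw: np.ndarray
    vimp_relative: np.ndarray
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    interactions: list[Interaction] = field(default_factory=list)


class IterativeRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Feature-weighted random-forest classifier refit iteratively.

    Parameters
    ----------
    n_iterations : int
        K; iteration 1 uses uniform feature weights (K=1 is a plain RF).
    n_trees : int
        Trees per forest.
    mtry : int or None
        Split candidates per node, drawn without replacement with
        probability proportional to the current weights; default ceil(sqrt(p)).
    max_depth, min_samples_leaf : tree-growth controls.
    random_state : seed for all randomness (bootstraps, candidate draws).

    Attributes
    ----------
    trees_ : list of Tree (final iteration's forest).
    weight_history_ : (K, p) array; row k-1 is the weight vector used by
        iteration k.  Each row sums to 1.
    feature_importances_ : normalized Gini importances of the final forest.
    oob_proba_ : out-of-bag class-1 vote fraction per training sample
        (NaN for samples never out of bag).
    """

    def __init__(self, n_iterations: int = 5, n_trees: int = 500,
                 mtry: int | None = None, max_depth: int = 10,
                 min_samples_leaf: int = 1, random_state: int | None = None):
        self.n_iterations = n_iterations
        self.n_trees = n_trees
        self.mtry = mtry
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X, names = _as_array(X)
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise ValueError("y must contain both classes")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        n, p = X.shape
        mtry = self.mtry or int(np.ceil(np.sqrt(p)))
        rng = np.random.default_rng(self.random_state)
        weights = np.full(p, 1.0 / p)
        history = []
        for k in range(self.n_iterations):
            history.append(weights.copy())
            trees, oob_sets = _grow_forest(
                X, y, weights, rng, self.n_trees, mtry,
                self.max_depth, self.min_samples_leaf,
            )
            raw_imp = np.sum([t.gini_importances(p) for t in trees], axis=0)
            raw_imp = np.clip(raw_imp, 0.0, None)
            if raw_imp.sum() <= 0:
                logger.warning("all-zero importance vector; weights reset to uniform")
                weights = np.full(p, 1.0 / p)
            else:
                weights = raw_imp / raw_imp.sum()
        self.classes_ = np.unique(y)
        self.trees_ = trees
        self.weight_history_ = np.asarray(history)
        self.feature_importances_ = weights
        self.raw_importances_ = raw_imp
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.mtry_ = mtry
        self.oob_proba_ = _oob_probabilities(X, trees, oob_sets)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X, _ = _as_array(X)
        votes = np.mean([(t.predict_proba(X) >= 0.5) for t in self.trees_], axis=0)
        return np.column_stack([1.0 - votes, votes])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def leaf_itemsets(self) -> list[tuple[frozenset, int]]:
        """(feature set on path, leaf sample count) for every class-1 leaf
        of the final forest."""
        check_is_fitted(self, "trees_")
        out = []
        for t in self.trees_:
            for value, n_samples, feats in t.decision_paths():
                if value >= 0.5 and feats:
                    out.append((feats, n_samples))
        return out


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"f{j}" for j in range(X.shape[1])]


def _grow_forest(X, y, weights, rng, n_trees, mtry, max_depth, min_leaf):
    n = X.shape[0]
    trees: list[Tree] = []
    oob_sets: list[np.ndarray] = []
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[idx] = True
        trees.append(grow_tree(X[idx], y[idx], weights, rng, mtry,
                               max_depth=max_depth, min_samples_leaf=min_leaf))
        oob_sets.append(np.nonzero(~in_bag)[0])
    return trees, oob_sets


def _oob_probabilities(X, trees, oob_sets) -> np.ndarray:
    n = X.shape[0]
    votes = np.zeros(n)
    counts = np.zeros(n)
    for tree, oob in zip(trees, oob_sets):
        if oob.size == 0:
            continue
        votes[oob] += tree.predict_proba(X[oob]) >= 0.5
        counts[oob] += 1
    never = counts == 0
    if np.any(never):
        warnings.warn(f"{int(never.sum())} sample(s) never out of bag; "
                      "OOB probability set to NaN", stacklevel=2)
    with np.errstate(invalid="ignore"):
        return np.where(never, np.nan, votes / np.maximum(counts, 1))


# ---------------------------------------------------------------- wrappers

def iterate_irf(
    X,
    y,
    K: int = 5,
    n_trees: int = 500,
    seed: int | None = None,
    mtry: int | None = None,
    max_depth: int = 10,
    min_samples_leaf: int = 1,
    n_boot_ci: int = 1000,
) -> IrfResult:
    """Run the K-iteration feature-weighted forest and summarize it."""
    est = IterativeRandomForestClassifier(
        n_iterations=K, n_trees=n_trees, mtry=mtry, max_depth=max_depth,
        min_samples_leaf=min_samples_leaf, random_state=seed,
    ).fit(X, y)
    y = np.asarray(y).astype(int)
    auc, lo, hi = roc_auc(est.oob_proba_, y, n_boot_ci=n_boot_ci,
                          seed=seed)
    raw = est.raw_importances_
    rel = relative_vimp(raw) if np.any(raw > 0) else np.zeros_like(raw)
    return IrfResult(
        n_iterations=K,
        weight_history=est.weight_history_,
        n_trees=n_trees,
        mtry=est.mtry_,
        seed=seed,
        feature_names=list(est.feature_names_in_),
        oob_probabilities=est.oob_proba_,
        vimp_raw=raw,
        vimp_relative=rel,
        auc=auc,
        auc_ci=(lo, hi),
    )


def tune_iterations(X, y, K_grid, n_trees: int = 500, seed: int | None = None,
                    **kwargs) -> int:
    """Pick K from the grid by maximum OOB AUC (ties -> smallest K)."""
    grid = sorted(set(int(k) for k in K_grid))
    if not grid:
        raise ValueError("empty K grid")
    if grid[0] < 1 or grid[-1] > 100:
        raise ValueError("K values must lie in 1..100")
    best_k, best_auc = None, -np.inf
    for k in grid:
        est = IterativeRandomForestClassifier(
            n_iterations=k, n_trees=n_trees, random_state=seed, **kwargs
        ).fit(X, y)
        auc, _, _ = roc_auc(est.oob_proba_, np.asarray(y).astype(int),
                            n_boot_ci=0)
        if auc > best_auc + 1e-12:
            best_k, best_auc = k, auc
    return best_k


# --------------------------------------------------- random intersection

def _rit_survivors(itemsets, weights, rng, depth, branch, n_rit_trees):
    """Run RIT over weighted itemsets; return surviving sets of size >= 2.

    Each intersection tree starts from one sampled itemset; every node at
    depth < D branches into `branch` children, each the intersection of
    the parent set with a freshly sampled itemset.  Depth-D survivors are
    collected."""
    m = len(itemsets)
    if m == 0:
        return set()
    probs = np.asarray(weights, dtype=float)
    probs = probs / probs.sum()
    survivors: set[frozenset] = set()
    for _ in range(n_rit_trees):
        root = itemsets[rng.choice(m, p=probs)]
        level = [root]
        for _ in range(depth):
            nxt = []
            for node in level:
                for _ in range(branch):
                    child = node & itemsets[rng.choice(m, p=probs)]
                    if len(child) >= 2:
                        nxt.append(child)
            level = nxt
            if not level:
                break
        survivors.update(level)
    return survivors


def mine_interactions(
    X,
    y,
    K: int = 5,
    n_boot: int = 30,
    rit_depth: int = 5,
    rit_branch: int = 2,
    n_rit_trees: int = 500,
    seed: int | None = None,
    n_trees: int = 500,
    max_depth: int = 10,
    min_samples_leaf: int = 1,
    mtry: int | None = None,
) -> list[Interaction]:
    """Bootstrap-stabilized interaction mining.

    For each of ``n_boot`` outer bootstraps the K-iteration forest is
    refit, class-1 decision-path itemsets are extracted and RIT mines the
    prevalent intersections; an interaction's stability is the fraction of
    bootstraps recovering it.  Returned sorted by decreasing stability,
    order >= 2 only."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    Xa, names = _as_array(X)
    y = np.asarray(y).astype(int)
    n = Xa.shape[0]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size == 2:
                break
            logger.info("single-class outer bootstrap redrawn")
        est = IterativeRandomForestClassifier(
            n_iterations=K, n_trees=n_trees, mtry=mtry, max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(Xa[idx], y[idx])
        itemsets = est.leaf_itemsets()
        if not itemsets:
            logger.info("no class-1 leaves in bootstrap %d", b)
            continue
        sets = [s for s, _ in itemsets]
        wts = [w for _, w in itemsets]
        found = _rit_survivors(sets, wts, rng, rit_depth, rit_branch, n_rit_trees)
        for s in found:
            counts[s] = counts.get(s, 0) + 1
    out = [
        Interaction(features=tuple(sorted(names[j] for j in s)),
                    stability=c / n_boot)
        for s, c in counts.items()
    ]
    out.sort(key=lambda it: (-it.stability, it.features))
    return out


# -------------------------------------------------------------------- AUC

def roc_auc(
    probs: np.ndarray,
    y: np.ndarray,
    n_boot_ci: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """AUC by the rank (Mann-Whitney) formulation, ties counted 0.5, with a
    percentile CI from stratified (within-class) bootstrap replicates.

    NaN probabilities (samples never out of bag) are dropped with a
    warning.  Returns (auc, ci_lo, ci_hi); the CI is (nan, nan) when
    n_boot_ci == 0."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(int)
    keep = ~np.isnan(probs)
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} sample(s) with missing "
                      "OOB probability from AUC", stacklevel=2)
        probs, y = probs[keep], y[keep]
    if np.unique(y).size < 2:
        raise ValueError("both classes required for AUC")
    if np.all(probs == probs[0]):
        warnings.warn("constant probabilities: AUC is 0.5", stacklevel=2)

    def _auc(p, labels):
        r = rankdata(p)
        n1 = int(labels.sum())
        n0 = labels.size - n1
        return (r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    point = float(_auc(probs, y))
    if n_boot_ci <= 0:
        return point, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    reps = np.empty(n_boot_ci)
    for b in range(n_boot_ci):
        idx = np.concatenate([
            rng.choice(pos, size=pos.size, replace=True),
            rng.choice(neg, size=neg.size, replace=True),
        ])
        reps[b] = _auc(probs[idx], y[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, float(lo), float(hi)


def relative_vimp(importances: np.ndarray) -> np.ndarray:
    """Rescale importances so the maximum is exactly 100 (%).

    Non-positive raw importances map to non-positive percentages and are
    meant to be excluded from display."""
    imp = np.asarray(importances, dtype=float)
    if not np.any(imp > 0):
        raise ValueError("at least one positive importance required")
    return imp * (100.0 / imp.max())
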