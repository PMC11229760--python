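"""Feature-weighted CART trees.

A minimal binary classification tree where, at every node, the ``mtry``
split-candidate features are drawn *without replacement with probability
proportional to a feature-weight vector*.  Weighted candidate sampling is
the defining ingredient of iteratively re-weighted forests and is not
available in mainstream tree libraries, hence this implementation.

Trees are stored as flat arrays (feature, threshold, children, leaf value)
so that forests of thousands of trees stay cheap to hold and traverse.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tree", "grow_tree"]

_LEAF = -1


class Tree:
    """Flat-array binary decision tree for 0/1 classification.

    Attributes
    ----------
    feature, threshold : per-node split definition; ``feature == -1`` marks
        a leaf.  A sample goes left when ``x[feature] <= threshold``.
    left, right : child node indices.
    value : fraction of class-1 training samples in the node.
    n_node_samples : training samples reaching the node.
    """

    __slots__ = ("feature", "threshold", "left", "right", "value", "n_node_samples")

    def __init__(self, feature, threshold, left, right, value, n_node_samples):
        self.feature = np.asarray(feature, dtype=np.int32)
        self.threshold = np.asarray(threshold, dtype=np.float64)
        self.left = np.asarray(left, dtype=np.int32)
        self.right = np.asarray(right, dtype=np.int32)
        self.value = np.asarray(value, dtype=np.float64)
        self.n_node_samples = np.asarray(n_node_samples, dtype=np.int32)

    @property
    def n_nodes(self) -> int:
        return self.feature.shape[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability (leaf class-1 fraction) per row of X."""
        X = np.asarray(X, dtype=np.float64)
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] != _LEAF
        while np.any(active):
            idx = np.nonzero(active)[0]
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            active[idx] = self.feature[node[idx]] != _LEAF
        return self.value[node]

    def decision_paths(self):
        """Yield (leaf_value, n_samples, frozenset of features on the path)
        for every leaf, by depth-first walk with an explicit stack."""
        out = []
        stack = [(0, frozenset())]
        while stack:
            node, feats = stack.pop()
            f = self.feature[node]
            if f == _LEAF:
                out.append((self.value[node], int(self.n_node_samples[node]), feats))
            else:
                child_feats = feats | {int(f)}
                stack.append((int(self.left[node]), child_feats))
                stack.append((int(self.right[node]), child_feats))
        return out

    def gini_importances(self, n_features: int) -> np.ndarray:
        """Importance of feature f = total weighted Gini impurity decrease
        over nodes splitting on f, normalized by the root sample count."""
        imp = np.zeros(n_features)
        n_root = max(int(self.n_node_samples[0]), 1)
        internal = np.nonzero(self.feature != _LEAF)[0]
        for node in internal:
            nl = self.n_node_samples[self.left[node]]
            nr = self.n_node_samples[self.right[node]]
            n = self.n_node_samples[node]
            g = _gini(self.value[node])
            gl = _gini(self.value[self.left[node]])
            gr = _gini(self.value[self.right[node]])
            decrease = n * g - nl * gl - nr * gr
            imp[self.feature[node]] += decrease / n_root
        return imp


def _gini(p1: float) -> float:
    return 2.0 * p1 * (1.0 - p1)


def _best_split(Xsub: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (feature column, threshold) over a candidate submatrix.

    Returns (impurity_decrease, column_index, threshold) or None.  The
    decrease is n*gini(parent) - nl*gini(left) - nr*gini(right) in units of
    sample counts (parent term common to all candidates; comparison-safe).
    """
    n, k = Xsub.shape
    if n < 2 * min_leaf:
        return None
    order = np.argsort(Xsub, axis=0, kind="stable")
    xs = np.take_along_axis(Xsub, order, axis=0)
    ys = y[order]  # (n, k)
    cum_pos = np.cumsum(ys, axis=0, dtype=np.float64)
    total_pos = cum_pos[-1, 0]
    nl = np.arange(1, n, dtype=np.float64)[:, None]
    pos_l = cum_pos[:-1]
    nr = n - nl
    pos_r = total_pos - pos_l
    # valid split points: value changes and both children >= min_leaf
    valid = (xs[1:] != xs[:-1]) & (nl >= min_leaf) & (nr >= min_leaf)
    if not np.any(valid):
        return None
    # per-child impurity times child size: 2 * npos * nneg / n_child
    child_term = 2.0 * pos_l * (nl - pos_l) / nl + 2.0 * pos_r * (nr - pos_r) / nr
    child_term[~valid] = np.inf
    flat = int(np.argmin(child_term))
    row, col = divmod(flat, k)
    parent_term = 2.0 * total_pos * (n - total_pos) / n
    decrease = parent_term - child_term[row, col]
    if decrease <= 1e-12:
        return None
    thr = 0.5 * (xs[row, col] + xs[row + 1, col])
    return float(decrease), col, float(thr)


def _draw_candidates(rng, weights, mtry):
    """Weighted sampling of split-candidate features without replacement."""
    pos = np.count_nonzero(weights > 0)
    k = min(mtry, pos)
    if k == 0:
        return np.array([], dtype=np.int64)
    return rng.choice(weights.shape[0], size=k, replace=False, p=weights)


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    mtry: int,
    max_depth: int = 10,
    min_samples_leaf: int = 1,
) -> Tree:
    """Grow a single feature-weighted classification tree on (X, y).

    weights must be a probability vector over features; at each node the
    candidate features are drawn without replacement with probability
    proportional to it.
    """
    n, p = X.shape
    feature, threshold, left, right, value, nsamp = [], [], [], [], [], []

    def new_node():
        feature.append(_LEAF)
        threshold.append(0.0)
        left.append(_LEAF)
        right.append(_LEAF)
        value.append(0.0)
        nsamp.append(0)
        return len(feature) - 1

    root = new_node()
    stack = [(root, np.arange(n), 0)]
    while stack:
        node, idx, depth = stack.pop()
        ysub = y[idx]
        nsamp[node] = idx.shape[0]
        value[node] = float(ysub.mean())
        if (
            depth >= max_depth
            or idx.shape[0] < 2 * min_samples_leaf
            or value[node] in (0.0, 1.0)
        ):
            continue
        cands = _draw_candidates(rng, weights, mtry)
        if cands.shape[0] == 0:
            continue
        res = _best_split(X[np.ix_(idx, cands)], ysub, min_samples_leaf)
        if res is None:
            continue
        _, col, best_thr = res
        best_f = int(cands[col])
        go_left = X[idx, best_f] <= best_thr
        l_node, r_node = new_node(), new_node()
        feature[node] = best_f
        threshold[node] = best_thr
        left[node] = l_node
        right[node] = r_node
        stack.append((l_node, idx[go_left], depth + 1))
        stack.append((r_node, idx[~go_left], depth + 1))
    return Tree(feature, threshold, left, right, value, nsamp)
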