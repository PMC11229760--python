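"""Model interpretation: Accumulated Local Effects and 2-D Partial Dependence.

ALE answers "how does the predicted probability move, on average, as this
feature moves through its observed range", accumulating *local* prediction
differences within quantile bins so that correlated features do not leak
in; the curve is centered so that 0 marks the average predicted risk.  A
2-D PDP instead clamps a feature pair to a grid of values and averages the
prediction over all samples, mapping the joint abundance regions where the
positive outcome is most probable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ALECurve",
    "PDPSurface",
    "ale_curve",
    "pdp_surface",
    "select_ale_features",
    "select_pdp_pairs",
    "interaction_edges",
    "VIMP_DISPLAY_THRESHOLD",
    "PDP_STABILITY_THRESHOLD",
    "EDGE_STABILITY_THRESHOLD",
]

#: Features shown in ALE panels: relative VIMP strictly above 10%.
VIMP_DISPLAY_THRESHOLD = 10.0
#: Pairs eligible for PDP surfaces: stability strictly above 0.70.
PDP_STABILITY_THRESHOLD = 0.70
#: Edges kept in the interaction network: stability at least 0.5.
EDGE_STABILITY_THRESHOLD = 0.5


@dataclass
class ALECurve:
    feature: str
    edges: np.ndarray        # len B+1, strictly increasing
    effects: np.ndarray      # len B, centered accumulated effect at upper edges
    counts: np.ndarray       # len B, samples per bin


@dataclass
class PDPSurface:
    features: tuple[str, str]
    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray       # (len(grid_x), len(grid_y)) mean probabilities
    high_risk: np.ndarray    # boolean mask, values >= threshold
    threshold: float


def _column(X, feature):
    if isinstance(X, pd.DataFrame):
        if feature not in X.columns:
            raise KeyError(f"unknown feature {feature!r}")
        return X[feature].to_numpy(dtype=float), str(feature)
    X = np.asarray(X, dtype=float)
    j = int(feature)
    if not 0 <= j < X.shape[1]:
        raise KeyError(f"unknown feature {feature!r}")
    return X[:, j], f"f{j}"


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _col_index(X, feature) -> int:
    if isinstance(X, pd.DataFrame):
        return int(X.columns.get_loc(feature))
    return int(feature)


def ale_curve(predict_fn, X, feature, n_bins: int = 20) -> ALECurve:
    """First-order ALE of ``feature`` for a probability model.

    Bin edges are the feature's quantiles (duplicates from heavy ties are
    merged, so every bin is nonempty).  The local effect of a bin is the
    mean over its samples of f(x with feature set to the upper edge) minus
    f(x with feature set to the lower edge); effects are accumulated over
    bins and centered so the count-weighted mean is zero — an ALE of 0 is
    the average predicted risk."""
    xs, name = _column(X, feature)
    if np.unique(xs).size < 2:
        raise ValueError(f"feature {name!r} is constant")
    edges = np.unique(np.quantile(xs, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        raise ValueError("could not form bins")
    # assign each sample to a bin; values at the lowest edge go to bin 0
    bins = np.clip(np.searchsorted(edges, xs, side="left") - 1, 0, edges.size - 2)
    mat = _as_matrix(X)
    j = _col_index(X, feature)
    B = edges.size - 1
    local = np.zeros(B)
    counts = np.zeros(B, dtype=int)
    for b in range(B):
        mask = bins == b
        counts[b] = int(mask.sum())
        if counts[b] == 0:
            continue
        lo = mat[mask].copy()
        hi = mat[mask].copy()
        lo[:, j] = edges[b]
        hi[:, j] = edges[b + 1]
        local[b] = float(np.mean(predict_fn(hi) - predict_fn(lo)))
    acc = np.cumsum(local)
    center = np.sum(counts * acc) / counts.sum()
    return ALECurve(feature=name, edges=edges, effects=acc - center, counts=counts)


def pdp_surface(predict_fn, X, pair, grid_size: int = 20,
                threshold: float = 0.5) -> PDPSurface:
    """2-D partial dependence of a feature pair on the predicted probability.

    Grid points are the marginal quantiles of each feature; each cell
    value averages predict_fn over all samples with the pair clamped to
    the cell.  Cells at or above ``threshold`` are flagged high-risk."""
    if len(pair) != 2 or pair[0] == pair[1]:
        raise ValueError("pair must be two distinct features")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    xs, name_x = _column(X, pair[0])
    ys, name_y = _column(X, pair[1])
    gx = np.unique(np.quantile(xs, np.linspace(0, 1, grid_size)))
    gy = np.unique(np.quantile(ys, np.linspace(0, 1, grid_size)))
    mat = _as_matrix(X)
    jx, jy = _col_index(X, pair[0]), _col_index(X, pair[1])
    vals = np.empty((gx.size, gy.size))
    work = mat.copy()
    for a, vx in enumerate(gx):
        work[:, jx] = vx
        for b, vy in enumerate(gy):
            work[:, jy] = vy
            vals[a, b] = float(np.mean(predict_fn(work)))
        work[:, jy] = mat[:, jy]
    return PDPSurface(features=(name_x, name_y), grid_x=gx, grid_y=gy,
                      values=vals, high_risk=vals >= threshold,
                      threshold=float(threshold))


def select_ale_features(feature_names, vimp_relative,
                        threshold: float = VIMP_DISPLAY_THRESHOLD) -> list[str]:
    """Features whose relative VIMP exceeds the display threshold (10%)."""
    vimp = np.asarray(vimp_relative, dtype=float)
    return [str(f) for f, v in zip(feature_names, vimp) if v > threshold]


def select_pdp_pairs(interactions,
                     threshold: float = PDP_STABILITY_THRESHOLD) -> list[tuple[str, str]]:
    """Order-2 interactions stable enough for PDP surfaces (> 0.70)."""
    return [it.features for it in interactions
            if len(it.features) == 2 and it.stability > threshold]


def interaction_edges(interactions,
                      threshold: float = EDGE_STABILITY_THRESHOLD) -> list[tuple[str, str, float]]:
    """Edge list (u, v, stability) of order-2 interactions with stability
    >= 0.5, for network rendering."""
    return [(it.features[0], it.features[1], it.stability)
            for it in interactions
            if len(it.features) == 2 and it.stability >= threshold]
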