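"""Abundance transforms: zero replacement, logit Z-scores, cluster centroids.

Relative abundances live on the percent scale (0-100).  For modeling, each
taxon's percent is mapped to ``logit(p/100)`` and standardized to mean 0,
sample SD 1 over the *whole cohort* (both groups pooled).  Exact zeros are
first replaced by half of the smallest nonzero percent found in the entire
matrix, so the logit is defined everywhere.

A cluster "centroid" is the per-sample unweighted mean of the Z-scores of
its member taxa.  Because centroids are linear in the members, the group
mean of a centroid equals the plain average of the member group means —
the arithmetic behind published per-cluster summary tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .abundance_io import AbundanceTable

__all__ = [
    "ZScoreMatrix",
    "CentroidResult",
    "LogitZTransformer",
    "replace_zeros",
    "logit_zscore",
    "centroid",
    "compare_centroids",
    "absent_group_constant",
]


@dataclass
class ZScoreMatrix:
    """Logit-transformed, per-feature standardized abundances.

    values holds retained (non-constant) features only; dropped_features
    maps each zero-variance feature to its constant logit value.
    """

    values: pd.DataFrame
    feature_means: pd.Series
    feature_sds: pd.Series
    replacement_value: float
    dropped_features: dict[str, float] = field(default_factory=dict)
    group: pd.Series | None = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CentroidResult:
    members: list[str]
    per_sample: pd.Series
    group_means: dict[int, float]
    group_sds: dict[int, float]
    statistic: float | None = None
    p_value: float | None = None
    test_used: str | None = None


def replace_zeros(table: AbundanceTable) -> AbundanceTable:
    """Replace exact-zero percents by half the dataset-wide minimum nonzero
    percent; nonzero entries are untouched."""
    vals = table.values.to_numpy(dtype=float)
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("all-zero abundance matrix: no replacement value defined")
    half_min = nz.min() / 2.0
    out = table.values.where(table.values > 0, other=half_min)
    return AbundanceTable(values=out, group=table.group, rank=table.rank,
                          validate=False)


def _logit_percent(values: np.ndarray) -> np.ndarray:
    p = values / 100.0
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("percents must lie strictly in (0, 100) after zero "
                         "replacement; call replace_zeros first")
    return np.log(p / (1.0 - p))


class LogitZTransformer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: percent abundances -> logit Z-scores.

    fit learns the zero-replacement value and per-feature logit-scale mean
    and sample SD (ddof=1); transform applies them.  Zero-variance features
    (constant after replacement, e.g. all-zero taxa) are dropped from the
    output and recorded in ``dropped_features_`` with their constant logit.

    Parameters
    ----------
    replacement : float or None
        Percent substituted for exact zeros.  None (default) uses half the
        smallest nonzero percent of the fitted matrix.
    """

    def __init__(self, replacement: float | None = None):
        self.replacement = replacement

    def fit(self, X, y=None):
        X = self._as_frame(X)
        vals = X.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("negative abundances")
        if self.replacement is None:
            nz = vals[vals > 0]
            if nz.size == 0:
                raise ValueError("all-zero matrix")
            self.replacement_ = float(nz.min() / 2.0)
        else:
            self.replacement_ = float(self.replacement)
        logit = _logit_percent(np.where(vals > 0, vals, self.replacement_))
        sds = logit.std(axis=0, ddof=1)
        # constant columns can carry ~1e-15 of floating noise from the mean
        keep = sds > 1e-10 * (1.0 + np.abs(logit.mean(axis=0)))
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.retained_ = self.feature_names_in_[keep]
        self.dropped_features_ = {
            str(c): float(v)
            for c, v in zip(self.feature_names_in_[~keep], logit[0, ~keep])
        }
        self.means_ = pd.Series(logit[:, keep].mean(axis=0), index=self.retained_)
        self.sds_ = pd.Series(sds[keep], index=self.retained_)
        return self

    def transform(self, X) -> pd.DataFrame:
        X = self._as_frame(X)
        sub = X[list(self.retained_)].to_numpy(dtype=float)
        logit = _logit_percent(np.where(sub > 0, sub, self.replacement_))
        z = (logit - self.means_.to_numpy()) / self.sds_.to_numpy()
        return pd.DataFrame(z, index=X.index, columns=self.retained_)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, AbundanceTable):
            return X.values
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))


def logit_zscore(table: AbundanceTable) -> ZScoreMatrix:
    """Zero-replace, logit-transform and pooled-standardize an abundance
    table; returns the Z matrix plus the stored transform parameters."""
    tr = LogitZTransformer().fit(table.values)
    z = tr.transform(table.values)
    return ZScoreMatrix(
        values=z,
        feature_means=tr.means_,
        feature_sds=tr.sds_,
        replacement_value=tr.replacement_,
        dropped_features=tr.dropped_features_,
        group=table.group,
    )


def absent_group_constant(n_absent: int, n_other: int, other_group_mean: float) -> float:
    """Constant Z of a feature that is absent (all zeros, hence constant) in
    one group, implied by pooled standardization: the pooled mean of any
    Z column is 0, so n_a*c + n_b*mean_b = 0."""
    if n_absent <= 0:
        raise ValueError("n_absent must be positive")
    return -n_other * other_group_mean / n_absent


def centroid(
    z: ZScoreMatrix | pd.DataFrame,
    members: list[str],
    group: pd.Series | np.ndarray | None = None,
    absent_constants: dict[str, dict[int, float]] | None = None,
    run_test: bool = True,
) -> CentroidResult:
    """Per-sample centroid (unweighted mean Z) of a member set.

    absent_constants supplies, for members without a retained Z column
    (zero-variance within the data, or known only through per-group
    constants), the constant Z value to impute per group label.
    """
    if not members:
        raise ValueError("empty member set")
    values = z.values if isinstance(z, ZScoreMatrix) else z
    if group is None and isinstance(z, ZScoreMatrix):
        group = z.group
    absent_constants = absent_constants or {}
    cols = []
    for m in members:
        if m in values.columns:
            cols.append(values[m].astype(float))
        elif m in absent_constants:
            if group is None:
                raise ValueError("group labels required to impute absent member")
            g = pd.Series(np.asarray(group), index=values.index)
            cols.append(g.map(absent_constants[m]).astype(float).rename(m))
        else:
            raise KeyError(f"unknown cluster member: {m!r}")
    mat = pd.concat(cols, axis=1)
    per_sample = mat.mean(axis=1)
    group_means: dict[int, float] = {}
    group_sds: dict[int, float] = {}
    res = CentroidResult(members=list(members), per_sample=per_sample,
                         group_means=group_means, group_sds=group_sds)
    if group is not None:
        garr = np.asarray(group)
        for lvl in np.unique(garr):
            vals = per_sample.to_numpy()[garr == lvl]
            group_means[int(lvl)] = float(vals.mean())
            group_sds[int(lvl)] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        if run_test and len(np.unique(garr)) == 2:
            res.statistic, res.p_value, res.test_used = compare_centroids(
                per_sample.to_numpy(), garr
            )
    return res


def compare_centroids(
    values: np.ndarray,
    group: np.ndarray,
    force_test: str | None = None,
) -> tuple[float, float, str]:
    """Two-group comparison of per-sample centroid values.

    Welch's two-sample t-test by default; the Mann-Whitney U test is used
    when either group has zero variance (e.g. a taxon absent from one
    group), where the t statistic is undefined or degenerate.  Override
    with force_test in {"t", "mannwhitney"}.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    lvls = np.unique(group)
    if lvls.size != 2:
        raise ValueError("exactly two groups required")
    a = values[group == lvls[0]]
    b = values[group == lvls[1]]
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs at least 2 samples")
    zero_var = a.std(ddof=1) == 0 or b.std(ddof=1) == 0
    test = force_test or ("mannwhitney" if zero_var else "t")
    if test == "mannwhitney":
        if np.array_equal(np.sort(a), np.sort(b)):
            return 0.0, 1.0, "mannwhitney"
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(stat), float(p), "mannwhitney"
    if np.allclose(a.mean(), b.mean()) and zero_var:
        return 0.0, 1.0, "t"
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p), "t"
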