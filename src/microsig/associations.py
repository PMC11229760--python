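"""Taxon-metabolite association mapping by pairwise Spearman correlation.

Being rank-based, Spearman's rho is identical on raw percents, logit
values or Z-scores (any strictly monotone transform), so the caller may
pass whichever representation is at hand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrelationResult", "spearman_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    rho: pd.DataFrame      # taxa x metabolites
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean mask, p < alpha (or BH-adjusted)
    alpha: float
    fdr: bool = False

    def significant_pairs(self) -> pd.DataFrame:
        """Long-format table of significant (taxon, metabolite, rho, p)."""
        rows = []
        for t in self.rho.index:
            for m in self.rho.columns:
                if bool(self.significant.loc[t, m]):
                    rows.append((t, m, self.rho.loc[t, m], self.p.loc[t, m]))
        return pd.DataFrame(rows, columns=["taxon", "metabolite", "rho", "p"])


def spearman_matrix(
    taxa_values: pd.DataFrame,
    metabolite_values: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> CorrelationResult:
    """All-pairs Spearman correlation between two sample-aligned blocks.

    rho is the Pearson correlation of (average) ranks; the two-sided p
    comes from the t approximation with n-2 degrees of freedom.  Pairs are
    flagged significant when p < alpha (raw by default; BH-adjusted across
    all pairs with ``fdr=True``).  Constant columns yield NaN rho/p and
    are logged."""
    t = _frame(taxa_values)
    m = _frame(metabolite_values)
    if t.shape[0] != m.shape[0]:
        raise ValueError("blocks must have the same samples")
    if isinstance(taxa_values, pd.DataFrame) and isinstance(metabolite_values, pd.DataFrame):
        if not t.index.equals(m.index):
            raise ValueError("sample indices are not aligned")
    n = t.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    rho = np.full((t.shape[1], m.shape[1]), np.nan)
    pval = np.full_like(rho, np.nan)
    t_arr, m_arr = t.to_numpy(dtype=float), m.to_numpy(dtype=float)
    t_const = np.ptp(t_arr, axis=0) == 0
    m_const = np.ptp(m_arr, axis=0) == 0
    for name, mask in (("taxon", t_const), ("metabolite", m_const)):
        for j in np.nonzero(mask)[0]:
            logger.warning("constant %s column %d: rho undefined", name, j)
    t_ranks = np.apply_along_axis(stats.rankdata, 0, t_arr)
    m_ranks = np.apply_along_axis(stats.rankdata, 0, m_arr)
    for i in range(t.shape[1]):
        if t_const[i]:
            continue
        for j in range(m.shape[1]):
            if m_const[j]:
                continue
            r = np.corrcoef(t_ranks[:, i], m_ranks[:, j])[0, 1]
            rho[i, j] = r
            # two-sided p via t approximation, n-2 df
            if abs(r) >= 1.0:
                pval[i, j] = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
                pval[i, j] = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    rho_df = pd.DataFrame(rho, index=t.columns, columns=m.columns)
    p_df = pd.DataFrame(pval, index=t.columns, columns=m.columns)
    if fdr:
        flat = p_df.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        mask = pd.DataFrame((adj < alpha).reshape(p_df.shape),
                            index=p_df.index, columns=p_df.columns)
    else:
        mask = p_df < alpha
    mask = mask.fillna(False).astype(bool)
    return CorrelationResult(rho=rho_df, p=p_df, significant=mask,
                             alpha=float(alpha), fdr=fdr)


def _frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"c{j}" for j in range(X.shape[1])])
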