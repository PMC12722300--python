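"""Donor-level expression aggregation: pseudobulk, z-scored group means,
and per-cluster nonzero-expression percentages."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["pseudobulk", "normalized_donor_means", "group_zscore_means",
           "pct_nonzero"]


def _to_dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def pseudobulk(X, obs: pd.DataFrame, genes, by=("donor_id",)) -> pd.DataFrame:
    """Sum raw counts per group, one profile per grouping key.

    ``X`` is a cells × genes count matrix (dense or scipy sparse), ``obs``
    the per-cell metadata aligned on rows, ``by`` the grouping columns
    (e.g. ``("donor_id",)`` or ``("donor_id", "cluster")``). Total counts
    are conserved exactly; empty groups cannot arise (groups are derived
    from the cells present).
    """
    by = list(by)
    X = _to_dense(X)
    keys = obs[by].apply(tuple, axis=1)
    groups = sorted(keys.unique())
    rows = {g: X[np.asarray(keys == g)].sum(axis=0) for g in groups}
    index = pd.MultiIndex.from_tuples(groups, names=by) if len(by) > 1 \
        else pd.Index([g[0] for g in groups], name=by[0])
    return pd.DataFrame(np.vstack([rows[g] for g in groups]),
                        index=index, columns=list(genes))


def normalized_donor_means(X, obs: pd.DataFrame, genes,
                           donor_col: str = "donor_id",
                           scale_factor: float = 1e4) -> pd.DataFrame:
    """Donor × gene means of library-size-normalised log expression.

    Per cell: counts are scaled to ``scale_factor`` total and log1p
    transformed, then averaged per donor — the donor-level averages that
    feed the z-scored heatmap summaries.
    """
    X = _to_dense(X).astype(float)
    libsize = X.sum(axis=1, keepdims=True)
    libsize[libsize == 0] = 1.0
    logn = np.log1p(X / libsize * scale_factor)
    donors = sorted(obs[donor_col].unique())
    rows = [logn[np.asarray(obs[donor_col] == d)].mean(axis=0)
            for d in donors]
    return pd.DataFrame(rows, index=pd.Index(donors, name=donor_col),
                        columns=list(genes))


def group_zscore_means(donor_means: pd.DataFrame,
                       groups: pd.Series) -> pd.DataFrame:
    """Z-score each gene across donors, then average per group.

    ``donor_means`` is donor × gene; ``groups`` maps donor → group.
    Genes with zero variance across donors are set to all-zero z-scores
    with a warning (they carry no contrast).
    """
    mu = donor_means.mean(axis=0)
    sd = donor_means.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) set to 0",
                      stacklevel=2)
        sd = sd.replace(0, 1.0)
    z = (donor_means - mu) / sd
    z.loc[:, np.asarray(flat)] = 0.0
    return z.groupby(groups.reindex(z.index)).mean()


def pct_nonzero(X, obs: pd.DataFrame, genes, gene: str,
                by=("cluster", "sample_id")) -> pd.Series:
    """Percentage of cells with nonzero expression of ``gene`` per group."""
    genes = list(genes)
    if gene not in genes:
        raise KeyError(f"gene {gene!r} not in matrix")
    col = _to_dense(X)[:, genes.index(gene)]
    df = obs[list(by)].copy()
    df["_nz"] = col > 0
    return df.groupby(list(by))["_nz"].mean() * 100.0
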