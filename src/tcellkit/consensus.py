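"""Cross-study fold-change quantile binning and consensus gene ranking.

Each study's genes are ranked by log fold change (T1D vs healthy) and the
ranks converted to 20-quantiles — bin 1 holds the genes most upregulated
in healthy donors, bin 20 the genes most upregulated in T1D. Genes that
sit in an extreme bin consistently across studies are the cross-study
consensus signature. Two consistency scores are reported: the mean bin
across observed studies (primary) and the count of studies in which the
gene falls in the extreme bin (alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["rank_to_quantiles", "consensus", "ConsensusResult"]


def rank_to_quantiles(fold_changes: pd.Series, k: int = 20) -> pd.Series:
    """Convert one study's fold changes to quantile bins 1..k.

    Genes are sorted ascending by fold change (most healthy-upregulated
    first); ties are broken by gene name so the result is independent of
    input row order. Bin sizes differ by at most one. Missing values are
    dropped before binning.
    """
    fc = fold_changes.dropna()
    if len(fc) < k:
        raise ValueError(f"need >= {k} genes with values, got {len(fc)}")
    order = sorted(fc.index, key=lambda g: (fc[g], g))
    n = len(order)
    bins = pd.Series(
        [int(i * k / n) + 1 for i in range(n)],
        index=order, name=fold_changes.name, dtype=int)
    return bins.reindex(fc.index)


@dataclass
class ConsensusResult:
    """Per-gene quantile bins and cross-study consensus scores."""

    bins: pd.DataFrame          # gene × study, NaN where unobserved
    scores: pd.DataFrame        # mean_bin, n_extreme_low/high, n_studies
    healthy_consistent: list[str] = field(default_factory=list)
    t1d_consistent: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def consensus(matrix: pd.DataFrame, k: int = 20,
              min_studies: int = 2) -> ConsensusResult:
    """Bin every study and rank genes by cross-study consistency.

    ``matrix`` is gene × study log fold changes; NaN marks genes absent
    from a study's gene universe (excluded from that study's ranking,
    not imputed). The consensus score of a gene is its mean bin over the
    studies where it was observed; genes seen in fewer than
    ``min_studies`` studies are excluded and reported. Direction lists
    are sorted ascending (healthy-consistent, toward bin 1) and
    descending (T1D-consistent, toward bin k), ties broken by gene name.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 studies")
    bins = pd.DataFrame(
        {study: rank_to_quantiles(matrix[study], k=k)
         for study in matrix.columns},
        index=matrix.index)
    n_obs = bins.notna().sum(axis=1)
    mean_bin = bins.mean(axis=1)
    scores = pd.DataFrame({
        "mean_bin": mean_bin,
        "n_extreme_low": (bins == 1).sum(axis=1),
        "n_extreme_high": (bins == k).sum(axis=1),
        "n_studies": n_obs,
    })
    keep = scores.index[n_obs >= min_studies]
    excluded = sorted(scores.index.difference(keep))
    kept = scores.loc[keep]
    asc = sorted(keep, key=lambda g: (kept.at[g, "mean_bin"], g))
    desc = sorted(keep, key=lambda g: (-kept.at[g, "mean_bin"], g))
    return ConsensusResult(
        bins=bins,
        scores=scores,
        healthy_consistent=asc,
        t1d_consistent=desc,
        excluded=excluded,
    )
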