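"""HLA risk-haplotype flagging and genotype–expression confound modelling.

The two classical T1D risk haplotypes are flagged from unphased two-field
genotypes, and the per-locus gaussian GLM regresses dataset-scaled
expression of a gene (BTN3A2 in the motivating study) on study, disease
status and allele dosage simultaneously, separating allele effects from
the disease-status confound.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "flag_risk_haplotypes",
    "scale_expression",
    "fit_locus_glm",
]

# Allele triplets defining the risk haplotypes (two-field resolution).
DR3_DQ2 = {"DRB1": "DRB1*03:01", "DQA1": "DQA1*05:01", "DQB1": "DQB1*02:01"}
DR4_DQ8 = {"DRB1": "DRB1*04:01", "DQA1": "DQA1*03:01", "DQB1": "DQB1*03:02"}


def flag_risk_haplotypes(genotype: dict[str, tuple[str, str]]
                         ) -> dict[str, bool | None]:
    """Flag DR3-DQ2 and DR4-DQ8 carriage from an unphased genotype.

    ``genotype`` maps locus → (allele1, allele2) at two-field resolution.
    A haplotype is flagged when all three of its alleles are present
    anywhere in the genotype (phase is unavailable from short-read
    typing, so cis/trans cannot be distinguished). A required locus that
    is untyped yields ``None`` for the affected flag.
    """
    flags: dict[str, bool | None] = {}
    for name, triplet in (("DR3_DQ2", DR3_DQ2), ("DR4_DQ8", DR4_DQ8)):
        missing = [loc for loc in triplet if loc not in genotype]
        if missing:
            flags[name] = None
            continue
        flags[name] = all(
            allele in genotype[locus] for locus, allele in triplet.items()
        )
    return flags


def scale_expression(records: pd.DataFrame,
                     expression_col: str = "expression",
                     dataset_col: str = "dataset") -> pd.Series:
    """Scale raw expression to [-1, 1] within each dataset.

    The lowest-expressing donor of a dataset maps to −1 and the highest
    to +1 (x → 2(x−min)/(max−min) − 1), making expression comparable
    across datasets with different units. A dataset with constant
    expression is mapped to all zeros with a warning.
    """
    def _scale(x: pd.Series) -> pd.Series:
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(
                f"constant expression in dataset {x.name!r}; scaled to 0",
                stacklevel=2)
            return pd.Series(0.0, index=x.index)
        return 2.0 * (x - lo) / (hi - lo) - 1.0

    grouped = records.groupby(dataset_col, group_keys=False)[expression_col]
    scaled = grouped.apply(_scale)
    scaled.name = "scaled_expression"
    return scaled.reindex(records.index)


def allele_dosage(records: pd.DataFrame, locus: str) -> pd.DataFrame:
    """0/1/2 dosage matrix for every allele observed at ``locus``.

    Expects columns ``{locus}_1`` and ``{locus}_2``. Rows sum to 2.
    """
    a1, a2 = records[f"{locus}_1"], records[f"{locus}_2"]
    alleles = sorted(set(a1) | set(a2))
    dosage = pd.DataFrame(
        {al: (a1 == al).astype(int) + (a2 == al).astype(int)
         for al in alleles},
        index=records.index)
    return dosage


def fit_locus_glm(records: pd.DataFrame, locus: str,
                  encoding: str = "dosage",
                  expression_col: str = "scaled_expression",
                  status_col: str = "status",
                  dataset_col: str = "dataset",
                  drop_allele: str | None = None) -> pd.DataFrame:
    """Per-locus gaussian GLM of scaled expression.

    Ordinary least squares of scaled expression on study indicators, a
    disease-status indicator and per-allele genotype covariates at one
    locus. Alleles are coded additively (dosage 0/1/2) by default, or as
    presence/absence with ``encoding='dominant'``. The rarest allele's
    column is dropped (dosages sum to 2, so the full set is collinear
    with the intercept); ``drop_allele`` overrides which allele serves
    as the reference, so a focal allele's coefficient can always be read
    directly. Returns a tidy table of coefficient, standard
    error and two-sided p per term; terms that remain inestimable after
    the drop are reported with NaN.
    """
    if encoding not in ("dosage", "dominant"):
        raise ValueError(f"unknown encoding {encoding!r}")
    dosage = allele_dosage(records, locus)
    if dosage.shape[1] < 2:
        raise ValueError(f"need >= 2 alleles at {locus}, "
                         f"got {dosage.shape[1]}")
    if encoding == "dominant":
        dosage = (dosage > 0).astype(int)
    # drop the rarest allele (ties broken by allele name for determinism)
    # unless an explicit reference allele is requested
    if drop_allele is None:
        counts = dosage.sum(axis=0)
        rarest = counts.sort_values(kind="stable").index[0]
    else:
        if drop_allele not in dosage.columns:
            raise ValueError(f"allele {drop_allele!r} not observed at "
                             f"{locus}")
        rarest = drop_allele
    dosage = dosage.drop(columns=[rarest])

    X = pd.DataFrame(index=records.index)
    X["Intercept"] = 1.0
    datasets = sorted(records[dataset_col].unique())
    for ds in datasets[1:]:
        X[f"study[{ds}]"] = (records[dataset_col] == ds).astype(float)
    status = records[status_col]
    if status.dtype == object:
        status = (status == "T1D").astype(float)
    X["status[T1D]"] = status.astype(float)
    for al in dosage.columns:
        X[f"allele[{al}]"] = dosage[al].astype(float)

    y = records[expression_col].astype(float)
    rank = np.linalg.matrix_rank(X.values)
    fit = sm.OLS(y, X).fit()
    table = pd.DataFrame({
        "term": X.columns,
        "coef": fit.params.values,
        "se": fit.bse.values,
        "p_value": fit.pvalues.values,
    })
    if rank < X.shape[1]:
        # flag terms whose removal does not reduce rank: inestimable
        for i, col in enumerate(X.columns):
            sub = X.drop(columns=[col])
            if np.linalg.matrix_rank(sub.values) == rank:
                table.loc[i, ["coef", "se", "p_value"]] = np.nan
    table.attrs["dropped_allele"] = rarest
    table.attrs["encoding"] = encoding
    return table
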