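# tcellkit

Statistical toolkit for longitudinal single-cell T cell studies of
pediatric type 1 diabetes (T1D): paired-chain TCR clonotype analysis,
CDR3β physicochemical contrasts, Bayesian compositional modelling of
T cell subsets, cross-study fold-change consensus, HLA
genotype–expression confound modelling, and clinical index derivations.
It is aimed at computational immunologists who have per-cell clonotype
tables (AIRR Rearrangement TSV), per-sample subset counts, per-study
fold-change tables and HLA genotypes, and who need the analysis layer
between those tables and the figures.

Because the patient-level data such studies rest on are
access-protected, the package ships first-class synthetic-data
generators (`tcellkit.simulate`) that emulate every input family with
planted, recoverable effects — cohort structure, clonally expanded
repertoires with within-donor persistence, negative-binomially
distributed subset counts, fold-change matrices with consistent genes,
and allele-linked expression confounded with disease status. All
statistical claims in the test suite are recovery claims against that
planted truth.

## The models at the core

**Clone definition.** Cells are clones when their CDR3β nucleotide
junctions are identical and their TCRα sets match, with a tolerance for
dual-α cells: a single detected α matching one of a pair counts (the
second α taken as not detected). The relation is non-transitive, so
clones are connected components, with ambiguous bridged components
flagged. Repertoire overlap is directional on unique amino-acid CDR3s:
overlap of donor A with B = 100·|A∩B|/|A|, grouped into HD–HD, HD–T1D,
T1D–T1D and within-donor T1-vs-T0 contrasts.

**CDR3β biophysics.** Boman index, Eisenberg hydrophobic moment (100°)
and Kyte–Doolittle hydrophobicity, contrasted either pooled (each
sequence weighted by its total occurrence count — a clone seen 50, 10
and 1 times in three donors counts 61 times) with Mann–Whitney p and a
Hodges–Lehmann shift estimate with 95% CI, or per donor (unweighted
mean over unique sequences).

**Composition.** Counts of Level-3 subsets follow a negative-binomial
GLMM with a log(total) offset,

    log μ = log T_s + β0 + β_group + β_pop + u_L2[q(p),g] + u_L3[p,g],
    log φ_p = γ0 + γ_L2[q(p)] + v_p,

with correlated sample-type random effects per hierarchy level (LKJ(1)
prior), brms-default priors, and shape modelled per population. The
posterior is sampled by Hamiltonian Monte Carlo with an analytic
gradient and dense mass-matrix adaptation; split-R̂/ESS are reported
and fits with R̂ > 1.05 are flagged. Frequentist companions: unpaired
Mann–Whitney (healthy vs T1D T0) and paired Wilcoxon (T0 vs T1).

**Consensus.** Per-study fold-change ranks are converted to
20-quantiles (bin 1 = healthy-up, bin 20 = T1D-up); genes are ranked by
mean bin across studies to find cross-study-consistent signatures.

**HLA.** DR3-DQ2 / DR4-DQ8 risk-haplotype flags from unphased two-field
genotypes, and a per-locus gaussian GLM of (dataset-scaled) expression
on study + disease status + allele dosage that separates allele effects
from the disease-status confound.

**Clinical.** IDAA1c = HbA1c + 4 × insulin dose (U/kg/24h), partial
remission (IDAA1c < 9), DKA (pH < 7.3 and/or bicarbonate < 15 mEq/L).

See `docs/methods.md` for assumptions, priors, parameterisations and
limitations.

## Worked example

```python
from tcellkit.repertoire import cells_from_table, overlap_contrasts
from tcellkit.simulate import (CohortSpec, RepertoireSimParams,
                               gen_cohort, gen_repertoire)

cohort = gen_cohort(CohortSpec(n_healthy=4, n_t1d=5, seed=3))
cells_df, _ = gen_repertoire(cohort, RepertoireSimParams(
    n_clones_per_donor=80, persistence_rate=0.5, public_rate=0.001,
    seed=3))
cells = cells_from_table(cells_df)
groups = {d: ("HD" if d.startswith("HD") else "T1D")
          for d in cells_df["donor_id"].unique()}
print(overlap_contrasts(cells, groups)
      .groupby("contrast")["overlap_pct"].median().round(2))
```

prints

```
contrast
HD-HD             0.00
HD-T1D            0.00
SelfT1-SelfT0    51.25
T1D-T1D           0.00
```

— with half of each donor's clones persisting from diagnosis to one
year, the median within-donor T1-vs-T0 overlap is ~51% of unique CDR3β
amino-acid sequences, while repertoires stay essentially private
between donors (medians 0%). The `examples/` directory holds one short
script per capability (clones and expansion, overlap, biophysics,
composition model, consensus + HLA), each printing the numbers it
computes and a line on what they mean.

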