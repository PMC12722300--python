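# Methods

`tcellkit` implements the bespoke statistical layer of a longitudinal
single-cell T cell receptor (TCR) and composition study of pediatric
type 1 diabetes (T1D): paired-chain clone definition, repertoire
overlap, CDR3β physicochemical contrasts, a Bayesian negative-binomial
model of subset composition, cross-study fold-change consensus, HLA
genotype–expression confound modelling, and clinical index derivations.
Every analysis is exercised end-to-end on synthetic data with planted
effects, so the statistical machinery is testable without the
access-protected patient data it was designed for.

## Clone definition (`repertoire`)

Cells are matched into clones on the **nucleotide** sequences of their
CDR3 junctions. Two cells are the same clone when their CDR3β nt are
identical and (i) their full TCRα sets are identical, (ii) the single
detected TCRα of one cell is among the other cell's two (a second α can
escape detection), or (iii) both cells lack a detected TCRα. Because
rule (ii) makes the relation non-transitive (a dual-α cell can bridge
two single-α cells with different α chains), clones are taken as
connected components of the relation. This is deterministic,
order-independent, and the most inclusive reading of the matching rule;
components that contain a mutually incompatible pair are flagged in the
output rather than split, since no principled split exists without
additional evidence. Cells without a productive TCRβ are excluded — the
clone key requires the β junction. The V(D)J doublet rule (>2 TCRα or
>1 productive TCRβ) is applied upstream as QC.

Repertoire **overlap** operates on unique **amino-acid** CDR3 sequences
per donor and is directional: overlap of donor A with donor B is
100·|A∩B|/|A|. One value is reported per ordered pair, grouped into
HD–HD, HD–T1D and T1D–T1D contrasts; the self contrast is the overlap
of a donor's T1 set with their T0 set. Both the chain (α/β) and the
sequence level (aa/nt) are parameters; aa is the default for overlap,
nt for clone matching.

CDR3β length distributions are per-donor frequencies over unique
sequences; group comparison is per-length two-tailed Mann–Whitney with
no multiplicity correction (each length is read as one panel of a
distribution figure, not as a family of tests).

## CDR3 biophysics (`biophysics`)

Three per-residue indices with their classical scales, shipped as
in-package tables: Boman index (mean per-residue protein-binding
contribution derived from Radzicka–Wolfenden transfer free energies,
kcal/mol; proline 0 by convention), Eisenberg hydrophobic moment
(magnitude of the phase-weighted hydrophobicity sum at 100° helical
periodicity, divided by length; computed over the full sequence by
default, sliding-window mode available but off), and Kyte–Doolittle
hydrophobicity (mean hydropathy). Sums are accumulated in canonical
residue order so the two mean-type indices are bitwise
reversal-invariant. Ambiguity codes (B/J/X/Z) are rejected by default
(`on_invalid="skip"` drops them) because no scale values exist.

Two contrast modes:

* **Pooled, occurrence-weighted** — each unique sequence is replicated
  by its total occurrence count across the dataset (a clone seen 50, 10
  and 1 times in three donors counts 61 times), then a two-tailed
  Mann–Whitney test and a Hodges–Lehmann location estimate (median of
  all pairwise between-group differences) with 95% CI. The CI is the
  exact rank interval (null distribution of the Mann–Whitney U by the
  counting recurrence) for n+m ≤ 50, the normal approximation above;
  all-identical pairwise differences yield a zero-width interval.
* **Per-donor** — each donor summarised by the unweighted mean over
  their unique sequences, removing clonal-expansion weighting; groups
  compared by Mann–Whitney on the donor means.

Note that occurrence weighting treats every occurrence of a clone as an
independent observation; since occurrences of one clone share a
sequence, the weighted test and CI overstate precision relative to the
clone-level sampling variability. This is inherent to the pooled
analysis (the per-donor mode is the robust companion); the CI's nominal
coverage holds on unique-sequence pools with unit weights.

## Composition model (`composition`)

Counts y of Level-3 population p (Level-2 parent q(p)) in sample s of
type g ∈ {healthy, T1D_T0, T1D_T1}:

    y ~ NB(mean μ, shape φ_p),   var = μ + μ²/φ
    log μ = log(total_s) + β0 + β_group[g] + β_pop[p]
            + u_L2[q(p), g] + u_L3[p, g]
    log φ_p = γ0 + γ_L2[q(p)] + v_p

Random effects of the sample type are grouped by both hierarchy levels:
each level of a grouping factor carries one 3-vector (one entry per
sample type) with a full covariance — per-entry SDs and an LKJ(1)
correlation. A separate random intercept per Level-3 population would
be confounded with the fixed Level-3 effects; the 3-vector already
absorbs level shifts, so this is the identifiable reading of
"random effects of the sample type grouped by Level 2 and Level 3".
Priors are the brms defaults: student-t(3, loc, 2.5) on β0 with loc the
median of the link-transformed response (median of log((y+0.5)/total),
recorded in the fit output — it is a data-derived convention, not a
constant), student-t(3, 0, 2.5) on γ0, improper flat on all fixed
effects (a proper wide-normal fallback is available and recorded when
switched on), half student-t(3, 0, 2.5) on random-effect SDs, LKJ(1)
on correlations. Reference levels: group = healthy, population = first
alphabetically.

**Computation.** The posterior is sampled by fixed-path-length
Hamiltonian Monte Carlo with an analytic gradient of the full log
posterior (negative-binomial terms via digamma, chain rule through the
non-centered random-effect transform u = diag(σ)·L·z and through the
tanh-parameterised canonical partial correlations, whose transformed
prior reproduces LKJ exactly). Chains run in lockstep through a
vectorised log-density, start in a small cloud around an L-BFGS
posterior mode, adapt their step size by dual averaging (target
acceptance 0.8–0.9) and estimate a dense mass matrix from the middle
half of warmup — the dense metric is what decorrelates the linear ridge
between the flat-prior group effects and the random-effect block.
Defaults: 4 chains × 1000 draws after 1000 warmup steps, 40 ± 2
leapfrog steps. Convergence is gated, not assumed: split-R̂ and bulk
ESS (arviz) are reported per parameter, non-finite proposals count as
divergences, and any fit with max R̂ > 1.05 is flagged with a warning.
Group contrasts per population (β_group[g] + Δu_L2 + Δu_L3 relative to
healthy, on the log scale) are summarised with posterior means and
central 95% intervals.

The frequentist companion is per-population two-tailed Mann–Whitney
(healthy vs T1D at T0) on count/total frequencies and the paired
two-tailed Wilcoxon signed-rank (T0 vs T1) restricted to donors with
both timepoints — a donor who withdrew before T1 contributes everywhere
except the paired test. No multiplicity correction.

## Cross-study consensus (`consensus`)

Per study, genes are ranked ascending by log fold change (T1D vs
healthy) and the ranks converted to 20-quantiles: bin 1 = most
upregulated in healthy, bin 20 = most upregulated in T1D; bin sizes
differ by at most one; ties break by gene name so the result does not
depend on input row order. Missing genes are excluded from that study's
ranking, not imputed (studies have different gene universes). The
consensus score is the mean bin over observed studies (primary; the
count of studies in the extreme bin is reported as an alternative, as
"most consistently enriched" admits both readings), restricted to genes
seen in a configurable minimum number of studies; direction lists sort
ascending (healthy-consistent) and descending (T1D-consistent).

## HLA model (`hla`)

Risk haplotypes are flagged from unphased two-field genotypes: DR3-DQ2
requires DRB1\*03:01, DQA1\*05:01 and DQB1\*02:01 all present; DR4-DQ8
requires DRB1\*04:01, DQA1\*03:01 and DQB1\*03:02. Short-read typing
gives no phase, so presence anywhere in the genotype is used — a
documented limitation (cis/trans cannot be distinguished).

Expression of the focal gene is min-max scaled to [−1, 1] within each
dataset (lowest donor → −1, highest → +1) to make heterogeneous units
comparable; a constant-expression dataset maps to 0 with a warning
rather than erroring. The per-locus gaussian GLM is ordinary least
squares of expression on study indicators + disease status + per-allele
dosage (0/1/2; dominant presence/absence coding available — the
additive choice is a default, not a claim). Dosages sum to 2, so one
allele column (the rarest by default, overridable) is dropped as
reference; remaining rank deficiencies are reported as inestimable
terms rather than silently pseudo-inverted. Note that recovery tests of
planted effects run on the generator's native expression scale: min-max
scaling rescales coefficients, so "effect = 1 per dosage unit" is only
meaningful before harmonisation.

## Clinical indices (`clinical`)

IDAA1c = HbA1c(%) + 4 × insulin dose (U/kg/24h); partial remission is
IDAA1c < 9 (strict). DKA is pH < 7.3 and/or bicarbonate < 15 mEq/L
(strict; either measurement alone suffices, both missing → missing
flag). Boundary values are excluded by the strict inequalities —
a literal reading of the definitions.

## Aggregation utilities (`summaries`)

Pseudobulk profiles are exact sums of raw counts per donor (or
donor × cluster); totals are conserved. Heatmap summaries z-score each
gene across donor-level means of library-size-normalised (10⁴ scale
factor, log1p) expression, then average per group; zero-variance genes
yield zero rows with a warning. Percent-nonzero summaries are
100 × (cells with count > 0)/(cells in group) per cluster × sample.

## Synthetic data (`simulate`)

The generators define the study conditions: a default cohort of 13
healthy donors (single sample) and 30 T1D donors sampled at diagnosis
(T0) and ~1 year (T1). What they emulate, and what they do not:

* **Repertoires** — clone sizes follow a truncated power law (exponent
  2.5, max 64), reproducing the expanded-effector vs unexpanded-naive
  contrast; CDR3 lengths are a clipped normal on 8–22 aa (mean 14,
  sd 1.8); within-donor T0→T1 clone persistence and a small public
  pool plant the overlap structure; a configurable residue-sampling
  tilt along the (standardised) Boman scale plants biophysical group
  differences. Nucleotide junctions are arbitrary codon spellings fixed
  per clone per donor, so nt identity implies aa identity but not
  conversely — exactly the property that separates nt-level clone
  matching from aa-level overlap. No V(D)J recombination model, UMIs or
  library chemistry; empirical clone-size/length laws are not published
  numerically, so the defaults are realistic placeholders and fully
  configurable.
* **Subset counts** — drawn from the same NB hierarchical law the model
  fits (baseline log-proportions spanning ~20-fold and summing to 0.95,
  NB totals around 5000 cells), so parameter recovery is a well-posed
  oracle test. Real data violate the model in ways the generator does
  not (annotation errors, donor-level correlations beyond the modelled
  random effects).
* **Fold changes** — planted consistent genes at ±3 log-units over
  study noise, with per-study missingness emulating differing gene
  universes.
* **HLA/expression** — expression linear in allele dosage, study and
  status, with disease status deliberately correlated with the risk
  allele (the confound the GLM must untangle).
* **Clinical variables** — uniform within plausible new-onset ranges;
  they feed threshold rules only, so covariance structure is not
  modelled.

Every generator is deterministic under a fixed seed, and every table
carries hidden ground-truth columns (or a JSON sidecar) used only by
tests. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated generative assumptions — not
robustness to the annotation, batch and selection artefacts of real
cohorts.

## Problem sizes used in tests

The multi-fit recovery study runs 20 datasets of 40 samples × 10
populations at 4 chains × 500 draws after 1000 warmup steps (~33 s per
fit); the acceptance script runs 10 refits at the same settings.
Overlap patterns use 50 cohorts of 9 donors × 80 clones;
consensus uses 20 replicates of 2000 genes × 5 studies; HLA separation
uses 50 simulations of 200 donors. These sizes give stable pass/fail
behaviour for the stochastic checks while keeping the default test run
fast.

## Known limitations

* Fixed-path HMC, not NUTS: trajectory length is a tuning constant
  (jittered ±2); the funnel-shaped tails of the random-effect SD
  posteriors mix more slowly than the contrasts of interest.
* Hierarchical shrinkage biases single-population effects toward the
  group mean, so 95% intervals for an effect planted on one population
  cover slightly below nominal — a property of partial pooling, not of
  the sampler.
* Haplotype flags are unphased; dual-α bridging components are flagged,
  not resolved; the consensus score's "consistency" definition is a
  choice between two natural readings, both reported.
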