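"""Bayesian negative-binomial composition analysis of T cell subsets.

Simulates per-sample counts over a two-level population hierarchy with a
planted +0.7 log-rate increase of central-memory cells in T1D at
diagnosis, fits the hierarchical NB model by HMC, and prints the
group-contrast posterior next to the frequentist tests.
"""

from tcellkit.composition import build_design, fit_bayes, frequentist_compare
from tcellkit.simulate import (CohortSpec, CompositionSimParams, gen_cohort,
                               gen_subset_counts)

cohort = gen_cohort(CohortSpec(n_healthy=14, n_t1d=13, seed=7))
counts, truth = gen_subset_counts(cohort, CompositionSimParams(
    group_effects={("T1D_T0", "Tcm"): 0.7}, seed=7))

design = build_design(counts)
fit = fit_bayes(design, chains=4, draws=500, warmup=1000, seed=7,
                n_leapfrog=40, target_accept=0.9)
print(f"max split-Rhat {fit.diagnostics['max_rhat']:.3f}, "
      f"divergences {fit.diagnostics['n_divergent']}, "
      f"intercept prior location {fit.intercept_prior_loc:.2f}")

cc = fit.contrasts.set_index(["population", "contrast"])
for pop in ("Tcm", "Treg"):
    row = cc.loc[(pop, "T1D_T0-healthy")]
    print(f"{pop:6s} T1D_T0 vs healthy: {row['mean']:+.2f} "
          f"[{row['q2.5']:+.2f}, {row['q97.5']:+.2f}] (log scale)")

freq = frequentist_compare(counts).set_index("population")
print("Mann-Whitney p (healthy vs T1D_T0): "
      f"Tcm {freq.loc['Tcm', 'p_unpaired']:.4f}, "
      f"Treg {freq.loc['Treg', 'p_unpaired']:.4f}")
# The planted Tcm effect should show a clearly positive posterior
# interval (truth +0.7 on the log scale) while unperturbed populations
# straddle zero; the rank test agrees in direction.
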