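"""Proportions, frequentist tests, model design and the NB posterior."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcellkit.composition import (
    CompositionPriors,
    GROUPS,
    NBHierarchicalModel,
    build_design,
    fit_bayes,
    frequentist_compare,
    nb_loglik,
    proportions,
)
from tcellkit.simulate import (
    CohortSpec,
    CompositionSimParams,
    gen_cohort,
    gen_subset_counts,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "donor_id", "group",
                                       "population", "parent", "count",
                                       "total"])


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def test_proportions_arithmetic():
    tbl = make_table([
        ("s1", "d1", "healthy", "A", "P", 10, 40),
        ("s1", "d1", "healthy", "B", "P", 30, 40),
        ("s2", "d2", "healthy", "A", "P", 0, 50),
    ])
    out = proportions(tbl)
    assert list(out["frequency"][:2]) == pytest.approx([0.25, 0.75])
    assert out["frequency"].iloc[2] == 0.0
    zero_total = make_table([("s3", "d3", "healthy", "A", "P", 0, 0)])
    assert np.isnan(proportions(zero_total)["frequency"].iloc[0])


# ---------------------------------------------------------------------------
# Frequentist comparisons
# ---------------------------------------------------------------------------

def test_mirrored_groups_give_p_one():
    rows = []
    for i, f in enumerate([5, 10, 15]):
        rows.append((f"h{i}", f"h{i}", "healthy", "A", "P", f, 100))
        rows.append((f"t{i}", f"t{i}", "T1D_T0", "A", "P", f, 100))
    res = frequentist_compare(make_table(rows))
    assert res["p_unpaired"].iloc[0] == pytest.approx(1.0)


def exact_signed_rank_p(diffs):
    """Enumeration oracle: two-sided exact signed-rank p for small n."""
    diffs = np.asarray(diffs, float)
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    stat_all = []
    for signs in itertools.product([0, 1], repeat=n):
        stat_all.append(sum(r for s, r in zip(signs, ranks) if s))
    stat_all = np.array(stat_all)
    mu = stat_all.mean()
    p = np.mean(np.abs(stat_all - mu) >= abs(w_obs - mu) - 1e-12)
    return min(1.0, p)


def test_paired_test_matches_exact_enumeration():
    rng = np.random.default_rng(4)
    n = 8
    rows = []
    base = rng.uniform(0.1, 0.3, size=n)
    shift = base + rng.normal(0.05, 0.02, size=n)  # positive-trend shift
    for i in range(n):
        rows.append((f"d{i}_T0", f"d{i}", "T1D_T0", "A", "P",
                     int(base[i] * 1000), 1000))
        rows.append((f"d{i}_T1", f"d{i}", "T1D_T1", "A", "P",
                     int(shift[i] * 1000), 1000))
    # two healthy donors so the unpaired arm is defined
    rows.append(("h1", "h1", "healthy", "A", "P", 200, 1000))
    rows.append(("h2", "h2", "healthy", "A", "P", 220, 1000))
    res = frequentist_compare(make_table(rows))
    diffs = shift * 1000 // 1 / 1000 - base * 1000 // 1 / 1000
    d = (np.floor(shift * 1000) - np.floor(base * 1000)) / 1000
    expected = exact_signed_rank_p(d)
    assert res["p_paired"].iloc[0] == pytest.approx(expected, abs=1e-8)


def test_donor_missing_t1_excluded_from_paired_test():
    rows = []
    for i in range(5):
        rows.append((f"d{i}_T0", f"d{i}", "T1D_T0", "A", "P", 100 + i, 1000))
        if i < 4:  # one donor withdrew before T1
            rows.append((f"d{i}_T1", f"d{i}", "T1D_T1", "A", "P",
                         150 + i, 1000))
    rows.append(("h1", "h1", "healthy", "A", "P", 90, 1000))
    rows.append(("h2", "h2", "healthy", "A", "P", 95, 1000))
    res = frequentist_compare(make_table(rows))
    assert res["n_paired_donors"].iloc[0] == 4


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def test_design_reference_levels_and_offset():
    rows = []
    pops = [("A", "P1"), ("B", "P1"), ("C", "P2"), ("D", "P2"),
            ("E", "P2")]
    for g, d in [("healthy", "h1"), ("T1D_T0", "t1"), ("T1D_T1", "t1")]:
        for p, par in pops:
            rows.append((f"{d}_{g}", d, g, p, par, 10, 500))
    design = build_design(make_table(rows))
    assert design.n_pops == 5
    assert design.n_parents == 2
    # treatment coding: 1 intercept + 2 group + 4 population columns
    assert design.reference_group == "healthy"
    assert design.reference_population == "A"
    model = NBHierarchicalModel(design)
    assert model.pmap.slices["beta_group"].stop - \
        model.pmap.slices["beta_group"].start == 2
    assert model.pmap.slices["beta_pop"].stop - \
        model.pmap.slices["beta_pop"].start == 4
    assert np.allclose(design.offset, np.log(500.0))


def test_design_single_parent_flagged():
    rows = [("s1", "d1", "healthy", "A", "P", 5, 100),
            ("s1", "d1", "healthy", "B", "P", 5, 100)]
    with pytest.warns(UserWarning):
        design = build_design(make_table(rows))
    assert design.single_parent


def test_design_inconsistent_hierarchy_error():
    rows = [("s1", "d1", "healthy", "A", "P1", 5, 100),
            ("s2", "d2", "healthy", "A", "P2", 5, 100)]
    with pytest.raises(ValueError):
        build_design(make_table(rows))


# ---------------------------------------------------------------------------
# NB likelihood and priors
# ---------------------------------------------------------------------------

def test_nb_loglik_matches_scipy_pmf_oracle(rng):
    for _ in range(100):
        n = rng.integers(3, 30)
        y = rng.integers(0, 200, size=n)
        mu = rng.uniform(0.5, 100, size=n)
        phi = rng.uniform(0.2, 50, size=n)
        ours = nb_loglik(y, np.log(mu), np.log(phi))
        # scipy parameterisation: n = phi, p = phi/(phi+mu)
        oracle = stats.nbinom.logpmf(y, phi, phi / (phi + mu)).sum()
        assert ours == pytest.approx(oracle, abs=1e-8)


def test_intercept_prior_reproduces_student_t():
    cohort = gen_cohort(CohortSpec(n_healthy=4, n_t1d=4, seed=0))
    tbl, _ = gen_subset_counts(cohort, CompositionSimParams(seed=0))
    model = NBHierarchicalModel(build_design(tbl))
    rng = np.random.default_rng(2)
    draws = model.sample_prior(40000, rng)["theta"]
    b0 = draws[:, model.pmap.slices["beta0"]].ravel()
    loc, scale, df = model.intercept_loc, 2.5, 3.0
    # compare central quantiles with the analytic student-t
    for q in (0.1, 0.25, 0.5, 0.75, 0.9):
        expected = loc + scale * stats.t.ppf(q, df)
        assert np.quantile(b0, q) == pytest.approx(expected, abs=0.12)
    # SD prior draws are half-t distributed on the natural scale
    sds = np.exp(draws[:, model.pmap.slices["log_sd_l2"]]).ravel()
    assert np.median(sds) == pytest.approx(
        scale * stats.t.ppf(0.75, df), abs=0.1)


def test_log_prob_gradient_consistency(rng):
    cohort = gen_cohort(CohortSpec(n_healthy=3, n_t1d=3, seed=1))
    tbl, _ = gen_subset_counts(cohort, CompositionSimParams(seed=1))
    model = NBHierarchicalModel(build_design(tbl))
    D = model.pmap.n_params
    x = rng.normal(0, 0.3, (2, D))
    lp, g = model.log_prob_and_grad(x)
    assert np.allclose(lp, model.log_prob(x))
    h = 1e-6
    for ci in range(2):
        pts = x[ci] + np.vstack([h * np.eye(D), -h * np.eye(D)])
        vals = model.log_prob(pts)
        fd = (vals[:D] - vals[D:]) / (2 * h)
        assert np.allclose(fd, g[ci], rtol=1e-4, atol=1e-5)


def test_proper_prior_fallback_changes_density():
    cohort = gen_cohort(CohortSpec(n_healthy=3, n_t1d=3, seed=1))
    tbl, _ = gen_subset_counts(cohort, CompositionSimParams(seed=1))
    design = build_design(tbl)
    flat = NBHierarchicalModel(design)
    proper = NBHierarchicalModel(
        design, CompositionPriors(fixed_effect_sd=5.0))
    x = np.zeros((1, flat.pmap.n_params))
    x[0, flat.pmap.slices["beta_group"]] = 2.0
    assert proper.log_prob(x)[0] < flat.log_prob(x)[0]


# ---------------------------------------------------------------------------
# Posterior behaviour (single reduced-size fit; the multi-fit recovery
# study lives in the acceptance suite)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_fit():
    cohort = gen_cohort(CohortSpec(n_healthy=10, n_t1d=9, seed=2))
    tbl, _ = gen_subset_counts(cohort, CompositionSimParams(
        group_effects={("T1D_T0", "Tcm"): 1.0}, seed=2))
    design = build_design(tbl)
    fit = fit_bayes(design, chains=4, draws=250, warmup=500, seed=0,
                    n_leapfrog=15)
    return tbl, fit


def test_fit_reports_reference_and_diagnostics(planted_fit):
    _, fit = planted_fit
    assert fit.reference_levels == {"group": "healthy",
                                    "population": "MAIT"}
    assert {"max_rhat", "n_divergent", "mean_accept"} <= \
        set(fit.diagnostics)
    assert (fit.summary["rhat"].notna()).all()
    assert np.isfinite(fit.intercept_prior_loc)


def test_fit_detects_planted_effect_direction(planted_fit):
    tbl, fit = planted_fit
    cc = fit.contrasts.set_index(["population", "contrast"])
    planted = cc.loc[("Tcm", "T1D_T0-healthy")]
    assert planted["q2.5"] > 0  # strong planted effect is resolved
    # frequentist analysis concurs in direction
    freq = frequentist_compare(tbl).set_index("population")
    f = proportions(tbl)
    hd = f[(f.population == "Tcm") & (f.group == "healthy")]["frequency"]
    t0 = f[(f.population == "Tcm") & (f.group == "T1D_T0")]["frequency"]
    assert t0.median() > hd.median()
    assert freq.loc["Tcm", "p_unpaired"] < 0.05


def test_contrast_table_covers_all_populations(planted_fit):
    _, fit = planted_fit
    counts = fit.contrasts.groupby("population").size()
    assert (counts == 2).all()  # T1D_T0 and T1D_T1 vs healthy
    assert (fit.contrasts["q2.5"] <= fit.contrasts["q97.5"]).all()
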