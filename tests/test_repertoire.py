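"""Clone definition, filtering, overlap and length analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcellkit.repertoire import (
    build_clones,
    cells_from_airr,
    expansion_score,
    filter_conventional,
    flag_vdj_doublet,
    length_distribution,
    length_group_test,
    overlap_contrasts,
    pairwise_overlap,
    repertoire_sets,
    same_clone,
)
from conftest import make_cell


# ---------------------------------------------------------------------------
# Doublet rule and conventional-cell filtering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_alpha, n_beta, expected", [
    (1, 1, False),
    (2, 1, False),
    (3, 1, True),
    (2, 2, True),
    (0, 1, False),
])
def test_vdj_doublet_rule(n_alpha, n_beta, expected):
    cell = make_cell("c1",
                     beta=None if n_beta == 0 else "TGT",
                     alphas=tuple(f"TG{chr(65 + i)}" * 1
                                  for i in range(n_alpha)))
    # rebuild with explicit multi-beta when needed
    if n_beta == 2:
        from tcellkit.repertoire import CellReceptor
        cell = CellReceptor("c1", "D1", tra_nt=cell.tra_nt,
                            tra_aa=cell.tra_aa,
                            trb_nt=("TGT", "TGC"), trb_aa=("C", "C"))
    assert flag_vdj_doublet(cell) is expected


def test_filter_conventional_modes():
    cells = [make_cell("c1", subset="conventional"),
             make_cell("c2", subset="MAIT"),
             make_cell("c3", subset="NK"),
             make_cell("c4", subset="gdT"),
             make_cell("c5", subset="iNKT")]
    cd8 = filter_conventional(cells, "CD8")
    assert [c.cell_id for c in cd8] == ["c1", "c5"]
    cd4 = filter_conventional(cells, "CD4")
    # the CD4 rule names iNKT only: MAIT/NK/gdT are retained
    assert [c.cell_id for c in cd4] == ["c1", "c2", "c3", "c4"]
    with pytest.raises(ValueError):
        filter_conventional(cells, "CD3")


# ---------------------------------------------------------------------------
# Clone identity rule
# ---------------------------------------------------------------------------

def test_same_clone_rule_cases():
    b = "TGTGCAAGC"
    x = make_cell("x", beta=b, alphas=("A1", "A2"))
    y = make_cell("y", beta=b, alphas=("A1",))
    z = make_cell("z", beta=b, alphas=("A1", "A3"))
    w = make_cell("w", beta=b, alphas=("A4",))
    n = make_cell("n", beta="TGTGCATTT", alphas=("A1",))
    e1 = make_cell("e1", beta=b, alphas=())
    e2 = make_cell("e2", beta=b, alphas=())
    assert same_clone(y, make_cell("y2", beta=b, alphas=("A1",)))
    assert same_clone(x, y)          # single α contained in the pair
    assert same_clone(y, z)
    assert not same_clone(x, z)      # two dual-α cells must share both
    assert not same_clone(y, w)
    assert not same_clone(x, n)      # β differs
    assert same_clone(e1, e2)        # both lack TCRα
    assert not same_clone(e1, y)     # 0 vs 1 α is not a match
    with pytest.raises(ValueError):
        same_clone(make_cell("q", beta=None), y)


def brute_force_clones(cells):
    """Independent oracle: O(n²) pairwise rule + graph components."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(c.cell_id for c in cells)
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            if same_clone(a, b):
                g.add_edge(a.cell_id, b.cell_id)
    return [frozenset(comp) for comp in nx.connected_components(g)]


def _partition(assignment):
    groups = {}
    for cell, clone in assignment.cell_to_clone.items():
        groups.setdefault(clone, set()).add(cell)
    return {frozenset(v) for v in groups.values()}


def test_build_clones_bridging_component():
    b = "TGTGCAAGC"
    x = make_cell("x", beta=b, alphas=("A1", "A2"))
    y = make_cell("y", beta=b, alphas=("A1",))
    z = make_cell("z", beta=b, alphas=("A1", "A3"))
    asg = build_clones([x, y, z])
    assert _partition(asg) == {frozenset({"x", "y", "z"})}
    # the component holds an incompatible pair (x, z): flagged
    assert asg.flagged == {asg.cell_to_clone["x"]}


def test_build_clones_disjoint_and_chain():
    b1, b2, b3 = "TGTAAA", "TGTCCC", "TGTGGG"
    cells = [make_cell(f"c{i}", beta=b, alphas=("A1",))
             for i, b in enumerate([b1, b2, b3])]
    asg = build_clones(cells)
    assert len(asg.clone_size) == 3
    assert set(asg.clone_size.values()) == {1}
    trio = [make_cell(f"t{i}", beta=b1, alphas=("A1",)) for i in range(3)]
    asg2 = build_clones(trio)
    assert list(asg2.clone_size.values()) == [3]
    assert asg2.flagged == set()


def test_build_clones_matches_brute_force_on_random_tables(rng):
    from tcellkit.simulate import (CohortSpec, RepertoireSimParams,
                                   gen_cohort, gen_repertoire)
    for rep in range(10):
        cohort = gen_cohort(CohortSpec(n_healthy=2, n_t1d=2,
                                       seed=1000 + rep))
        cells_df, _ = gen_repertoire(cohort, RepertoireSimParams(
            n_clones_per_donor=25, dual_alpha_rate=0.3,
            clone_size_max=8, seed=1000 + rep))
        cells_df = cells_df.iloc[:200]
        cells = [
            make_cell(r.cell_id, beta=r.trb_nt,
                      alphas=tuple(r.tra_nt.split(";")), donor=r.donor_id)
            for r in cells_df.itertuples()
        ]
        asg = build_clones(cells)
        assert _partition(asg) == set(brute_force_clones(cells))


def test_expansion_score_log2_of_clone_size():
    b = "TGTAAA"
    cells = [make_cell(f"c{i}", beta=b, alphas=("A1",)) for i in range(8)]
    cells.append(make_cell("solo", beta="TGTCCC", alphas=("A2",)))
    asg = build_clones(cells)
    assert expansion_score(asg, "c0") == pytest.approx(3.0)
    assert expansion_score(asg, "solo") == pytest.approx(0.0)
    tri = build_clones([make_cell(f"t{i}", beta=b, alphas=("A1",))
                        for i in range(3)])
    assert expansion_score(tri, "t1") == pytest.approx(np.log2(3))
    with pytest.raises(KeyError):
        expansion_score(asg, "ghost")


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------

def test_pairwise_overlap_set_arithmetic():
    reps = {"A": {"s1", "s2", "s3", "s4"}, "B": {"s1", "s2"}}
    ov = pairwise_overlap(reps).set_index(["from", "to"])["overlap_pct"]
    assert ov[("A", "B")] == pytest.approx(50.0)
    assert ov[("B", "A")] == pytest.approx(100.0)
    disjoint = pairwise_overlap({"A": {"s1"}, "B": {"s2"}})
    assert (disjoint["overlap_pct"] == 0).all()
    empty = pairwise_overlap({"A": set(), "B": {"s1"}})
    assert np.isnan(
        empty.set_index(["from", "to"])["overlap_pct"][("A", "B")])


@given(shared=st.sets(st.text("ACDEF", min_size=3, max_size=6),
                      min_size=0, max_size=8),
       only_a=st.sets(st.text("GHIKL", min_size=3, max_size=6),
                      min_size=1, max_size=8),
       only_b=st.sets(st.text("MNPQR", min_size=3, max_size=6),
                      min_size=1, max_size=8),
       extra=st.text("STVWY", min_size=3, max_size=6))
@settings(max_examples=60, deadline=None)
def test_overlap_bounded_and_monotone(shared, only_a, only_b, extra):
    a = shared | only_a
    b = shared | only_b
    ov = pairwise_overlap({"A": a, "B": b}).set_index(
        ["from", "to"])["overlap_pct"]
    assert 0.0 <= ov[("A", "B")] <= 100.0
    # identical repertoires overlap fully
    full = pairwise_overlap({"A": a, "B": set(a)})
    assert (full["overlap_pct"] == 100.0).all()
    # adding one shared sequence never decreases either direction
    a2, b2 = a | {extra}, b | {extra}
    ov2 = pairwise_overlap({"A": a2, "B": b2}).set_index(
        ["from", "to"])["overlap_pct"]
    assert ov2[("A", "B")] >= ov[("A", "B")] - 1e-12
    assert ov2[("B", "A")] >= ov[("B", "A")] - 1e-12


def test_overlap_contrast_labels():
    cells = []
    for donor, grp, tp in [("H1", "HD", "single"), ("H2", "HD", "single"),
                           ("P1", "T1D", "T0"), ("P1", "T1D", "T1")]:
        for i in range(3):
            cells.append(make_cell(f"{donor}{tp}{i}", beta="TGTGCA",
                                   alphas=("A1",), donor=donor,
                                   timepoint=tp))
    res = overlap_contrasts(cells, {"H1": "HD", "H2": "HD", "P1": "T1D"})
    assert set(res["contrast"]) == {"HD-HD", "HD-T1D", "T1D-T1D",
                                    "SelfT1-SelfT0"} - {"T1D-T1D"}
    self_row = res[res["contrast"] == "SelfT1-SelfT0"]
    assert len(self_row) == 1
    assert self_row["overlap_pct"].iloc[0] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# Lengths
# ---------------------------------------------------------------------------

def test_length_distribution_counting():
    rep = {"AAAAAAAAAAAAA", "CCCCCCCCCCCCC", "DDDDDDDDDDDDD",
           "EEEEEEEEEEEEEEE"}
    dist = length_distribution(rep)
    assert dist[13] == pytest.approx(0.75)
    assert dist[15] == pytest.approx(0.25)
    assert dist.sum() == pytest.approx(1.0, abs=1e-12)
    single = length_distribution({"AAAA", "CCCC"})
    assert dict(single) == {4: 1.0}
    with pytest.raises(ValueError):
        length_distribution(set())


def test_length_group_test_mirrored_groups_null():
    reps = {}
    groups = {}
    base = [{"AAAA", "CCCCC"}, {"DDDD", "EEEEE", "FFFF"}]
    for i, rep in enumerate(base):
        reps[f"hd{i}"] = set(rep)
        reps[f"t1d{i}"] = set(rep)
        groups[f"hd{i}"] = "HD"
        groups[f"t1d{i}"] = "T1D"
    res = length_group_test(reps, groups)
    assert (res["p_value"] == 1.0).all()


def test_cells_from_airr_roundtrip():
    from tcellkit.simulate import (CohortSpec, RepertoireSimParams,
                                   gen_cohort, gen_repertoire,
                                   repertoire_to_airr)
    cohort = gen_cohort(CohortSpec(n_healthy=2, n_t1d=1, seed=11))
    cells_df, _ = gen_repertoire(cohort, RepertoireSimParams(
        n_clones_per_donor=10, seed=11))
    airr = repertoire_to_airr(cells_df.iloc[:30])
    cells = cells_from_airr(airr)
    assert len(cells) == len(cells_df.iloc[:30])
    byid = {c.cell_id: c for c in cells}
    for r in cells_df.iloc[:30].itertuples():
        c = byid[r.cell_id]
        assert c.trb_nt == (r.trb_nt,)
        assert set(c.tra_nt) == set(r.tra_nt.split(";"))


def test_repertoire_sets_levels():
    cells = [make_cell("c1", beta="TGTGCA", alphas=("TGCAAA",), donor="D1")]
    by_nt = repertoire_sets(cells, chain="beta", level="nt")
    by_aa = repertoire_sets(cells, chain="beta", level="aa")
    assert by_nt["D1"] == {"TGTGCA"}
    assert by_aa["D1"] == {"CC"}
    with pytest.raises(ValueError):
        repertoire_sets(cells, chain="gamma")
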