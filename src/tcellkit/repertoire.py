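"""Paired-chain clone definition, expansion, filtering, repertoire overlap
and CDR3β length analysis.

A clone is a set of cells with identical CDR3 nucleotide junctions of
both chains, with a tolerance for dual-α cells: two cells belong to the
same clone when their CDR3β nucleotide sequences are identical and either
their full TCRα sets match, or one cell shows a single TCRα that is
present in the other cell's pair (the second α simply escaping
detection). Because that relation is not transitive, clones are taken as
connected components of it; components that contain a mutually
incompatible pair are flagged rather than split.

Repertoire overlap operates on unique amino-acid CDR3 sequences per
donor, directionally: the overlap of donor A with donor B is the
percentage of A's unique sequences also found in B.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellReceptor",
    "CloneAssignment",
    "cells_from_airr",
    "flag_vdj_doublet",
    "filter_conventional",
    "same_clone",
    "build_clones",
    "expansion_score",
    "pairwise_overlap",
    "overlap_contrasts",
    "length_distribution",
    "length_group_test",
]

# subsets excluded from the "conventional" analyses, per lineage
_EXCLUDE = {"CD8": {"MAIT", "NK", "gdT"}, "CD4": {"iNKT"}}


@dataclass(frozen=True)
class CellReceptor:
    """One T cell's paired-chain receptor with provenance."""

    cell_id: str
    donor_id: str
    timepoint: str = "single"          # T0 | T1 | single
    tra_nt: tuple[str, ...] = ()       # 0–2 productive TCRα junctions (nt)
    tra_aa: tuple[str, ...] = ()
    trb_nt: tuple[str, ...] = ()       # <=1 productive TCRβ junction (nt)
    trb_aa: tuple[str, ...] = ()
    subset: str = "conventional"

    def __post_init__(self):
        if len(self.tra_nt) != len(self.tra_aa):
            raise ValueError("tra_nt / tra_aa length mismatch")
        if len(self.trb_nt) != len(self.trb_aa):
            raise ValueError("trb_nt / trb_aa length mismatch")


def cells_from_airr(df: pd.DataFrame) -> list[CellReceptor]:
    """Assemble per-cell receptors from AIRR Rearrangement rows.

    Expects one row per productive chain with columns ``cell_id``,
    ``locus`` (TRA/TRB), ``productive``, ``junction``, ``junction_aa``
    plus ``donor_id`` and optional ``timepoint``/``subset``.
    Non-productive rows are dropped.
    """
    prod = df[df["productive"].astype(str).str.upper().isin(["T", "TRUE"])]
    cells = []
    for cell_id, rows in prod.groupby("cell_id", sort=True):
        tra = rows[rows["locus"] == "TRA"].sort_values("junction")
        trb = rows[rows["locus"] == "TRB"].sort_values("junction")
        first = rows.iloc[0]
        cells.append(CellReceptor(
            cell_id=str(cell_id),
            donor_id=str(first["donor_id"]),
            timepoint=str(first.get("timepoint", "single")),
            tra_nt=tuple(tra["junction"]),
            tra_aa=tuple(tra["junction_aa"]),
            trb_nt=tuple(trb["junction"]),
            trb_aa=tuple(trb["junction_aa"]),
            subset=str(first["subset"]) if "subset" in rows.columns
            else "conventional",
        ))
    return cells


def cells_from_table(df: pd.DataFrame) -> list[CellReceptor]:
    """Assemble receptors from a wide per-cell table.

    Expects one row per cell with ``trb_nt``/``trb_aa`` strings and
    ``tra_nt``/``tra_aa`` as ``;``-joined strings (the layout the
    repertoire simulator emits).
    """
    cells = []
    for r in df.itertuples():
        cells.append(CellReceptor(
            cell_id=str(r.cell_id), donor_id=str(r.donor_id),
            timepoint=str(getattr(r, "timepoint", "single")),
            tra_nt=tuple(r.tra_nt.split(";")) if r.tra_nt else (),
            tra_aa=tuple(r.tra_aa.split(";")) if r.tra_aa else (),
            trb_nt=(r.trb_nt,) if r.trb_nt else (),
            trb_aa=(r.trb_aa,) if r.trb_aa else (),
            subset=str(getattr(r, "subset", "conventional"))))
    return cells


def flag_vdj_doublet(cell: CellReceptor) -> bool:
    """QC doublet rule: more than 2 TCRα or more than 1 productive TCRβ."""
    return len(cell.tra_nt) > 2 or len(cell.trb_nt) > 1


def filter_conventional(cells, lineage: str):
    """Drop unconventional subsets for a lineage, preserving order.

    CD8 mode removes MAIT, NK and γδT cells; CD4 mode removes iNKT.
    """
    if lineage not in _EXCLUDE:
        raise ValueError(f"unknown lineage {lineage!r}; use CD8 or CD4")
    excluded = _EXCLUDE[lineage]
    return [c for c in cells if c.subset not in excluded]


def same_clone(a: CellReceptor, b: CellReceptor) -> bool:
    """Paired-chain clone identity at the nucleotide level.

    Requires identical CDR3β nt. The TCRα sets must be identical, or the
    single detected TCRα of one cell must be among the other's two (the
    second α taken as not detected), or both cells must lack TCRα.
    """
    if not a.trb_nt or not b.trb_nt:
        raise ValueError("clone matching requires a productive TCRβ")
    if a.trb_nt[0] != b.trb_nt[0]:
        return False
    sa, sb = set(a.tra_nt), set(b.tra_nt)
    if sa == sb:
        return True  # covers both-empty and identical sets
    if len(sa) == 1 and len(sb) == 2 and sa <= sb:
        return True
    if len(sb) == 1 and len(sa) == 2 and sb <= sa:
        return True
    return False


@dataclass
class CloneAssignment:
    """Partition of cells into clones with sizes and flags."""

    cell_to_clone: dict[str, int]
    clone_size: dict[int, int]
    clone_beta_nt: dict[int, str]
    # clones containing at least one mutually incompatible cell pair
    flagged: set[int] = field(default_factory=set)

    def size_of(self, cell_id: str) -> int:
        return self.clone_size[self.cell_to_clone[cell_id]]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_clones(cells) -> CloneAssignment:
    """Partition cells into clones (connected components of same_clone).

    Cells lacking a productive TCRβ must be excluded beforehand (the
    clone key requires the β junction). Candidate pairs are restricted
    to identical CDR3β nt before the α rule is applied, so the
    construction is near-linear in practice. Components containing an
    incompatible pair (possible through dual-α bridging) are flagged.
    """
    cells = list(cells)
    for c in cells:
        if not c.trb_nt:
            raise ValueError(f"cell {c.cell_id} has no productive TCRβ")
    uf = _UnionFind(len(cells))
    by_beta: dict[str, list[int]] = defaultdict(list)
    for i, c in enumerate(cells):
        by_beta[c.trb_nt[0]].append(i)
    for idxs in by_beta.values():
        for i, j in combinations(idxs, 2):
            if same_clone(cells[i], cells[j]):
                uf.union(i, j)
    roots = [uf.find(i) for i in range(len(cells))]
    clone_ids = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    cell_to_clone = {c.cell_id: clone_ids[r] for c, r in zip(cells, roots)}
    clone_size = Counter(cell_to_clone.values())
    clone_beta: dict[int, str] = {}
    for i, r in enumerate(roots):
        clone_beta.setdefault(clone_ids[r], cells[i].trb_nt[0])
    members: dict[int, list[int]] = defaultdict(list)
    for i, r in enumerate(roots):
        members[clone_ids[r]].append(i)
    flagged = {
        cid for cid, idxs in members.items()
        if any(not same_clone(cells[i], cells[j])
               for i, j in combinations(idxs, 2))
    }
    return CloneAssignment(cell_to_clone, dict(clone_size), clone_beta,
                           flagged)


def expansion_score(assignment: CloneAssignment, cell_id: str) -> float:
    """log2 size of the clone containing ``cell_id``."""
    if cell_id not in assignment.cell_to_clone:
        raise KeyError(f"cell {cell_id!r} not in assignment")
    return float(np.log2(assignment.size_of(cell_id)))


# ---------------------------------------------------------------------------
# Repertoire overlap
# ---------------------------------------------------------------------------

def repertoire_sets(cells, chain: str = "beta", level: str = "aa",
                    split_timepoints: bool = False
                    ) -> dict[str, set[str]]:
    """Unique CDR3 sequences per donor (or per donor×timepoint).

    ``chain`` selects α or β; ``level`` selects amino-acid (the overlap
    convention) or nucleotide sequences. Keys are donor ids, or
    ``(donor, timepoint)`` tuples with ``split_timepoints``.
    """
    if chain not in ("alpha", "beta"):
        raise ValueError(f"chain must be 'alpha' or 'beta', got {chain!r}")
    if level not in ("aa", "nt"):
        raise ValueError(f"level must be 'aa' or 'nt', got {level!r}")
    attr = {("alpha", "aa"): "tra_aa", ("alpha", "nt"): "tra_nt",
            ("beta", "aa"): "trb_aa", ("beta", "nt"): "trb_nt"}[(chain, level)]
    sets: dict = defaultdict(set)
    for c in cells:
        key = (c.donor_id, c.timepoint) if split_timepoints else c.donor_id
        sets[key].update(getattr(c, attr))
    return dict(sets)


def pairwise_overlap(repertoires: dict[str, set[str]]) -> pd.DataFrame:
    """Directional overlap percentages for every ordered donor pair.

    Overlap of A with B = 100 × |A ∩ B| / |A| — the share of the
    focal donor's unique sequences found in the other donor. Donors with
    empty repertoires are reported as NaN.
    """
    donors = sorted(repertoires)
    if len(donors) < 2:
        raise ValueError("need >= 2 repertoires")
    rows = []
    for a in donors:
        for b in donors:
            if a == b:
                continue
            sa, sb = repertoires[a], repertoires[b]
            pct = 100.0 * len(sa & sb) / len(sa) if sa else np.nan
            rows.append({"from": a, "to": b, "overlap_pct": pct})
    return pd.DataFrame(rows)


def overlap_contrasts(cells, groups: dict[str, str],
                      chain: str = "beta", level: str = "aa"
                      ) -> pd.DataFrame:
    """Grouped overlap contrasts: HD–HD, HD–T1D, T1D–T1D, SelfT1–SelfT0.

    ``groups`` maps donor → {"HD", "T1D"}. Cross-donor contrasts pool
    each donor's sequences over timepoints; the self contrast is the
    overlap of a donor's T1 set with their T0 set, defined only for
    donors sampled at both timepoints.
    """
    reps = repertoire_sets(cells, chain=chain, level=level)
    ov = pairwise_overlap(reps)

    def _label(row):
        ga, gb = groups[row["from"]], groups[row["to"]]
        return f"{ga}-{gb}" if ga == gb else "HD-T1D"

    ov["contrast"] = ov.apply(_label, axis=1)
    by_tp = repertoire_sets(cells, chain=chain, level=level,
                            split_timepoints=True)
    self_rows = []
    donors = {d for d, _ in by_tp}
    for d in sorted(donors):
        t0, t1 = by_tp.get((d, "T0")), by_tp.get((d, "T1"))
        if t0 and t1:
            self_rows.append({
                "from": d, "to": d,
                "overlap_pct": 100.0 * len(t1 & t0) / len(t1),
                "contrast": "SelfT1-SelfT0",
            })
    return pd.concat([ov, pd.DataFrame(self_rows)], ignore_index=True)


# ---------------------------------------------------------------------------
# CDR3β length analysis
# ---------------------------------------------------------------------------

def length_distribution(repertoire: set[str]) -> pd.Series:
    """Frequency of each CDR3 length among a donor's unique sequences."""
    if not repertoire:
        raise ValueError("empty repertoire")
    counts = Counter(len(s) for s in repertoire)
    total = sum(counts.values())
    return pd.Series({ln: c / total for ln, c in sorted(counts.items())},
                     name="frequency")


def length_group_test(donor_reps: dict[str, set[str]],
                      groups: dict[str, str]) -> pd.DataFrame:
    """Per-length two-group comparison of donor length frequencies.

    For every CDR3 length, the per-donor frequencies are compared
    between the two groups by a two-tailed Mann–Whitney test, without
    multiple-comparison correction (each length read as one panel of a
    length-distribution figure).
    """
    freq = pd.DataFrame({d: length_distribution(r)
                         for d, r in donor_reps.items()}).fillna(0.0).T
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    grp = pd.Series({d: groups[d] for d in freq.index})
    rows = []
    for length in sorted(freq.columns):
        a = freq.loc[grp == labels[0], length]
        b = freq.loc[grp == labels[1], length]
        if np.array_equal(np.sort(a.values), np.sort(b.values)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b,
                                         alternative="two-sided").pvalue)
        rows.append({"length": length, "p_value": p,
                     f"mean_{labels[0]}": float(a.mean()),
                     f"mean_{labels[1]}": float(b.mean())})
    return pd.DataFrame(rows)
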