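"""Synthetic cohort, repertoire, composition, fold-change and HLA data
with planted ground truth.

Every generator is deterministic under a fixed seed and returns its
ground truth alongside the data, so downstream statistics can be tested
for recovery of known effects. The default settings emulate the study
conditions of a pediatric new-onset T1D cohort: 13 healthy donors
sampled once and 30 T1D donors sampled at diagnosis (T0) and about one
year later (T1), clonally expanded repertoires with within-donor
T0→T1 clone persistence and near-zero cross-donor sharing, negative-
binomially distributed subset counts from a hierarchical log-linear
model, cross-study fold-change matrices with planted consistent genes,
and allele-linked expression confounded with disease status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import BOMAN, CANONICAL_AA

__all__ = [
    "CohortSpec",
    "RepertoireSimParams",
    "CompositionSimParams",
    "gen_cohort",
    "gen_repertoire",
    "gen_subset_counts",
    "gen_fold_change_studies",
    "gen_hla_expression",
    "DEFAULT_HIERARCHY",
]

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

# Sampling bounds for the clinical variables; they feed threshold rules
# only, so uniform draws within plausible new-onset ranges suffice.
DEFAULT_CLINICAL_RANGES = {
    "hba1c": (6.0, 14.0),          # %
    "insulin_dose": (0.1, 1.2),    # U/kg/24h
    "ph": (7.0, 7.45),
    "bicarbonate": (8.0, 28.0),    # mEq/L
}
HEALTHY_CLINICAL_RANGES = {
    "hba1c": (4.8, 5.6),
    "insulin_dose": (0.0, 0.0),
    "ph": (7.35, 7.45),
    "bicarbonate": (22.0, 28.0),
}


@dataclass
class CohortSpec:
    """Cohort layout: healthy donors sampled once, T1D donors at T0/T1."""

    n_healthy: int = 13
    n_t1d: int = 30
    paired_timepoints: bool = True
    seed: int = 0
    clinical_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_RANGES))

    def __post_init__(self):
        if self.n_healthy < 1 or self.n_t1d < 1:
            raise ValueError("n_healthy and n_t1d must be >= 1")


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per sample: donor, group, timepoint, clinical variables."""
    rng = np.random.default_rng(spec.seed)
    rows = []

    def _clinical(ranges):
        return {k: float(rng.uniform(*ranges[k])) for k in
                ("hba1c", "insulin_dose", "ph", "bicarbonate")}

    for i in range(spec.n_healthy):
        rows.append({"donor_id": f"HD{i + 1:02d}", "group": "healthy",
                     "timepoint": "single",
                     **_clinical(HEALTHY_CLINICAL_RANGES)})
    for i in range(spec.n_t1d):
        donor = f"T1D{i + 1:02d}"
        clin = _clinical(spec.clinical_ranges)
        rows.append({"donor_id": donor, "group": "T1D_T0",
                     "timepoint": "T0", **clin})
        if spec.paired_timepoints:
            rows.append({"donor_id": donor, "group": "T1D_T1",
                         "timepoint": "T1", **clin})
    df = pd.DataFrame(rows)
    df.insert(0, "sample_id", df["donor_id"] + "_" + df["timepoint"])
    return df


# ---------------------------------------------------------------------------
# Repertoire
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSimParams:
    """Clonally structured paired-chain repertoire settings.

    Clone sizes follow a truncated zeta-like power law (exponent
    ``clone_size_alpha``, max ``clone_size_max``), reproducing the
    contrast between expanded effector and unexpanded naïve clones.
    ``persistence_rate`` is the probability that a T0 clone of a donor
    recurs at T1; ``public_rate`` the probability a clone's CDR3s are
    drawn from a small cross-donor public pool; ``dual_alpha_rate`` the
    probability a clone carries two productive TCRα chains.
    ``group_biophys_shift`` tilts residue sampling toward hydrophilic,
    protein-binding residues for T1D donors, planting a Boman-index /
    hydrophobicity difference of tunable size.
    """

    n_clones_per_donor: int = 150
    clone_size_alpha: float = 2.5
    clone_size_max: int = 64
    persistence_rate: float = 0.5
    public_rate: float = 0.001
    dual_alpha_rate: float = 0.15
    cdr3_length_range: tuple[int, int] = (8, 22)
    cdr3_length_mean: float = 14.0
    cdr3_length_sd: float = 1.8
    group_biophys_shift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("persistence_rate", "public_rate", "dual_alpha_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.clone_size_max < 1 or self.n_clones_per_donor < 1:
            raise ValueError("clone counts/sizes must be >= 1")


def _sample_clone_sizes(rng, n, alpha, smax):
    sizes = np.arange(1, smax + 1)
    probs = sizes ** (-alpha)
    probs /= probs.sum()
    return rng.choice(sizes, size=n, p=probs)


def _sample_length(rng, params: RepertoireSimParams) -> int:
    lo, hi = params.cdr3_length_range
    ln = int(round(rng.normal(params.cdr3_length_mean,
                              params.cdr3_length_sd)))
    return int(np.clip(ln, lo, hi))


_AA = np.array(list(CANONICAL_AA))
_BOMAN_Z = np.array([BOMAN[a] for a in CANONICAL_AA])
_BOMAN_Z = (_BOMAN_Z - _BOMAN_Z.mean()) / _BOMAN_Z.std()


def _aa_weights(shift: float) -> np.ndarray:
    w = np.exp(shift * _BOMAN_Z)
    return w / w.sum()


def _random_cdr3_aa(rng, length: int, weights: np.ndarray) -> str:
    return "".join(rng.choice(_AA, size=length, p=weights))


def _spell_nt(rng, aa: str) -> str:
    return "".join(_CODONS[c][rng.integers(len(_CODONS[c]))] for c in aa)


def gen_repertoire(cohort: pd.DataFrame, params: RepertoireSimParams
                   ) -> tuple[pd.DataFrame, dict]:
    """Per-cell paired-chain clonotype table with ground-truth clone ids.

    Returns ``(cells, truth)`` where ``cells`` has one row per cell with
    α/β junctions at nt and aa level (nt spellings are arbitrary codon
    choices fixed per clone per donor, so nt identity implies aa
    identity but not conversely) and a hidden ``truth_clone_id`` column;
    ``truth`` records per-donor persisted clone ids and the public pool.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(params.seed)
    weights_by_group = {
        "healthy": _aa_weights(0.0),
        "T1D_T0": _aa_weights(params.group_biophys_shift),
        "T1D_T1": _aa_weights(params.group_biophys_shift),
    }
    # small public pool of aa sequences shared across donors
    public_pool = [
        _random_cdr3_aa(rng, _sample_length(rng, params), _aa_weights(0.0))
        for _ in range(50)
    ]
    rows = []
    truth: dict = {"persisted_clones": {}, "public_pool": public_pool,
                   "clone_alpha_count": {}}
    cell_counter = 0
    clone_counter = 0
    donors = cohort.drop_duplicates("donor_id")
    for _, donor_row in donors.iterrows():
        donor = donor_row["donor_id"]
        donor_samples = cohort[cohort["donor_id"] == donor]
        timepoints = list(donor_samples["timepoint"])
        base_group = donor_row["group"]
        w = weights_by_group[base_group]

        # donor's clone catalogue at the first timepoint
        clones = []
        for _ in range(params.n_clones_per_donor):
            is_public = rng.random() < params.public_rate
            if is_public:
                aa_b = public_pool[rng.integers(len(public_pool))]
            else:
                aa_b = _random_cdr3_aa(rng, _sample_length(rng, params), w)
            n_alpha = 2 if rng.random() < params.dual_alpha_rate else 1
            aa_a = tuple(
                _random_cdr3_aa(rng, _sample_length(rng, params), w)
                for _ in range(n_alpha))
            clones.append({
                "clone_id": clone_counter,
                "aa_b": aa_b,
                "nt_b": _spell_nt(rng, aa_b),
                "aa_a": aa_a,
                "nt_a": tuple(_spell_nt(rng, a) for a in aa_a),
            })
            truth["clone_alpha_count"][clone_counter] = n_alpha
            clone_counter += 1

        persisted = set()
        for tp_idx, tp in enumerate(timepoints):
            group = donor_samples.iloc[tp_idx]["group"]
            if tp_idx == 0:
                tp_clones = clones
            else:
                keep = [c for c in clones
                        if rng.random() < params.persistence_rate]
                persisted = {c["clone_id"] for c in keep}
                fresh = []
                for _ in range(params.n_clones_per_donor - len(keep)):
                    aa_b = _random_cdr3_aa(
                        rng, _sample_length(rng, params), w)
                    n_alpha = (2 if rng.random() < params.dual_alpha_rate
                               else 1)
                    aa_a = tuple(
                        _random_cdr3_aa(rng, _sample_length(rng, params), w)
                        for _ in range(n_alpha))
                    fresh.append({
                        "clone_id": clone_counter, "aa_b": aa_b,
                        "nt_b": _spell_nt(rng, aa_b), "aa_a": aa_a,
                        "nt_a": tuple(_spell_nt(rng, a) for a in aa_a)})
                    truth["clone_alpha_count"][clone_counter] = n_alpha
                    clone_counter += 1
                tp_clones = keep + fresh
            sizes = _sample_clone_sizes(
                rng, len(tp_clones), params.clone_size_alpha,
                params.clone_size_max)
            for clone, size in zip(tp_clones, sizes):
                for _ in range(size):
                    cell_counter += 1
                    rows.append({
                        "cell_id": f"cell{cell_counter:07d}",
                        "donor_id": donor, "timepoint": tp, "group": group,
                        "trb_nt": clone["nt_b"], "trb_aa": clone["aa_b"],
                        "tra_nt": ";".join(clone["nt_a"]),
                        "tra_aa": ";".join(clone["aa_a"]),
                        "subset": "conventional",
                        "truth_clone_id": clone["clone_id"],
                    })
        truth["persisted_clones"][donor] = persisted
    return pd.DataFrame(rows), truth


def repertoire_to_airr(cells: pd.DataFrame) -> pd.DataFrame:
    """Explode a per-cell table to AIRR Rearrangement rows (one per chain)."""
    rows = []
    for _, r in cells.iterrows():
        common = {"cell_id": r["cell_id"], "donor_id": r["donor_id"],
                  "timepoint": r["timepoint"], "group": r["group"],
                  "subset": r["subset"], "productive": "T",
                  "v_call": "", "d_call": "", "j_call": ""}
        for nt, aa in zip(r["tra_nt"].split(";"), r["tra_aa"].split(";")):
            rows.append({**common, "locus": "TRA",
                         "junction": nt, "junction_aa": aa})
        rows.append({**common, "locus": "TRB",
                     "junction": r["trb_nt"], "junction_aa": r["trb_aa"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subset counts
# ---------------------------------------------------------------------------

DEFAULT_HIERARCHY = {
    "Tcm": "CD4_memory", "Tem_CD4": "CD4_memory", "Treg": "CD4_memory",
    "Naive_CD4": "CD4_naive", "Tfh": "CD4_memory",
    "Naive_CD8": "CD8_naive", "Temra": "CD8_effector",
    "Tem_CD8": "CD8_effector", "MAIT": "CD8_effector",
    "gdT": "CD8_effector",
}


@dataclass
class CompositionSimParams:
    """Negative-binomial hierarchical composition settings.

    Counts for Level-3 population p in sample s are drawn
    NB(mean = total_s · exp(η), shape = φ_p) with
    η = baseline_p + group_effect[g, p] + u_L2[parent(p), g] +
    u_L3[p, g], random effects gaussian with the stated SDs, and
    log φ_p = shape_baseline + shape_l2[parent(p)] + N(0, shape_l3_sd).
    """

    hierarchy: dict = field(
        default_factory=lambda: dict(DEFAULT_HIERARCHY))
    baseline_log_rates: dict | None = None   # Level-3 → log proportion
    group_effects: dict = field(default_factory=dict)
    # (group, population) → log-rate shift
    random_effect_sds: dict = field(
        default_factory=lambda: {"level2": 0.0, "level3": 0.0})
    shape_baseline: float = np.log(20.0)
    shape_l2: dict | None = None
    shape_l3_sd: float = 0.0
    total_mean: float = 5000.0
    total_shape: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_log_rates is None:
            pops = sorted(self.hierarchy)
            # proportions spanning ~20-fold, normalised to sum 0.95
            raw = np.exp(-np.linspace(0, 3, len(pops)))
            props = 0.95 * raw / raw.sum()
            self.baseline_log_rates = dict(zip(pops, np.log(props)))
        if self.shape_l2 is None:
            self.shape_l2 = {q: 0.0 for q in set(self.hierarchy.values())}
        if np.exp(self.shape_baseline) <= 0:
            raise ValueError("shape must be positive")


def gen_subset_counts(cohort: pd.DataFrame, params: CompositionSimParams
                      ) -> tuple[pd.DataFrame, dict]:
    """Per-sample × Level-3 NB counts with totals and ground truth."""
    rng = np.random.default_rng(params.seed)
    pops = sorted(params.hierarchy)
    parents = sorted(set(params.hierarchy.values()))
    groups = ["healthy", "T1D_T0", "T1D_T1"]
    sd2 = params.random_effect_sds.get("level2", 0.0)
    sd3 = params.random_effect_sds.get("level3", 0.0)
    u_l2 = {(q, g): rng.normal(0.0, sd2) if sd2 > 0 else 0.0
            for q in parents for g in groups}
    u_l3 = {(p, g): rng.normal(0.0, sd3) if sd3 > 0 else 0.0
            for p in pops for g in groups}
    log_shape = {
        p: params.shape_baseline + params.shape_l2[params.hierarchy[p]]
        + (rng.normal(0.0, params.shape_l3_sd)
           if params.shape_l3_sd > 0 else 0.0)
        for p in pops
    }
    rows = []
    for _, s in cohort.iterrows():
        g = s["group"]
        total = int(max(1, rng.negative_binomial(
            params.total_shape,
            params.total_shape / (params.total_shape + params.total_mean))))
        for p in pops:
            eta = (params.baseline_log_rates[p]
                   + params.group_effects.get((g, p), 0.0)
                   + u_l2[(params.hierarchy[p], g)] + u_l3[(p, g)])
            mu = total * np.exp(eta)
            phi = np.exp(log_shape[p])
            count = int(rng.negative_binomial(phi, phi / (phi + mu)))
            rows.append({"sample_id": s["sample_id"],
                         "donor_id": s["donor_id"], "group": g,
                         "population": p,
                         "parent": params.hierarchy[p],
                         "count": count, "total": total})
    truth = {"u_l2": u_l2, "u_l3": u_l3, "log_shape": log_shape,
             "group_effects": dict(params.group_effects),
             "baseline_log_rates": dict(params.baseline_log_rates)}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Fold-change studies
# ---------------------------------------------------------------------------

def gen_fold_change_studies(n_genes: int, n_studies: int,
                            planted_up: int, planted_down: int,
                            noise_sd: float, seed: int,
                            planted_magnitude: float = 3.0,
                            missing_rate: float = 0.05
                            ) -> tuple[pd.DataFrame, dict]:
    """Gene × study log fold changes with planted consistent genes.

    ``planted_up`` genes are strongly positive (T1D-up) in every study,
    ``planted_down`` strongly negative, the rest pure noise; a random
    fraction of entries per study is missing, emulating differing gene
    universes. Returns the matrix and the planted gene sets.
    """
    if planted_up + planted_down > n_genes:
        raise ValueError("planted sets exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    up = genes[:planted_up]
    down = genes[planted_up:planted_up + planted_down]
    fc = rng.normal(0.0, noise_sd, size=(n_genes, n_studies))
    fc[:planted_up] += planted_magnitude
    fc[planted_up:planted_up + planted_down] -= planted_magnitude
    if missing_rate > 0:
        mask = rng.random(fc.shape) < missing_rate
        fc[mask] = np.nan
    matrix = pd.DataFrame(
        fc, index=pd.Index(genes, name="gene"),
        columns=[f"study{j + 1}" for j in range(n_studies)])
    return matrix, {"planted_up": up, "planted_down": down}


# ---------------------------------------------------------------------------
# HLA genotype / expression
# ---------------------------------------------------------------------------

def gen_hla_expression(n_donors: int,
                       allele_pool: dict[str, list[str]] | None = None,
                       allele_effect: float = 0.0,
                       study_effect: float = 0.5,
                       status_effect: float = 0.0,
                       seed: int = 0,
                       n_datasets: int = 3,
                       confound_rate: float = 0.3,
                       noise_sd: float = 0.3,
                       risk_allele: str | None = None,
                       locus: str = "DRB1"
                       ) -> tuple[pd.DataFrame, dict]:
    """Donor genotype + expression with an allele effect confounded with
    disease status.

    Expression = dataset baseline + allele_effect × dosage(risk allele)
    + status_effect × [T1D] + N(0, noise_sd). Disease status is tilted
    toward risk-allele carriers by ``confound_rate`` (0 = independent),
    planting the confound the per-locus GLM must untangle.
    """
    if allele_pool is None:
        allele_pool = {
            "DRB1": ["DRB1*03:01", "DRB1*04:01", "DRB1*07:01",
                     "DRB1*11:01", "DRB1*15:01"],
            "DQA1": ["DQA1*05:01", "DQA1*03:01", "DQA1*01:02"],
            "DQB1": ["DQB1*02:01", "DQB1*03:02", "DQB1*06:02"],
        }
    for loc, pool in allele_pool.items():
        if not pool:
            raise ValueError(f"empty allele pool at {loc}")
    if risk_allele is None:
        risk_allele = allele_pool[locus][0]
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_donors):
        genotype = {
            loc: tuple(pool[j] for j in rng.integers(len(pool), size=2))
            for loc, pool in allele_pool.items()
        }
        dosage = sum(a == risk_allele for a in genotype[locus])
        p_t1d = 0.5 + confound_rate * (dosage - 1) / 2.0
        status = "T1D" if rng.random() < np.clip(p_t1d, 0.0, 1.0) \
            else "healthy"
        dataset = f"DS{rng.integers(n_datasets) + 1}"
        expr = (study_effect * int(dataset[2:])
                + allele_effect * dosage
                + status_effect * (status == "T1D")
                + rng.normal(0.0, noise_sd))
        row = {"donor_id": f"D{i + 1:04d}", "dataset": dataset,
               "status": status, "expression": expr,
               "truth_dosage": dosage}
        for loc, (a1, a2) in genotype.items():
            row[f"{loc}_1"], row[f"{loc}_2"] = a1, a2
        rows.append(row)
    truth = {"risk_allele": risk_allele, "locus": locus,
             "allele_effect": allele_effect, "status_effect": status_effect}
    return pd.DataFrame(rows), truth
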