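"""Per-residue physicochemical scales over the 20 canonical amino acids.

Values are the published defaults of the classical references:

* ``BOMAN`` — per-residue protein-binding/solubility contributions derived
  from the Radzicka–Wolfenden water/cyclohexane transfer free energies
  (kcal/mol, sign such that hydrophilic residues contribute positively;
  proline, unmeasured, is assigned 0 by convention).
* ``EISENBERG`` — Eisenberg consensus hydrophobicity, the conventional
  scale for the helical hydrophobic moment.
* ``KYTE_DOOLITTLE`` — Kyte–Doolittle hydropathy.
"""

from __future__ import annotations

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

BOMAN: dict[str, float] = {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35,
    "W": -2.33, "A": -1.81, "C": -1.28, "G": -0.94, "Y": 0.14,
    "P": 0.0, "T": 2.57, "S": 3.40, "H": 4.66, "Q": 5.54,
    "K": 5.55, "N": 6.64, "E": 6.81, "D": 8.72, "R": 14.92,
}

EISENBERG: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SCALES: dict[str, dict[str, float]] = {
    "boman": BOMAN,
    "eisenberg": EISENBERG,
    "kyte_doolittle": KYTE_DOOLITTLE,
}

for _name, _scale in SCALES.items():
    assert set(_scale) == set(CANONICAL_AA), _name
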