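"""Clinical index derivations for cohort stratification.

IDAA1c (insulin-dose-adjusted HbA1c), the partial-remission flag derived
from it, and the diabetic-ketoacidosis flag from blood gas values. All
cutoffs are strict inequalities.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["idaa1c", "remission", "dka", "derive_clinical"]

REMISSION_CUTOFF = 9.0
DKA_PH_CUTOFF = 7.3
DKA_BICARBONATE_CUTOFF = 15.0  # mEq/L


def idaa1c(hba1c: float, insulin_dose: float) -> float:
    """Insulin-dose-adjusted HbA1c: HbA1c (%) + 4 × dose (U/kg/24h)."""
    if hba1c <= 0:
        raise ValueError(f"HbA1c must be positive, got {hba1c}")
    if insulin_dose < 0:
        raise ValueError(f"insulin dose must be >= 0, got {insulin_dose}")
    return hba1c + 4.0 * insulin_dose


def remission(idaa1c_value: float) -> bool:
    """Partial clinical remission: IDAA1c strictly below 9."""
    return bool(idaa1c_value < REMISSION_CUTOFF)


def dka(ph: float | None, bicarbonate: float | None) -> bool | None:
    """Diabetic ketoacidosis: pH < 7.3 and/or bicarbonate < 15 mEq/L.

    Either measurement alone can flag DKA; with both missing the flag is
    undeterminable and ``None`` is returned.
    """
    ph_missing = ph is None or (isinstance(ph, float) and math.isnan(ph))
    bic_missing = bicarbonate is None or (
        isinstance(bicarbonate, float) and math.isnan(bicarbonate))
    if ph_missing and bic_missing:
        return None
    flag = False
    if not ph_missing:
        flag = flag or ph < DKA_PH_CUTOFF
    if not bic_missing:
        flag = flag or bicarbonate < DKA_BICARBONATE_CUTOFF
    return bool(flag)


def derive_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns (idaa1c, remission, dka) to a clinical table.

    Expects columns ``hba1c``, ``insulin_dose``, ``ph``, ``bicarbonate``.
    """
    out = records.copy()
    out["idaa1c"] = [idaa1c(h, d) for h, d in
                     zip(out["hba1c"], out["insulin_dose"])]
    out["remission"] = out["idaa1c"].map(remission)
    out["dka"] = [dka(p, b) for p, b in zip(out["ph"], out["bicarbonate"])]
    return out
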