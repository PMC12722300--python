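"""Reading and writing the package's tabular interchange formats.

Clonotype tables travel as AIRR Rearrangement TSV (standard columns
``cell_id``, ``locus``, ``productive``, ``junction``, ``junction_aa``,
``v_call``, ``d_call``, ``j_call`` plus custom ``donor_id``,
``timepoint``, ``group``, ``subset``); everything else is headered CSV.
A JSON sidecar stores generator ground truth and the seed."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

AIRR_COLUMNS = [
    "cell_id", "locus", "productive", "junction", "junction_aa",
    "v_call", "d_call", "j_call",
    "donor_id", "timepoint", "group", "subset",
]


def write_airr(df: pd.DataFrame, path) -> None:
    """Write rearrangement rows as AIRR TSV (missing columns filled empty)."""
    out = df.copy()
    for col in AIRR_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out[AIRR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_airr(path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV, keeping junctions as strings."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_truth_sidecar(truth: dict, seed: int, path) -> None:
    """Store generator ground truth + seed as JSON next to the data."""
    def _default(o):
        if isinstance(o, set):
            return sorted(o)
        if hasattr(o, "item"):
            return o.item()
        if isinstance(o, dict):
            return {str(k): v for k, v in o.items()}
        return str(o)

    payload = {"seed": seed,
               "truth": {k: _default(v) if isinstance(v, set) else v
                         for k, v in truth.items()}}
    Path(path).write_text(json.dumps(payload, default=_default, indent=1))


def read_truth_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
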