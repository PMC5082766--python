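"""The cohort container and its on-disk CSV dialect.

A cohort is a validated per-subject table of demographics, health covariates
and brain morphometrics, plus provenance describing where it came from
(generator configuration and seed, or a source file).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError

#: Canonical column order of the cohort CSV.
COLUMNS = [
    "subject_id", "age", "sex", "bmi", "icv", "wm_volume", "surface_area",
    "thickness", "gw_contrast", "cattell", "qc",
    "high_bp", "diabetes", "cancer", "mi", "stroke", "high_chol",
    "degree", "income_above", "smoker", "activity",
]

FLAG_COLUMNS = ["high_bp", "diabetes", "cancer", "mi", "stroke", "high_chol",
                "degree", "income_above", "smoker"]

QC_CATEGORIES = ("good", "adequate", "poor")
SEX_CATEGORIES = ("female", "male")


@dataclass
class Cohort:
    """A validated collection of subject records plus provenance."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise InputError(f"cohort is missing columns: {missing}")
        df = self.df
        if len(df) == 0:
            raise InputError("cohort is empty")
        for col, cond in [("age", df["age"] >= 0), ("bmi", df["bmi"] > 0),
                          ("icv", df["icv"] > 0), ("wm_volume", df["wm_volume"] > 0)]:
            bad = ~cond.fillna(False)
            if bad.any():
                ids = df.loc[bad, "subject_id"].tolist()[:5]
                raise InputError(f"invalid {col} for subjects {ids}")
        bad_qc = ~df["qc"].isin(QC_CATEGORIES)
        if bad_qc.any():
            raise InputError(
                f"qc must be one of {QC_CATEGORIES}; offending subjects "
                f"{df.loc[bad_qc, 'subject_id'].tolist()[:5]}")
        bad_sex = ~df["sex"].isin(SEX_CATEGORIES)
        if bad_sex.any():
            raise InputError(f"sex must be one of {SEX_CATEGORIES}")

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write the cohort CSV (deterministic byte layout) plus a JSON sidecar
        carrying the provenance (generator config and seed, or source path)."""
        path = Path(path)
        out = self.df.loc[:, COLUMNS]
        out.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
        if sidecar:
            side = path.with_suffix(".json")
            side.write_text(json.dumps(_jsonable(self.provenance),
                                       indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        df = pd.read_csv(path)
        prov = {"source": str(path)}
        side = path.with_suffix(".json")
        if side.exists():
            prov["sidecar"] = json.loads(side.read_text())
        return cls(df=df, provenance=prov)

    def replace(self, df: pd.DataFrame, **prov_updates) -> "Cohort":
        prov = dict(self.provenance)
        prov.update(prov_updates)
        return Cohort(df=df.reset_index(drop=True), provenance=prov)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and tuples for JSON output."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
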