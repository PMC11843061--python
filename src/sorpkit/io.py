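"""CSV contracts and the in-memory cohort bundle.

A cohort is exchanged as five long-format CSV files:

* ``measurements.csv`` — patient_id, time, channel, value
* ``medications.csv``  — patient_id, time, drug_class (``antibiotic`` / ``vasopressor``)
* ``fluids.csv``       — patient_id, start, end, volume_ml
* ``cultures.csv``     — patient_id, time
* ``patients.csv``     — patient_id, weight_kg, icu_in, icu_out, death_time

Timestamps are ISO-8601.  Internally every module works in float hours from
each patient's ICU admission; :meth:`CohortBundle.in_hours` performs the
conversion once, and numeric time columns are passed through unchanged (they
are taken to already be hours from admission).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("sorpkit.io")

MEASUREMENT_COLS = ["patient_id", "time", "channel", "value"]
MEDICATION_COLS = ["patient_id", "time", "drug_class"]
FLUID_COLS = ["patient_id", "start", "end", "volume_ml"]
CULTURE_COLS = ["patient_id", "time"]
PATIENT_COLS = ["patient_id", "weight_kg", "icu_in", "icu_out", "death_time"]

_FILES = {
    "measurements": MEASUREMENT_COLS,
    "medications": MEDICATION_COLS,
    "fluids": FLUID_COLS,
    "cultures": CULTURE_COLS,
    "patients": PATIENT_COLS,
}


class SchemaError(ValueError):
    """An input table is missing a required column."""


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _hours_from_admission(
    times: pd.Series, patient_ids: pd.Series, icu_in: pd.Series
) -> pd.Series:
    """Convert a timestamp column to float hours from each patient's icu_in."""
    if pd.api.types.is_numeric_dtype(times):
        return times.astype(float)
    t = pd.to_datetime(times)
    base = patient_ids.map(icu_in)
    return (t - pd.to_datetime(base)).dt.total_seconds() / 3600.0


@dataclass
class CohortBundle:
    """The five event tables of a cohort, plus optional ground truth."""

    measurements: pd.DataFrame
    medications: pd.DataFrame
    fluids: pd.DataFrame
    cultures: pd.DataFrame
    patients: pd.DataFrame
    truth: Optional[pd.DataFrame] = None

    def validate(self) -> "CohortBundle":
        for name, cols in _FILES.items():
            _require_columns(getattr(self, name), cols, f"{name}.csv")
        bad = ~self.patients["weight_kg"].isna() & (self.patients["weight_kg"] <= 0)
        if bad.any():
            raise SchemaError("patients.csv: weight_kg must be > 0 where present")
        if (self.fluids["volume_ml"] < 0).any():
            raise SchemaError("fluids.csv: volume_ml must be >= 0")
        return self

    def in_hours(self) -> "CohortBundle":
        """Return a copy with all time columns as float hours from icu_in."""
        pats = self.patients.copy()
        icu_in = pats.set_index("patient_id")["icu_in"]
        meas = self.measurements.copy()
        meas["time"] = _hours_from_admission(meas["time"], meas["patient_id"], icu_in)
        meds = self.medications.copy()
        meds["time"] = _hours_from_admission(meds["time"], meds["patient_id"], icu_in)
        cult = self.cultures.copy()
        cult["time"] = _hours_from_admission(cult["time"], cult["patient_id"], icu_in)
        flu = self.fluids.copy()
        flu["start"] = _hours_from_admission(flu["start"], flu["patient_id"], icu_in)
        flu["end"] = _hours_from_admission(flu["end"], flu["patient_id"], icu_in)
        if pd.api.types.is_numeric_dtype(pats["icu_in"]):
            stay = pats["icu_out"].astype(float) - pats["icu_in"].astype(float)
        else:
            stay = (
                pd.to_datetime(pats["icu_out"]) - pd.to_datetime(pats["icu_in"])
            ).dt.total_seconds() / 3600.0
        pats["stay_h"] = stay
        return replace(
            self, measurements=meas, medications=meds, cultures=cult,
            fluids=flu, patients=pats,
        )

    @property
    def stay_hours(self) -> pd.Series:
        """Stay length in hours indexed by patient_id (requires in_hours())."""
        if "stay_h" not in self.patients.columns:
            raise ValueError("call in_hours() before querying stay_hours")
        return self.patients.set_index("patient_id")["stay_h"]

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in _FILES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(out / "truth.csv", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "CohortBundle":
        ind = Path(indir)
        frames = {}
        for name in _FILES:
            path = ind / f"{name}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing required input file: {path}")
            frames[name] = pd.read_csv(path)
        truth_path = ind / "truth.csv"
        truth = pd.read_csv(truth_path) if truth_path.exists() else None
        return cls(truth=truth, **frames).validate()
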