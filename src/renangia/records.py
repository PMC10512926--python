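"""Patient-level data model and cohort CSV I/O.

One :class:`PatientRecord` describes a single PICU admission: demographics,
the day-0 clinical flags that feed the renal angina risk strata, the serum
creatinine series (baseline if known, day 0, day 3) in µmol/L, the first
8-hour fluid balance in litres, day-3 urine output, and outcomes.

The cohort CSV dialect is one row per patient, a header with exactly the
field names of :class:`PatientRecord`, an empty cell meaning "missing",
UTF-8 encoded.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "DIAGNOSIS_CATEGORIES",
    "PatientRecord",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
    "frame_to_records",
    "MG_DL_TO_UMOL_L",
    "scr_mg_dl_to_umol_l",
]

DIAGNOSIS_CATEGORIES = (
    "CNS",
    "sepsis",
    "endocrine",
    "cardiovascular",
    "severe_malaria",
    "respiratory",
    "other",
)

#: conversion factor for serum creatinine, 1 mg/dL = 88.4 µmol/L
MG_DL_TO_UMOL_L = 88.4


def scr_mg_dl_to_umol_l(value_mg_dl: float) -> float:
    """Convert a serum creatinine from mg/dL to µmol/L (I/O convenience only;
    everything inside the package works in µmol/L)."""
    return value_mg_dl * MG_DL_TO_UMOL_L


class PatientRecord(BaseModel):
    """A single PICU admission.

    Creatinine values are µmol/L and strictly positive; fluids are litres;
    ``baseline_scr_umol_l`` may be absent, in which case ``height_cm`` must be
    present so the baseline can be imputed from an assumed creatinine
    clearance of 120 mL/min/1.73 m².
    """

    model_config = ConfigDict(extra="forbid")

    patient_id: str
    age_years: float = Field(ge=0.0)
    sex: Literal["male", "female"]
    height_cm: Optional[float] = Field(default=None, gt=0.0)
    weight_kg: float = Field(gt=0.0)
    diagnosis_category: Literal[DIAGNOSIS_CATEGORIES] = "other"  # type: ignore[valid-type]
    icu_admission: bool = True
    transplant_history: bool = False
    mechanical_ventilation_8h: bool = False
    vasopressor_support_8h: bool = False
    baseline_scr_umol_l: Optional[float] = Field(default=None, gt=0.0)
    d0_scr_umol_l: float = Field(gt=0.0)
    d3_scr_umol_l: Optional[float] = Field(default=None, gt=0.0)
    fluid_in_l_8h: Optional[float] = Field(default=None, ge=0.0)
    fluid_out_l_8h: Optional[float] = Field(default=None, ge=0.0)
    d3_urine_output_ml_kg_h: Optional[float] = Field(default=None, ge=0.0)
    d3_urine_output_duration_h: Optional[float] = Field(default=None, ge=0.0)
    died_in_picu: bool = False
    picu_los_days: float = Field(default=0.0, ge=0.0)
    ventilation_days: float = Field(default=0.0, ge=0.0)
    received_rrt: bool = False

    @model_validator(mode="after")
    def _baseline_or_height(self) -> "PatientRecord":
        if self.baseline_scr_umol_l is None and self.height_cm is None:
            raise ValueError(
                "baseline_scr_umol_l is absent and height_cm is absent: "
                "one of the two is required to establish a baseline creatinine"
            )
        return self


_FIELD_ORDER = list(PatientRecord.model_fields)

_BOOL_FIELDS = [
    "icu_admission",
    "transplant_history",
    "mechanical_ventilation_8h",
    "vasopressor_support_8h",
    "died_in_picu",
    "received_rrt",
]

_TRUE_STRINGS = {"true", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "0", "no", "n"}


def _coerce_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame with the CSV dialect's column order."""
    rows = [r.model_dump() for r in records]
    return pd.DataFrame(rows, columns=_FIELD_ORDER)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Parse a cohort DataFrame (e.g. from :func:`pandas.read_csv`) into records.

    NaN / empty cells become ``None``; boolean columns accept true/false,
    yes/no, 1/0.
    """
    records = []
    for _, row in frame.iterrows():
        payload = {}
        for key, value in row.items():
            if key not in PatientRecord.model_fields:
                continue
            if pd.isna(value):
                continue
            if key in _BOOL_FIELDS:
                value = _coerce_bool(value)
            payload[key] = value
        records.append(PatientRecord(**payload))
    return records


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV in the standard dialect into validated records."""
    frame = pd.read_csv(path)
    return frame_to_records(frame)


def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> None:
    """Write records as a cohort CSV (empty cell = missing)."""
    records_to_frame(records).to_csv(path, index=False)
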