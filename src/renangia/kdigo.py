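"""KDIGO acute-kidney-injury staging and severe-AKI (sAKI) adjudication.

Stage assignment on day 3 from the creatinine series and, where documented,
urine output:

* stage 1 — day-3 creatinine 1.5–1.9× baseline, or an absolute rise of
  ≥ 26.5 µmol/L (0.3 mg/dL) within 48 h when such a pair exists;
* stage 2 — 2.0–2.9× baseline, or urine output ≤ 0.5 mL/kg/h sustained for
  ≥ 8 h (the study rule; the KDIGO-standard ≥ 12 h window is available via
  ``uo_severe_hours``);
* stage 3 — ≥ 3.0× baseline, or receipt of renal replacement therapy.

Severe AKI is stage ≥ 2.  Reading "an increase of 200% from baseline" as
*reaching* 2.0× baseline matches the KDIGO stage-2 band (2.0–2.9×); the
alternative reading (a 200% rise, i.e. 3×) is not used because it would
collapse stages 2 and 3.  A ≥ 50% fall in estimated creatinine clearance is
mathematically the same criterion: with eCrCl = k·height/SCr at fixed
height, halving the clearance is exactly doubling the creatinine.

Patients lacking urine-output documentation are staged on creatinine alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import math

from .errors import InvalidInputError
from .records import PatientRecord
from .scoring import ScoreConfig, rai_original, _resolve_baseline

__all__ = [
    "AKIAssessment",
    "CohortAdjudication",
    "estimated_crcl",
    "kdigo_stage",
    "adjudicate_cohort",
]

Basis = Literal["none", "creatinine_ratio", "urine_output", "absolute_rise", "rrt"]

# reporting tie-break when several criteria reach the same stage
_BASIS_ORDER: tuple[Basis, ...] = ("creatinine_ratio", "urine_output", "absolute_rise", "rrt")

#: absolute 48-h creatinine rise that qualifies as stage 1, µmol/L (0.3 mg/dL)
ABSOLUTE_RISE_UMOL_L = 26.5


def estimated_crcl(height_cm: float, scr_umol_l: float, k_umol_cm: float = 36.5) -> float:
    """Height-based estimated creatinine clearance, mL/min/1.73 m²."""
    if height_cm <= 0:
        raise InvalidInputError(f"height_cm must be positive, got {height_cm!r}")
    if scr_umol_l <= 0:
        raise InvalidInputError(f"scr_umol_l must be positive, got {scr_umol_l!r}")
    return k_umol_cm * height_cm / scr_umol_l


@dataclass(frozen=True)
class AKIAssessment:
    """KDIGO stage and severity for one patient on day 3."""

    stage: int
    severe: bool
    basis: Basis
    ratio_d3: float

    def __post_init__(self):
        assert self.severe == (self.stage >= 2)


@dataclass(frozen=True)
class CohortAdjudication:
    assessments: list[AKIAssessment]
    n_assessed: int
    n_aki: int
    n_severe: int

    @property
    def prevalence(self) -> float:
        """Severe-AKI prevalence (proportion of assessed patients)."""
        return self.n_severe / self.n_assessed

    @property
    def aki_proportion(self) -> float:
        return self.n_aki / self.n_assessed

    def prevalence_ci(self, z: float = 1.96) -> tuple[float, float]:
        """Untruncated Wald 95% CI on the severe-AKI prevalence."""
        p, n = self.prevalence, self.n_assessed
        half = z * math.sqrt(p * (1.0 - p) / n)
        return (p - half, p + half)


def kdigo_stage(
    baseline_scr: float,
    current_scr: float,
    scr_rise_48h_umol: Optional[float] = None,
    uo_ml_kg_h: Optional[float] = None,
    uo_duration_h: Optional[float] = None,
    received_rrt: bool = False,
    *,
    uo_severe_hours: float = 8.0,
) -> AKIAssessment:
    """Stage AKI from the baseline→current creatinine ratio, an optional 48-h
    absolute rise, optional urine output, and RRT receipt.

    ``uo_severe_hours`` is the minimum duration of oliguria
    (≤ 0.5 mL/kg/h) that qualifies as severe: 8 h by default, 12 h for the
    KDIGO-standard rule.
    """
    if baseline_scr is None or baseline_scr <= 0:
        raise InvalidInputError(f"baseline_scr must be positive, got {baseline_scr!r}")
    if current_scr is None or current_scr <= 0:
        raise InvalidInputError(f"current_scr must be positive, got {current_scr!r}")

    ratio = current_scr / baseline_scr
    stages: dict[Basis, int] = {}

    if ratio >= 3.0:
        stages["creatinine_ratio"] = 3
    elif ratio >= 2.0:
        stages["creatinine_ratio"] = 2
    elif ratio >= 1.5:
        stages["creatinine_ratio"] = 1
    if received_rrt:
        stages["rrt"] = 3
    if (
        uo_ml_kg_h is not None
        and uo_duration_h is not None
        and uo_ml_kg_h <= 0.5
        and uo_duration_h >= uo_severe_hours
    ):
        stages["urine_output"] = 2
    if scr_rise_48h_umol is not None and scr_rise_48h_umol >= ABSOLUTE_RISE_UMOL_L:
        stages["absolute_rise"] = 1

    if not stages:
        return AKIAssessment(stage=0, severe=False, basis="none", ratio_d3=ratio)
    stage = max(stages.values())
    basis = next(b for b in _BASIS_ORDER if stages.get(b) == stage)
    return AKIAssessment(stage=stage, severe=stage >= 2, basis=basis, ratio_d3=ratio)


def adjudicate_cohort(
    records: list[PatientRecord],
    config: Optional[ScoreConfig] = None,
    *,
    uo_severe_hours: float = 8.0,
) -> CohortAdjudication:
    """Adjudicate every record with day-3 data; ``config`` supplies the
    baseline-imputation constants (original-index defaults if omitted).

    Day-0 and day-3 samples are more than 48 h apart, so the absolute-rise
    criterion has no qualifying pair in this data model and is not applied.
    """
    if not records:
        raise InvalidInputError("cohort is empty")
    config = config or rai_original()
    assessments = []
    for record in records:
        if record.d3_scr_umol_l is None:
            raise InvalidInputError(
                f"record {record.patient_id!r} lacks d3_scr_umol_l; "
                "day-3 creatinine is required for adjudication"
            )
        baseline, _ = _resolve_baseline(record, config)
        assessments.append(
            kdigo_stage(
                baseline,
                record.d3_scr_umol_l,
                uo_ml_kg_h=record.d3_urine_output_ml_kg_h,
                uo_duration_h=record.d3_urine_output_duration_h,
                received_rrt=record.received_rrt,
                uo_severe_hours=uo_severe_hours,
            )
        )
    n_aki = sum(a.stage >= 1 for a in assessments)
    n_severe = sum(a.severe for a in assessments)
    return CohortAdjudication(
        assessments=assessments,
        n_assessed=len(assessments),
        n_aki=n_aki,
        n_severe=n_severe,
    )
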