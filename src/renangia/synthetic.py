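"""Seedable synthetic PICU cohorts for end-to-end testing without patient data.

Two modes:

* **fixed-margin** — a deterministic 122-patient cohort whose 2×2 margins
  against severe AKI (renal-angina positivity 10/18 vs 15/104, elevated
  day-0 creatinine 16/18 vs 66/104, mortality 7/18 vs 13/104) are exact by
  construction, so the screening-metric tables can be reproduced to the
  printed digit;
* **stochastic** — labels sampled from configurable conditional
  probabilities, for law-of-large-numbers and property checks.

Creatinine trajectories are synthesized *backward from the sampled labels*:
severe-AKI status fixes the day-3/baseline ratio, the renal-angina tier
fixes the day-0/baseline fold-change, and the baseline itself comes from a
height-for-age model (or is imputed downstream).  Re-scoring and
re-adjudicating a generated cohort therefore recovers the sampled labels
exactly, which is the round-trip contract the tests rely on.  The generator
emulates the *statistical* structure of a PICU cohort, not renal physiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, InvalidInputError
from .kdigo import adjudicate_cohort
from .records import DIAGNOSIS_CATEGORIES, PatientRecord
from .scoring import compute_rai, rai_original

__all__ = ["CohortConfig", "generate", "generate_with_labels", "round_trip_check", "RoundTripReport"]

# Table-style diagnosis mix of a low-resource PICU (proportions of 122)
_DEFAULT_DIAGNOSIS_PROBS = {
    "CNS": 57 / 122,
    "sepsis": 17 / 122,
    "endocrine": 12 / 122,
    "cardiovascular": 10 / 122,
    "severe_malaria": 8 / 122,
    "respiratory": 7 / 122,
    "other": 11 / 122,
}


class CohortConfig(BaseModel):
    """Cohort structure: sample size, outcome prevalence, conditional
    renal-angina positivity, diagnosis mix, age mixture, outcome rates."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=122, gt=0)
    prevalence_saki: float = Field(default=18 / 122, gt=0.0, lt=1.0)
    p_rai_pos_given_saki: float = Field(default=10 / 18, ge=0.0, le=1.0)
    p_rai_pos_given_no_saki: float = Field(default=15 / 104, ge=0.0, le=1.0)
    p_stage1_given_no_saki: float = Field(default=10 / 104, ge=0.0, le=1.0)
    p_rrt_given_saki: float = Field(default=1 / 18, ge=0.0, le=1.0)
    diagnosis_probs: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_DIAGNOSIS_PROBS)
    )
    p_infant: float = Field(default=0.295, ge=0.0, le=1.0)
    p_vent_vaso: float = Field(default=21 / 122, ge=0.0, le=1.0)
    mortality_given_saki: float = Field(default=7 / 18, ge=0.0, le=1.0)
    mortality_given_no_saki: float = Field(default=13 / 104, ge=0.0, le=1.0)
    fo_missing_rate: float = Field(default=75 / 122, ge=0.0, le=1.0)
    measured_baseline_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    seed: int = 0
    fixed_margin_mode: bool = False

    @model_validator(mode="after")
    def _check_simplex(self) -> "CohortConfig":
        if set(self.diagnosis_probs) != set(DIAGNOSIS_CATEGORIES):
            raise ValueError(
                f"diagnosis_probs must cover exactly {DIAGNOSIS_CATEGORIES}"
            )
        probs = list(self.diagnosis_probs.values())
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("diagnosis_probs must be a simplex (non-negative, sum 1)")
        return self


@dataclass(frozen=True)
class RoundTripReport:
    n: int
    mismatches: list[dict]

    @property
    def ok(self) -> bool:
        return not self.mismatches


def _height_weight(age: float, rng: np.random.Generator) -> tuple[float, float]:
    """Rough pediatric growth model with mild jitter; label-invariant."""
    if age < 1.0:
        height = 52.0 + 22.0 * age
        weight = 3.5 + 6.0 * age
    else:
        height = 76.0 + 6.2 * age
        weight = 2.0 * age + 8.5
    height *= float(rng.uniform(0.95, 1.05))
    weight *= float(rng.uniform(0.9, 1.1))
    return height, weight


# ΔSCr fold-change realizing each injury tier (tier -> representative delta)
_TIER_DELTA = {1: 1.0, 2: 1.25, 4: 1.7, 8: 2.2}


def _fixed_margin_rows() -> list[dict]:
    """The deterministic 122-row label table.

    Counts are chosen so every conditional margin used in acceptance testing
    is exact: 18 severe of 122; renal angina positive 10/18 and 15/104;
    elevated day-0 creatinine (ΔSCr > 1) 16/18 and 66/104; deaths 7/18 and
    13/104; one RRT recipient; 28 any-stage AKI; 13 of the 18 severe aged
    ≤ 5 years; ventilation+vasopressors 6/18 and 15/104.
    """
    rows: list[dict] = []

    # --- severe-AKI group (18) -------------------------------------------
    saki_deltas = [1.0] * 2 + [1.25] * 3 + [1.7] * 9 + [2.2] * 4
    saki_vent = {5, 6, 7, 8, 9, 10}          # six of the nine tier-4 patients
    saki_ages = list(np.linspace(0.25, 0.95, 11)) + [2.5, 4.0, 7.0, 9.0, 11.0, 12.0, 14.0]
    saki_dx = (
        ["sepsis"] * 7 + ["CNS"] * 4 + ["severe_malaria"] * 2
        + ["respiratory"] * 2 + ["endocrine"] * 1 + ["other"] * 2
    )
    for i in range(18):
        rows.append(
            dict(
                saki=True,
                delta=saki_deltas[i],
                vent_vaso=i in saki_vent,
                vaso_only=False,
                age=float(saki_ages[i]),
                diagnosis=saki_dx[i],
                ratio3=3.4 if i == 14 else 2.3,
                rrt=i == 14,
                died=i < 7,
                los=8.0,
                vent_days=4.0 if i in saki_vent else 0.0,
            )
        )

    # --- non-severe group (104) ------------------------------------------
    deltas = [1.0] * 38 + [1.25] * 39 + [1.6] * 27
    vent = set(range(38 + 4, 38 + 12)) | set(range(77 + 3, 77 + 10))  # 8 + 7
    vaso_only = {0, 1}
    stage1 = set(range(38, 48))                                       # 10 stage-1 patients
    dead = set(range(2, 15))                                          # 13 deaths
    dx = (
        ["CNS"] * 53 + ["sepsis"] * 10 + ["endocrine"] * 11 + ["cardiovascular"] * 10
        + ["severe_malaria"] * 6 + ["respiratory"] * 5 + ["other"] * 9
    )
    ages = (
        list(np.linspace(0.15, 0.95, 25))
        + list(np.linspace(2.0, 5.0, 22))
        + list(np.linspace(6.0, 10.0, 25))
        + list(np.linspace(11.0, 16.0, 32))
    )
    for i in range(104):
        rows.append(
            dict(
                saki=False,
                delta=deltas[i],
                vent_vaso=i in vent,
                vaso_only=i in vaso_only,
                age=float(ages[i]),
                diagnosis=dx[i],
                ratio3=1.6 if i in stage1 else 0.85,
                rrt=False,
                died=i in dead,
                los=6.0,
                vent_days=3.0 if i in vent else 0.0,
            )
        )
    return rows


def _stochastic_rows(config: CohortConfig, rngs: dict[str, np.random.Generator]) -> list[dict]:
    rows = []
    categories = list(config.diagnosis_probs)
    probs = np.array([config.diagnosis_probs[c] for c in categories])
    probs = probs / probs.sum()
    for _ in range(config.n_patients):
        saki = bool(rngs["outcome"].random() < config.prevalence_saki)
        p_pos = config.p_rai_pos_given_saki if saki else config.p_rai_pos_given_no_saki
        rai_pos = bool(rngs["score"].random() < p_pos)
        vent_vaso = bool(rngs["score"].random() < config.p_vent_vaso)
        # injury tier consistent with the sampled positivity and risk stratum:
        # risk 5 (vent+vaso) is positive from injury >= 2; risk 1 needs 8.
        if rai_pos:
            tier = int(rngs["score"].choice([2, 4, 8])) if vent_vaso else 8
        else:
            tier = 1 if vent_vaso else int(rngs["score"].choice([1, 2, 4]))
        delta = _TIER_DELTA[tier]
        if tier == 1:
            delta = float(rngs["score"].uniform(0.85, 1.0))
        if saki:
            if rngs["outcome"].random() < 0.15:
                ratio3 = float(rngs["outcome"].uniform(3.0, 4.0))
            else:
                ratio3 = float(rngs["outcome"].uniform(2.05, 2.9))
            rrt = bool(rngs["outcome"].random() < config.p_rrt_given_saki)
            died = bool(rngs["outcome"].random() < config.mortality_given_saki)
        else:
            if rngs["outcome"].random() < config.p_stage1_given_no_saki:
                ratio3 = float(rngs["outcome"].uniform(1.5, 1.95))
            else:
                ratio3 = float(rngs["outcome"].uniform(0.7, 1.4))
            rrt = False
            died = bool(rngs["outcome"].random() < config.mortality_given_no_saki)
        if rngs["age"].random() < config.p_infant:
            age = float(rngs["age"].uniform(1 / 12, 1.0))
        else:
            age = float(rngs["age"].uniform(1.0, 16.0))
        rows.append(
            dict(
                saki=saki,
                delta=delta,
                vent_vaso=vent_vaso,
                vaso_only=bool(not vent_vaso and rngs["score"].random() < 0.03),
                age=age,
                diagnosis=str(rngs["diagnosis"].choice(categories, p=probs)),
                ratio3=ratio3,
                rrt=rrt,
                died=died,
                los=float(rngs["outcome"].negative_binomial(4, 0.4) + 1),
                vent_days=float(rngs["outcome"].negative_binomial(3, 0.5) + 1) if vent_vaso else 0.0,
            )
        )
    return rows


def generate_with_labels(config: CohortConfig) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a cohort and return it with the sampled label table
    (columns ``saki``, ``rai_positive``, ``elevated_d0``, ``died``)."""
    root = np.random.SeedSequence(config.seed)
    streams = ["layout", "anthro", "labs", "outcome", "score", "age", "diagnosis"]
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(streams, root.spawn(len(streams)))
    }

    rows = _fixed_margin_rows() if config.fixed_margin_mode else _stochastic_rows(config, rngs)
    order = rngs["layout"].permutation(len(rows))
    rows = [rows[i] for i in order]

    records, labels = [], []
    for i, row in enumerate(rows):
        height, weight = _height_weight(row["age"], rngs["anthro"])
        height = round(height, 1)  # rounded BEFORE imputation so the scorer
        # recovers the exact baseline the trajectory was built from
        imputed_baseline = 36.5 * height / 120.0
        if rngs["labs"].random() < config.measured_baseline_rate:
            baseline = round(imputed_baseline * float(rngs["labs"].uniform(0.8, 1.2)), 2)
        else:
            baseline = None
        effective = baseline if baseline is not None else imputed_baseline
        d0 = effective * row["delta"]
        d3 = effective * row["ratio3"]
        fo_missing = rngs["labs"].random() < config.fo_missing_rate
        if fo_missing:
            fluid_in = fluid_out = None
        else:
            # net balance kept under the 5% tier so %FO never alters the
            # sampled injury tier
            net_pct = float(rngs["labs"].uniform(0.0, 4.5))
            fluid_out = round(float(rngs["labs"].uniform(0.1, 0.5)), 3)
            fluid_in = round(fluid_out + net_pct * weight / 100.0, 3)
        records.append(
            PatientRecord(
                patient_id=f"SYN{i:04d}",
                age_years=round(row["age"], 3),
                sex="male" if rngs["anthro"].random() < 0.55 else "female",
                height_cm=height,
                weight_kg=round(weight, 2),
                diagnosis_category=row["diagnosis"],
                icu_admission=True,
                transplant_history=False,
                mechanical_ventilation_8h=row["vent_vaso"],
                vasopressor_support_8h=row["vent_vaso"] or row["vaso_only"],
                baseline_scr_umol_l=baseline,
                d0_scr_umol_l=d0,
                d3_scr_umol_l=d3,
                fluid_in_l_8h=fluid_in,
                fluid_out_l_8h=fluid_out,
                died_in_picu=row["died"],
                picu_los_days=row["los"],
                ventilation_days=row["vent_days"],
                received_rrt=row["rrt"],
            )
        )
        labels.append(
            dict(
                patient_id=f"SYN{i:04d}",
                saki=row["saki"],
                rai_positive=_intended_rai_positive(row),
                elevated_d0=row["delta"] > 1.0,
                died=row["died"],
            )
        )
    return records, pd.DataFrame(labels)


def _intended_rai_positive(row: dict) -> bool:
    risk = 5 if row["vent_vaso"] else 1
    return risk * _delta_tier(row["delta"]) >= 8


def _delta_tier(delta: float) -> int:
    if delta >= 2.0:
        return 8
    if delta >= 1.5:
        return 4
    if delta > 1.0:
        return 2
    return 1


def generate(config: CohortConfig) -> list[PatientRecord]:
    """Generate a synthetic cohort; the seed fully determines the output."""
    if not isinstance(config, CohortConfig):
        raise ConfigurationError("generate expects a CohortConfig")
    records, _ = generate_with_labels(config)
    return records


def round_trip_check(config: CohortConfig) -> RoundTripReport:
    """Regenerate the cohort, re-score it with the original index and
    re-adjudicate severity, and compare against the sampled labels."""
    records, labels = generate_with_labels(config)
    score_config = rai_original()
    adjudication = adjudicate_cohort(records, score_config)
    mismatches = []
    for record, (_, label), assessment in zip(records, labels.iterrows(), adjudication.assessments):
        result = compute_rai(record, score_config)
        if result.positive != label["rai_positive"]:
            mismatches.append(
                dict(patient_id=record.patient_id, field="rai_positive",
                     expected=bool(label["rai_positive"]), observed=result.positive)
            )
        if assessment.severe != label["saki"]:
            mismatches.append(
                dict(patient_id=record.patient_id, field="saki",
                     expected=bool(label["saki"]), observed=assessment.severe)
            )
        elevated = result.delta_scr > 1.0
        if elevated != label["elevated_d0"]:
            mismatches.append(
                dict(patient_id=record.patient_id, field="elevated_d0",
                     expected=bool(label["elevated_d0"]), observed=elevated)
            )
    return RoundTripReport(n=len(records), mismatches=mismatches)
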