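"""Renal angina index (RAI) scoring.

The RAI screens critically ill children on the day of PICU admission for the
risk of developing severe acute kidney injury by day 3.  It is the product of

* a **risk score** from the patient's context — ICU admission (weight 1),
  a history of stem-cell/solid-organ transplantation (3), or receipt of both
  mechanical ventilation and vasopressors within 8 h of admission (5) — and
* an **injury score** from early functional change — the fold-change of
  day-0 serum creatinine over baseline (ΔSCr) and/or the percent fluid
  overload accumulated over the first 8 h (%FO), each mapped through ordered
  tiers to a score in {1, 2, 4, 8}; the larger of the two signals is used.

A product of 8 or more is "renal angina positive".  In the original index
the risk score is the single highest applicable stratum; the locally
modified index (mRAI) instead *sums* the weights of all applicable local
risk factors and multiplies by the creatinine-based injury score only.

When no measured baseline creatinine exists it is imputed by inverting the
height-based (Schwartz) creatinine-clearance estimate at an assumed clearance
of 120 mL/min/1.73 m²: BSCr = k · height / 120 with k = 36.5 µmol·cm⁻¹
(0.413 mg/dL·cm⁻¹ × 88.4).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, InvalidInputError
from .records import PatientRecord

__all__ = [
    "Tier",
    "ScoreConfig",
    "RAIResult",
    "RISK_PREDICATES",
    "rai_original",
    "mrai_local",
    "load_score_config",
    "impute_baseline_scr",
    "delta_scr",
    "percent_fluid_overload",
    "risk_score",
    "injury_score",
    "compute_rai",
    "compute_mrai",
    "enumerate_achievable_scores",
]


class Tier(BaseModel):
    """One injury tier: applies when the signal exceeds ``lower`` (``>=`` when
    ``inclusive``, strict ``>`` otherwise)."""

    model_config = ConfigDict(frozen=True)

    lower: float
    score: int = Field(gt=0)
    inclusive: bool = True


# ΔSCr tiers: exactly 1.0 ("no change") scores 1, (1.0, 1.5) scores 2,
# [1.5, 2.0) scores 4, >= 2.0 scores 8.  The first tier is open at 1.0.
_DSCR_TIERS = (
    Tier(lower=1.0, score=2, inclusive=False),
    Tier(lower=1.5, score=4),
    Tier(lower=2.0, score=8),
)

# %FO tiers: <5% scores 1, [5,10) scores 2, [10,15) scores 4, >=15 scores 8.
_FO_TIERS = (
    Tier(lower=5.0, score=2),
    Tier(lower=10.0, score=4),
    Tier(lower=15.0, score=8),
)

ORIGINAL_RISK_WEIGHTS = {
    "icu_admission": 1,
    "transplant_history": 3,
    "ventilation_and_vasopressors": 5,
}

# Placeholder local-risk-factor weights for the modified index (synthetic —
# chosen so the maximum achievable risk sum is 20 and the maximum score
# 20 × 8 = 160); the engine is agnostic to the exact weight set.
MRAI_LOCAL_RISK_WEIGHTS = {
    "icu_admission": 1,
    "sepsis_admission": 7,
    "ventilation_and_vasopressors": 5,
    "severe_malaria_admission": 4,
    "age_under_5": 3,
}

#: risk-condition name -> predicate over a PatientRecord
RISK_PREDICATES: dict[str, Callable[[PatientRecord], bool]] = {
    "icu_admission": lambda r: r.icu_admission,
    "transplant_history": lambda r: r.transplant_history,
    "ventilation_and_vasopressors": lambda r: (
        r.mechanical_ventilation_8h and r.vasopressor_support_8h
    ),
    "mechanical_ventilation": lambda r: r.mechanical_ventilation_8h,
    "vasopressor_support": lambda r: r.vasopressor_support_8h,
    "sepsis_admission": lambda r: r.diagnosis_category == "sepsis",
    "severe_malaria_admission": lambda r: r.diagnosis_category == "severe_malaria",
    "age_under_5": lambda r: r.age_years <= 5.0,
}

#: factors that hold for every cohort-eligible record (all are ICU admissions)
ALWAYS_ON_FACTORS = frozenset({"icu_admission"})


class ScoreConfig(BaseModel):
    """Tier boundaries, risk weights and positivity cutoff for an index."""

    model_config = ConfigDict(frozen=True)

    risk_weights: dict[str, int]
    injury_dscr_tiers: tuple[Tier, ...] = _DSCR_TIERS
    injury_fo_tiers: tuple[Tier, ...] = _FO_TIERS
    positivity_cutoff: int = Field(default=8, gt=0)
    mrai_mode: bool = False
    schwartz_k_umol_cm: float = Field(default=36.5, gt=0.0)
    assumed_ecrcl: float = Field(default=120.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "ScoreConfig":
        for name, w in self.risk_weights.items():
            if name not in RISK_PREDICATES:
                raise ValueError(f"unknown risk condition {name!r}")
            if w <= 0:
                raise ValueError(f"risk weight for {name!r} must be positive")
        for tiers in (self.injury_dscr_tiers, self.injury_fo_tiers):
            lows = [t.lower for t in tiers]
            scores = [t.score for t in tiers]
            if sorted(lows) != lows or len(set(lows)) != len(lows):
                raise ValueError("tier lower bounds must be strictly increasing")
            if sorted(scores) != scores or len(set(scores)) != len(scores):
                raise ValueError("tier scores must be strictly increasing")
        return self


def rai_original() -> ScoreConfig:
    """The original renal angina index configuration (positive at >= 8)."""
    return ScoreConfig(risk_weights=dict(ORIGINAL_RISK_WEIGHTS))


def mrai_local() -> ScoreConfig:
    """Locally modified RAI: summed local risk weights × creatinine injury score."""
    return ScoreConfig(risk_weights=dict(MRAI_LOCAL_RISK_WEIGHTS), mrai_mode=True)


_PRESETS: dict[str, Callable[[], ScoreConfig]] = {
    "rai_original": rai_original,
    "mrai_local": mrai_local,
}


def load_score_config(source: str | Path) -> ScoreConfig:
    """Load a :class:`ScoreConfig` from a preset name or a YAML/JSON file."""
    name = str(source)
    if name in _PRESETS:
        return _PRESETS[name]()
    path = Path(source)
    if not path.exists():
        bundled = resources.files("renangia").joinpath(f"presets/{name}.yaml")
        if bundled.is_file():
            return ScoreConfig(**yaml.safe_load(bundled.read_text()))
        raise ConfigurationError(
            f"score config {source!r} is neither a preset ({sorted(_PRESETS)}) nor a file"
        )
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ScoreConfig(**data)


@dataclass(frozen=True)
class RAIResult:
    """Outcome of scoring one patient on day 0."""

    delta_scr: float
    percent_fo: Optional[float]
    fo_available: bool
    risk_score: int
    injury_score: int
    rai: int
    positive: bool
    imputed_baseline: bool
    baseline_scr_umol_l: float


def impute_baseline_scr(height_cm: float, config: ScoreConfig) -> float:
    """Baseline creatinine (µmol/L) from height, assuming a creatinine
    clearance of ``config.assumed_ecrcl`` mL/min/1.73 m².

    Inverts the height-based clearance estimate eCrCl = k·height/SCr.
    """
    if height_cm is None or height_cm <= 0:
        raise InvalidInputError(f"height_cm must be positive, got {height_cm!r}")
    return config.schwartz_k_umol_cm * height_cm / config.assumed_ecrcl


def delta_scr(enrollment_scr: float, baseline_scr: float) -> float:
    """ΔSCr: fold-change of the enrollment (day-0) creatinine over baseline."""
    if enrollment_scr is None or enrollment_scr <= 0:
        raise InvalidInputError(f"enrollment_scr must be positive, got {enrollment_scr!r}")
    if baseline_scr is None or baseline_scr <= 0:
        raise InvalidInputError(f"baseline_scr must be positive, got {baseline_scr!r}")
    return enrollment_scr / baseline_scr


def percent_fluid_overload(
    fluid_in_l: Optional[float], fluid_out_l: Optional[float], weight_kg: float
) -> Optional[float]:
    """%FO = (fluid in − fluid out) / admission weight × 100, fluids in litres.

    Returns ``None`` (not zero) when either fluid field is missing — an
    unavailable fluid balance must degrade the injury score, not bias it.
    May be negative under net diuresis.
    """
    if weight_kg is None or weight_kg <= 0:
        raise InvalidInputError(f"weight_kg must be positive, got {weight_kg!r}")
    if fluid_in_l is None or fluid_out_l is None:
        return None
    if fluid_in_l < 0 or fluid_out_l < 0:
        raise InvalidInputError("fluid volumes must be non-negative")
    return (fluid_in_l - fluid_out_l) / weight_kg * 100.0


def _applicable_factors(record: PatientRecord, config: ScoreConfig) -> list[str]:
    return [name for name in config.risk_weights if RISK_PREDICATES[name](record)]


def risk_score(record: PatientRecord, config: ScoreConfig) -> int:
    """Risk stratum score: highest applicable weight (original mode) or the
    sum of all applicable weights (mRAI mode)."""
    if not config.risk_weights:
        raise ConfigurationError("risk_weights is empty")
    applicable = _applicable_factors(record, config)
    if not applicable:
        # every cohort-eligible record is an ICU admission, so with the
        # bundled presets this cannot happen; lowest stratum for custom sets
        return 1
    weights = [config.risk_weights[name] for name in applicable]
    return sum(weights) if config.mrai_mode else max(weights)


def _tier_score(value: float, tiers: tuple[Tier, ...]) -> int:
    score = 1
    for tier in tiers:
        if value > tier.lower or (tier.inclusive and value == tier.lower):
            score = tier.score
    return score


def injury_score(
    delta: float, percent_fo: Optional[float], config: ScoreConfig
) -> int:
    """Injury score: max of the ΔSCr tier and the %FO tier.

    With %FO unavailable (``None``) the ΔSCr tier alone is used — a supported
    state, not an error, since fluid documentation is frequently missing.
    In mRAI mode the creatinine tier alone is used by definition.
    """
    if delta is None or delta <= 0:
        raise InvalidInputError(f"delta must be positive, got {delta!r}")
    dscr_tier = _tier_score(delta, config.injury_dscr_tiers)
    if config.mrai_mode or percent_fo is None:
        return dscr_tier
    return max(dscr_tier, _tier_score(percent_fo, config.injury_fo_tiers))


def _resolve_baseline(record: PatientRecord, config: ScoreConfig) -> tuple[float, bool]:
    if record.baseline_scr_umol_l is not None:
        return record.baseline_scr_umol_l, False
    if record.height_cm is None:
        raise InvalidInputError(
            "record has neither baseline_scr_umol_l nor height_cm; "
            "cannot establish a baseline creatinine"
        )
    return impute_baseline_scr(record.height_cm, config), True


def compute_rai(record: PatientRecord, config: ScoreConfig) -> RAIResult:
    """Score one patient: ΔSCr, %FO, risk and injury tiers, product, positivity."""
    if record.d0_scr_umol_l is None or record.d0_scr_umol_l <= 0:
        raise InvalidInputError("d0_scr_umol_l is required and must be positive")
    baseline, imputed = _resolve_baseline(record, config)
    delta = delta_scr(record.d0_scr_umol_l, baseline)
    fo = percent_fluid_overload(record.fluid_in_l_8h, record.fluid_out_l_8h, record.weight_kg)
    risk = risk_score(record, config)
    injury = injury_score(delta, fo, config)
    rai = risk * injury
    return RAIResult(
        delta_scr=delta,
        percent_fo=fo,
        fo_available=fo is not None,
        risk_score=risk,
        injury_score=injury,
        rai=rai,
        positive=rai >= config.positivity_cutoff,
        imputed_baseline=imputed,
        baseline_scr_umol_l=baseline,
    )


def compute_mrai(record: PatientRecord, config: ScoreConfig) -> RAIResult:
    """Modified RAI: sum of applicable local risk weights × creatinine injury score."""
    if not config.mrai_mode:
        raise ConfigurationError("compute_mrai requires a config with mrai_mode=True")
    return compute_rai(record, config)


def enumerate_achievable_scores(config: ScoreConfig) -> list[int]:
    """Every score the configured index can produce, by exhaustive enumeration
    over subsets of togglable risk factors × achievable injury tiers."""
    if not config.risk_weights:
        raise ConfigurationError("risk_weights is empty")
    togglable = [n for n in config.risk_weights if n not in ALWAYS_ON_FACTORS]
    base = [n for n in config.risk_weights if n in ALWAYS_ON_FACTORS]
    risk_values = set()
    for k in range(len(togglable) + 1):
        for subset in itertools.combinations(togglable, k):
            names = base + list(subset)
            weights = [config.risk_weights[n] for n in names] or [1]
            risk_values.add(sum(weights) if config.mrai_mode else max(weights))
    injuries = {1} | {t.score for t in config.injury_dscr_tiers}
    if not config.mrai_mode:
        injuries |= {t.score for t in config.injury_fo_tiers}
    return sorted({r * i for r in risk_values for i in injuries})
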