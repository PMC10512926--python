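"""Cohort pipeline: validate → score → adjudicate → evaluate → report.

Outputs are a pure function of (input CSV, configs, seed): the run summary
records a hash of the effective configuration so identical reruns can be
verified byte-for-byte.  Every number in the rendered tables is taken from
the diagnostics objects themselves — formatting happens once, at the edge.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import diagnostics
from .errors import InvalidInputError, ValidationFailure
from .kdigo import CohortAdjudication, adjudicate_cohort
from .records import PatientRecord, frame_to_records, records_to_frame
from .scoring import ScoreConfig, compute_rai, load_score_config

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "validate_cohort_csv",
    "run_pipeline",
]

logger = logging.getLogger("renangia")

ScoreName = Literal["rai", "mrai", "d0_gt_bscr", "delta_scr"]

_DEFAULT_CUTOFFS: dict[str, list[float]] = {
    "rai": [8, 10, 12],
    "mrai": [4, 6, 8, 10, 12, 14, 20, 28, 40],
    "delta_scr": [1.1, 1.25, 1.5, 2.0],
}

_OPTIONAL_COLUMNS = [
    "height_cm",
    "baseline_scr_umol_l",
    "d3_scr_umol_l",
    "fluid_in_l_8h",
    "fluid_out_l_8h",
    "d3_urine_output_ml_kg_h",
    "d3_urine_output_duration_h",
]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    cohort_csv: Path
    out_dir: Path
    rai_config: str = "rai_original"
    mrai_config: str = "mrai_local"
    scores: tuple[ScoreName, ...] = ("rai", "mrai", "d0_gt_bscr", "delta_scr")
    cutoffs: dict[str, list[float]] = Field(default_factory=dict)
    subgroup_age_max: Optional[float] = None
    seed: int = 0

    def cutoffs_for(self, score: str) -> list[float]:
        return self.cutoffs.get(score, _DEFAULT_CUTOFFS.get(score, [1]))


@dataclass
class ValidationReport:
    n_rows: int
    errors: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    missingness: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_cohort_csv(path: str | Path) -> ValidationReport:
    """Schema-validate a cohort CSV row by row.

    Violations of record invariants (negative creatinine, missing required
    fields) are errors with 1-based data row numbers; missing *optional*
    fields (fluids, urine output, day-3 creatinine) are reported as
    cohort-level missingness percentages and warnings only.
    """
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise InvalidInputError(f"cannot read cohort CSV {path}: {exc}") from exc

    report = ValidationReport(n_rows=len(frame))
    required = {
        name for name, f in PatientRecord.model_fields.items() if f.is_required()
    }
    missing_cols = required - set(frame.columns)
    for col in sorted(missing_cols):
        report.errors.append((0, f"required column {col!r} is absent"))
    if missing_cols:
        return report

    for idx, row in frame.iterrows():
        sub = frame.iloc[[idx]]
        try:
            frame_to_records(sub)
        except (ValidationError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                for err in exc.errors():
                    loc = ".".join(str(p) for p in err["loc"]) or "record"
                    report.errors.append((idx + 1, f"{loc}: {err['msg']}"))
            else:
                report.errors.append((idx + 1, str(exc)))

    for col in _OPTIONAL_COLUMNS:
        if col in frame.columns and len(frame):
            pct = float(frame[col].isna().mean() * 100.0)
            report.missingness[col] = pct
            if pct > 0:
                report.warnings.append(f"{col}: {pct:.1f}% missing")
    return report


def _score_table(records: list[PatientRecord], config: ScoreConfig, prefix: str) -> pd.DataFrame:
    rows = []
    for record in records:
        r = compute_rai(record, config)
        rows.append(
            {
                f"{prefix}delta_scr": r.delta_scr,
                f"{prefix}percent_fo": r.percent_fo,
                f"{prefix}risk": r.risk_score,
                f"{prefix}injury": r.injury_score,
                f"{prefix}rai": r.rai,
                f"{prefix}positive": r.positive,
                f"{prefix}imputed_baseline": r.imputed_baseline,
            }
        )
    return pd.DataFrame(rows)


def _metric_cell(m: Optional[diagnostics.MetricWithCI]) -> str:
    return str(m) if m is not None else "undefined"


def _render_cutoff_table(scan: diagnostics.CutoffScan, score_name: str) -> pd.DataFrame:
    rows = []
    for row in scan.rows:
        m = row.metrics
        rows.append(
            {
                "cutoff": row.cutoff,
                "sensitivity": _metric_cell(m.sensitivity),
                "specificity": _metric_cell(m.specificity),
                "ppv": _metric_cell(m.ppv),
                "npv": _metric_cell(m.npv),
                "youden": f"{row.youden_2dp:.2f}",
            }
        )
    table = pd.DataFrame(rows)
    table.insert(0, "score", score_name)
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns a summary dict (also written as ``run_summary.json``).  On
    failure, files written so far are removed so a partial bundle never
    masquerades as a complete one.
    """
    if not config.scores:
        raise InvalidInputError("at least one score must be selected")
    report = validate_cohort_csv(config.cohort_csv)
    if not report.ok:
        raise ValidationFailure(report)
    for warning in report.warnings:
        logger.warning("cohort: %s", warning)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False)
        written.append(path)
        logger.info("wrote %s", path)

    try:
        records = frame_to_records(pd.read_csv(config.cohort_csv))
        rai_cfg = load_score_config(config.rai_config)
        mrai_cfg = load_score_config(config.mrai_config)

        scored = records_to_frame(records)
        rai_table = _score_table(records, rai_cfg, "")
        mrai_table = _score_table(records, mrai_cfg, "mrai_")
        scored = pd.concat([scored, rai_table, mrai_table[["mrai_rai", "mrai_positive"]]], axis=1)
        scored = scored.rename(columns={"mrai_rai": "mrai"})
        _write_csv(scored, "scored.csv")

        if any(r.d3_scr_umol_l is None for r in records):
            raise InvalidInputError(
                "column d3_scr_umol_l has missing values; day-3 creatinine "
                "is required for adjudication"
            )
        adjudication: CohortAdjudication = adjudicate_cohort(records, rai_cfg)
        scored["kdigo_stage"] = [a.stage for a in adjudication.assessments]
        scored["saki"] = [a.severe for a in adjudication.assessments]
        _write_csv(scored, "adjudicated.csv")

        outcomes = scored["saki"].tolist()
        score_values: dict[str, list[float]] = {
            "rai": scored["rai"].tolist(),
            "mrai": scored["mrai"].tolist(),
            "d0_gt_bscr": (scored["delta_scr"] > 1.0).astype(float).tolist(),
            "delta_scr": scored["delta_scr"].tolist(),
        }

        tables, summary_metrics = [], {}
        for name in config.scores:
            cutoffs = [1] if name == "d0_gt_bscr" else config.cutoffs_for(name)
            scan = diagnostics.cutoff_scan(score_values[name], outcomes, cutoffs)
            tables.append(_render_cutoff_table(scan, name))
            roc = diagnostics.roc_auc(score_values[name], outcomes)
            summary_metrics[name] = {
                "auc": diagnostics.round_half_up(roc.auc, 2),
                "best_cutoff": scan.best_cutoff,
            }
        metric_table = pd.concat(tables, ignore_index=True)
        _write_csv(metric_table, "metric_tables.csv")

        roc_frames = []
        for name in config.scores:
            roc = diagnostics.roc_auc(score_values[name], outcomes)
            roc_frames.append(
                pd.DataFrame(
                    {
                        "score": name,
                        "threshold": roc.thresholds,
                        "sensitivity": roc.sensitivity,
                        "specificity": roc.specificity,
                    }
                )
            )
        _write_csv(pd.concat(roc_frames, ignore_index=True), "roc_points.csv")

        delong = None
        if "rai" in config.scores and "mrai" in config.scores:
            cmp = diagnostics.delong_compare(score_values["rai"], score_values["mrai"], outcomes)
            delong = {
                "auc_rai": cmp.auc_a,
                "auc_mrai": cmp.auc_b,
                "z": cmp.z,
                "p_two_sided": cmp.p_two_sided,
                "ci_diff": list(cmp.ci_diff),
            }

        subgroup = None
        if config.subgroup_age_max is not None:
            mask = scored["age_years"] <= config.subgroup_age_max
            sub_outcomes = scored.loc[mask, "saki"].tolist()
            cm = diagnostics.confusion_from_cohort(
                (scored.loc[mask, "rai"] >= rai_cfg.positivity_cutoff).tolist(), sub_outcomes
            )
            m = diagnostics.screening_metrics(cm)
            subgroup = {
                "age_max": config.subgroup_age_max,
                "n": int(mask.sum()),
                "rai_sensitivity": _metric_cell(m.sensitivity),
                "rai_specificity": _metric_cell(m.specificity),
                "rai_ppv": _metric_cell(m.ppv),
                "rai_npv": _metric_cell(m.npv),
            }

        # hash the analytic configuration only, so reruns into a different
        # directory still produce byte-identical summaries
        config_payload = config.model_dump(mode="json", exclude={"cohort_csv", "out_dir"})
        summary = {
            "n_patients": len(records),
            "n_saki": adjudication.n_severe,
            "saki_prevalence_pct": diagnostics.round_half_up(adjudication.prevalence * 100, 1),
            "aki_proportion_pct": diagnostics.round_half_up(adjudication.aki_proportion * 100, 1),
            "scores": summary_metrics,
            "delong_rai_vs_mrai": delong,
            "subgroup": subgroup,
            "missingness_pct": report.missingness,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config_payload, sort_keys=True).encode()
            ).hexdigest(),
        }
        path = out_dir / "run_summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(path)
        return summary
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
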