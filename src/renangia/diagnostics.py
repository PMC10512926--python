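"""Diagnostic-test evaluation of a score against the severe-AKI outcome.

Confusion metrics (sensitivity, specificity, PPV, NPV) carry untruncated
Wald 95% confidence intervals, p ± 1.96·√(p(1−p)/n): with small positive
counts the upper bound may legitimately exceed 100% and is reported as such
rather than clipped.  Wilson and Clopper–Pearson intervals are available via
``ci_method``.  Percentages are rounded half-up to 1 decimal place for
display; Youden's J (sensitivity + specificity − 1) to 2.

ROC curves are empirical over all distinct score values with "score ≥ cutoff"
meaning test-positive; the AUC is the Mann–Whitney statistic with ties
counted one half.  Paired AUCs are compared with DeLong's nonparametric
z-test from the placement values of each score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError
from .records import PatientRecord

__all__ = [
    "round_half_up",
    "wald_ci",
    "ConfusionMatrix",
    "MetricWithCI",
    "ScreeningMetrics",
    "confusion_from_cohort",
    "screening_metrics",
    "youden_j",
    "CutoffRow",
    "CutoffScan",
    "cutoff_scan",
    "ROCResult",
    "roc_auc",
    "PairedAUCComparison",
    "delong_compare",
    "subgroup_filter",
]

EN_DASH = "–"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of clinical tables),
    guarding against float artifacts like 0.48499999999999993."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(round(float(x), ndigits + 6))).quantize(q, rounding=ROUND_HALF_UP))


def wald_ci(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Untruncated normal-approximation CI on a proportion; bounds may fall
    outside [0, 1] by design."""
    if n <= 0:
        raise InvalidInputError(f"denominator must be positive, got {n}")
    half = z * np.sqrt(p * (1.0 - p) / n)
    return (p - half, p + half)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts of a binary test against the outcome (outcome=true = diseased)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion with its CI; stored raw, displayed as percent to 1 dp."""

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    n: int

    @property
    def pct(self) -> float:
        return round_half_up(self.estimate * 100.0, 1)

    @property
    def ci_pct(self) -> tuple[float, float]:
        return (round_half_up(self.ci_low * 100.0, 1), round_half_up(self.ci_high * 100.0, 1))

    def __str__(self) -> str:
        lo, hi = self.ci_pct
        return f"{self.pct}({lo}{EN_DASH}{hi})"


@dataclass(frozen=True)
class ScreeningMetrics:
    sensitivity: Optional[MetricWithCI]
    specificity: Optional[MetricWithCI]
    ppv: Optional[MetricWithCI]
    npv: Optional[MetricWithCI]


def confusion_from_cohort(
    scores: Sequence[bool], outcomes: Sequence[bool]
) -> ConfusionMatrix:
    """Cross-tabulate a binary test against the outcome."""
    if len(scores) != len(outcomes):
        raise InvalidInputError(
            f"scores ({len(scores)}) and outcomes ({len(outcomes)}) differ in length"
        )
    if len(scores) == 0:
        raise InvalidInputError("empty cohort")
    s = np.asarray(scores, dtype=bool)
    o = np.asarray(outcomes, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(s & o)),
        fp=int(np.sum(s & ~o)),
        fn=int(np.sum(~s & o)),
        tn=int(np.sum(~s & ~o)),
    )


def _metric(num: int, den: int, ci_method: str, z: float) -> Optional[MetricWithCI]:
    if den == 0:
        return None
    p = num / den
    if ci_method == "wald":
        lo, hi = wald_ci(p, den, z)
    elif ci_method in ("wilson", "beta"):
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(num, den, alpha=0.05, method=ci_method)
    else:
        raise InvalidInputError(f"unknown ci_method {ci_method!r}")
    return MetricWithCI(estimate=p, ci_low=float(lo), ci_high=float(hi), numerator=num, n=den)


def screening_metrics(
    cm: ConfusionMatrix, ci_method: str = "wald", z: float = 1.96
) -> ScreeningMetrics:
    """Sensitivity, specificity, PPV and NPV with CIs; a metric whose
    denominator is zero comes back as ``None``, the rest are still computed."""
    return ScreeningMetrics(
        sensitivity=_metric(cm.tp, cm.tp + cm.fn, ci_method, z),
        specificity=_metric(cm.tn, cm.fp + cm.tn, ci_method, z),
        ppv=_metric(cm.tp, cm.tp + cm.fp, ci_method, z),
        npv=_metric(cm.tn, cm.fn + cm.tn, ci_method, z),
    )


def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity − 1 (both as proportions)."""
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class CutoffRow:
    cutoff: float
    metrics: ScreeningMetrics
    youden: float

    @property
    def youden_2dp(self) -> float:
        return round_half_up(self.youden, 2)


@dataclass(frozen=True)
class CutoffScan:
    rows: list[CutoffRow]
    best_cutoff: float

    def __iter__(self):
        return iter(self.rows)


def cutoff_scan(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    cutoffs: Sequence[float],
    ci_method: str = "wald",
) -> CutoffScan:
    """Screening metrics and Youden's J at each cutoff ("score ≥ cutoff" is
    positive); the best cutoff maximises J, ties broken toward the smallest
    cutoff to favour sensitivity in a screening context."""
    if len(cutoffs) == 0:
        raise InvalidInputError("cutoffs is empty")
    s = np.asarray(scores, dtype=float)
    rows = []
    for cutoff in cutoffs:
        cm = confusion_from_cohort(s >= cutoff, outcomes)
        m = screening_metrics(cm, ci_method)
        if m.sensitivity is None or m.specificity is None:
            raise InvalidInputError(
                "cutoff scan needs at least one diseased and one healthy outcome"
            )
        rows.append(
            CutoffRow(
                cutoff=cutoff,
                metrics=m,
                youden=youden_j(m.sensitivity.estimate, m.specificity.estimate),
            )
        )
    best = min(rows, key=lambda r: (-r.youden, r.cutoff)).cutoff
    return CutoffScan(rows=rows, best_cutoff=best)


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _split_by_outcome(
    scores: Sequence[float], outcomes: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcomes, dtype=bool)
    if s.shape != o.shape:
        raise InvalidInputError("scores and outcomes differ in length")
    pos, neg = s[o], s[~o]
    if pos.size == 0:
        raise InvalidInputError("no diseased (outcome-positive) observations")
    if neg.size == 0:
        raise InvalidInputError("no healthy (outcome-negative) observations")
    return pos, neg


def roc_auc(scores: Sequence[float], outcomes: Sequence[bool]) -> ROCResult:
    """Empirical ROC (higher score = more diseased) and Mann–Whitney AUC
    with ties counted 0.5."""
    pos, neg = _split_by_outcome(scores, outcomes)
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)
    thresholds = np.unique(combined)[::-1]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


@dataclass(frozen=True)
class PairedAUCComparison:
    auc_a: float
    auc_b: float
    z: float
    p_two_sided: float
    ci_diff: tuple[float, float]
    se_diff: float

    @property
    def diff(self) -> float:
        return self.auc_a - self.auc_b


def _placements(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Heaviside placement values: for each diseased score its mean win-rate
    over the healthy scores (V10), and vice versa (V01)."""
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[bool],
) -> PairedAUCComparison:
    """DeLong z-test for the difference of two correlated (same-patient) AUCs.

    When the two scores are identical the difference and its variance are both
    exactly zero; the comparison reports z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("scores_a and scores_b differ in length")
    pos_a, neg_a = _split_by_outcome(a, outcomes)
    pos_b, neg_b = _split_by_outcome(b, outcomes)

    v10_a, v01_a, auc_a = _placements(pos_a, neg_a)
    v10_b, v01_b, auc_b = _placements(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size

    if m < 2 or n < 2:
        raise InvalidInputError("DeLong comparison needs >=2 diseased and >=2 healthy")
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var_diff <= 0:
        se = 0.0
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        se = float(np.sqrt(var_diff))
        z = diff / se
    p = 1.0 if se == 0.0 and diff == 0 else float(2.0 * stats.norm.sf(abs(z)))
    ci = (diff - 1.96 * se, diff + 1.96 * se)
    return PairedAUCComparison(
        auc_a=float(auc_a), auc_b=float(auc_b), z=float(z), p_two_sided=p,
        ci_diff=ci, se_diff=se,
    )


def subgroup_filter(
    records: Sequence[PatientRecord], predicate: Callable[[PatientRecord], bool]
) -> list[PatientRecord]:
    """Records satisfying ``predicate``, order preserved; warns when empty."""
    kept = [r for r in records if predicate(r)]
    if not kept:
        warnings.warn("subgroup_filter selected no records", stacklevel=2)
    return kept
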