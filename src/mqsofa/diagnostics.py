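"""Dichotomized-classifier evaluation at the score cutoff of 2.

Covers the 2x2 confusion machinery (including reconstruction of a 2x2 table
from printed sensitivity/specificity and outcome margins), sensitivity /
specificity / PPV / NPV / accuracy, cross-product odds ratios with Wald
intervals, the three-group reclassification summary, and the Pearson
chi-square for 2x2 contingency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .cohort_io import JointScoreTable, PatientRecord
from .scores import RiskGroup, SFBandDialect, ValidationError

__all__ = [
    "ConfusionTable",
    "DiagnosticMetrics",
    "OddsRatioResult",
    "ReclassificationSummary",
    "confusion_from_cohort",
    "reconstruct_confusion",
    "metrics",
    "dichotomized_or",
    "reclassification_summary",
    "chi_square_2x2",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 outcome-by-classifier counts; positives are deaths, positivity is score >= cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError(f"confusion cells must be non-negative: {self}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        """Number of deaths."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        """Number of survivors."""
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Proportions in [0,1]; ``report_percent`` gives the 1-decimal percent forms.

    A metric whose margin is empty is ``None`` (explicitly undefined, never a
    silent zero).
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    @property
    def report_percent(self) -> Mapping[str, float | None]:
        return {
            name: None if v is None else round_half_away(100.0 * v, 1)
            for name, v in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
                ("accuracy", self.accuracy),
            )
        }


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci95: tuple[float, float]
    p: float
    continuity_corrected: bool = False


@dataclass(frozen=True)
class ReclassificationSummary:
    n_low: int
    n_reclassified: int
    n_high: int
    fraction_reclassified: float
    deaths_by_group: Mapping[str, int] | None = None
    death_rate_by_group: Mapping[str, float] | None = None

    @property
    def total(self) -> int:
        return self.n_low + self.n_reclassified + self.n_high

    @property
    def percent_reclassified(self) -> float:
        return round_half_away(100.0 * self.fraction_reclassified, 1)


def confusion_from_cohort(
    records: Sequence[PatientRecord],
    score_field: str = "mqsofa",
    cutoff: int = 2,
    dialect: SFBandDialect | str = SFBandDialect.TABLE,
) -> ConfusionTable:
    """Count the 2x2 table for one score dichotomized at ``cutoff`` against death."""
    if len(records) == 0:
        raise ValidationError("cannot build a confusion table from an empty cohort")
    if score_field not in ("qsofa", "mqsofa"):
        raise ValueError(f"score_field must be qsofa or mqsofa, got {score_field!r}")
    tp = fp = fn = tn = 0
    for r in records:
        s = getattr(r.score(dialect), score_field)
        positive = s >= cutoff
        if r.died:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def reconstruct_confusion(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> ConfusionTable:
    """Rebuild integer 2x2 cells from printed sensitivity/specificity and margins.

    tp = round(sens * n_pos) and tn = round(spec * n_neg) with half rounded up;
    the remaining cells follow from the margins.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValidationError("sensitivity and specificity must be proportions in [0,1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValidationError("margins must be positive")
    tp = math.floor(sens * n_pos + 0.5)
    tn = math.floor(spec * n_neg + 0.5)
    return ConfusionTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(ct: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from a 2x2 table."""
    return DiagnosticMetrics(
        sensitivity=_ratio(ct.tp, ct.tp + ct.fn),
        specificity=_ratio(ct.tn, ct.tn + ct.fp),
        ppv=_ratio(ct.tp, ct.tp + ct.fp),
        npv=_ratio(ct.tn, ct.tn + ct.fn),
        accuracy=_ratio(ct.tp + ct.tn, ct.n) if ct.n else None,
    )


def dichotomized_or(ct: ConfusionTable, continuity: bool = True) -> OddsRatioResult:
    """Cross-product odds ratio with a 95% Wald interval and two-sided p.

    Zero cells receive the 0.5 continuity correction (flagged in the result)
    when ``continuity`` is true; otherwise they raise.
    """
    cells = [ct.tp, ct.fp, ct.fn, ct.tn]
    corrected = False
    if min(cells) == 0:
        if not continuity:
            raise ValidationError("zero cell in 2x2 table; enable the continuity correction")
        cells = [c + 0.5 for c in cells]
        corrected = True
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se if se > 0 else 0.0
    return OddsRatioResult(
        oddsratio=math.exp(log_or),
        ci95=(math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se)),
        p=2 * norm.sf(abs(z)),
        continuity_corrected=corrected,
    )


def reclassification_summary(
    table: JointScoreTable,
    records: Sequence[PatientRecord] | None = None,
    dialect: SFBandDialect | str = SFBandDialect.TABLE,
) -> ReclassificationSummary:
    """Three-group stratification of a joint score table.

    low: qSOFA < 2 and MqSOFA < 2; reclassified high: qSOFA < 2 and
    MqSOFA >= 2 (flagged only by the modified score); high: both >= 2.
    With patient records supplied, per-group death counts and rates are added.
    """
    c = table.counts
    n_low = int(c[:2, :2].sum())
    n_reclassified = int(c[2:, :2].sum())
    n_high = int(c[2:, 2:].sum())
    total = n_low + n_reclassified + n_high
    deaths = rates = None
    if records is not None:
        counts = {g.value: 0 for g in RiskGroup}
        sizes = {g.value: 0 for g in RiskGroup}
        for r in records:
            g = r.risk_group(dialect).value
            sizes[g] += 1
            counts[g] += r.died
        deaths = counts
        rates = {g: (counts[g] / sizes[g] if sizes[g] else float("nan")) for g in counts}
    return ReclassificationSummary(
        n_low=n_low,
        n_reclassified=n_reclassified,
        n_high=n_high,
        fraction_reclassified=n_reclassified / total,
        deaths_by_group=deaths,
        death_rate_by_group=rates,
    )


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined on a table with a zero margin")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, float(chi2_dist.sf(stat, df=1))
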