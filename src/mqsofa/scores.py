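"""Patient-level qSOFA and MqSOFA scoring.

qSOFA (quick Sequential Organ Failure Assessment) awards one point each for
systolic blood pressure <= 100 mmHg, respiratory rate >= 22/min and altered
mentation.  MqSOFA extends it with a 0/1/2-point band on the SpO2/FiO2 (S/F)
ratio, a non-invasive surrogate for the PaO2/FiO2 oxygenation index: the S/F
cutoffs 235 and 315 correspond to P/F 200 and 300 in lung-injury cohorts.

Two dialects exist for the score at exactly S/F = 315 because the published
point table ("0 points for >= 316") and the accompanying prose ("0 points for
>= 315") disagree.  The default ``table`` dialect scores 315 as 1 point,
matching the convention in which S/F = 315 maps onto the abnormal P/F = 300
boundary; the ``text`` dialect scores it 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "ValidationError",
    "VitalSigns",
    "ScorePair",
    "RiskGroup",
    "SFBandDialect",
    "compute_qsofa",
    "compute_sf_ratio",
    "sf_points",
    "compute_mqsofa",
    "assign_risk_group",
    "sf_to_pf",
]

#: Lower S/F band edge: <= 235 scores 2 points (corresponds to P/F 200).
SF_CUT_LOW = 235.0
#: Upper S/F band edge: the 1-point band ends at 315 (corresponds to P/F 300).
SF_CUT_HIGH = 315.0


class ValidationError(ValueError):
    """Raised when a vital sign or score is outside its physiologic domain."""


class SFBandDialect(str, enum.Enum):
    """Which side of the 235/315 band edges scores which way at S/F = 315."""

    TABLE = "table"  # 315 -> 1 point (band (235, 315] -> 1)
    TEXT = "text"  # 315 -> 0 points (band (235, 315) -> 1)


@dataclass(frozen=True)
class VitalSigns:
    """One admission's triage vitals.

    Parameters
    ----------
    sbp : float
        Systolic blood pressure, mmHg (> 0).
    rr : float
        Respiratory rate, breaths/min (> 0).
    altered_mentation : bool
        Any acute change in mental status.
    spo2 : float
        Peripheral oxygen saturation, percent, in (0, 100].
    fio2 : float
        Inspired oxygen fraction, in [0.21, 1.0]; room air is 0.21.
    """

    sbp: float
    rr: float
    altered_mentation: bool
    spo2: float
    fio2: float

    def __post_init__(self) -> None:
        if not self.sbp > 0:
            raise ValidationError(f"sbp must be positive, got {self.sbp}")
        if not self.rr > 0:
            raise ValidationError(f"rr must be positive, got {self.rr}")
        if not 0 < self.spo2 <= 100:
            raise ValidationError(f"spo2 must be in (0, 100], got {self.spo2}")
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValidationError(f"fio2 must be in [0.21, 1.0], got {self.fio2}")


@dataclass(frozen=True)
class ScorePair:
    """qSOFA and MqSOFA computed for one patient."""

    qsofa: int
    sf_points: int
    mqsofa: int
    sf_ratio: float

    def __post_init__(self) -> None:
        if not 0 <= self.qsofa <= 3:
            raise ValidationError(f"qsofa out of range: {self.qsofa}")
        if not 0 <= self.sf_points <= 2:
            raise ValidationError(f"sf_points out of range: {self.sf_points}")
        if self.mqsofa != self.qsofa + self.sf_points:
            raise ValidationError(
                f"mqsofa {self.mqsofa} != qsofa {self.qsofa} + sf_points {self.sf_points}"
            )


class RiskGroup(str, enum.Enum):
    """Three-level stratification by the two scores at cutoff 2.

    ``reclassified_high`` holds the patients flagged only by MqSOFA
    (qSOFA < 2 but MqSOFA >= 2); qSOFA >= 2 with MqSOFA < 2 is impossible
    because MqSOFA >= qSOFA by construction.
    """

    LOW = "low"
    RECLASSIFIED_HIGH = "reclassified_high"
    HIGH = "high"


def compute_qsofa(v: VitalSigns) -> int:
    """Sum of the three qSOFA indicator points; both thresholds are inclusive."""
    return int(v.sbp <= 100) + int(v.rr >= 22) + int(v.altered_mentation)


def compute_sf_ratio(spo2: float, fio2: float) -> float:
    """SpO2/FiO2 with SpO2 on the percent scale (healthy room air ~ 98/0.21 ~ 467)."""
    if not 0 < spo2 <= 100:
        raise ValidationError(f"spo2 must be in (0, 100], got {spo2}")
    if not 0.21 <= fio2 <= 1.0:
        raise ValidationError(f"fio2 must be in [0.21, 1.0], got {fio2}")
    return spo2 / fio2


def sf_points(sf_ratio: float, dialect: SFBandDialect | str = SFBandDialect.TABLE) -> int:
    """Points added to qSOFA for the S/F band.

    Bands on the real line (``table`` dialect, the default):
    ratio <= 235 -> 2; 235 < ratio <= 315 -> 1; ratio > 315 -> 0.
    The ``text`` dialect moves only the value 315 itself into the 0-point band.
    """
    if not sf_ratio > 0:
        raise ValidationError(f"sf_ratio must be positive, got {sf_ratio}")
    dialect = SFBandDialect(dialect)
    if sf_ratio <= SF_CUT_LOW:
        return 2
    if dialect is SFBandDialect.TABLE:
        return 1 if sf_ratio <= SF_CUT_HIGH else 0
    return 1 if sf_ratio < SF_CUT_HIGH else 0


def compute_mqsofa(v: VitalSigns, dialect: SFBandDialect | str = SFBandDialect.TABLE) -> ScorePair:
    """Score one patient: qSOFA, the S/F band points and their sum (MqSOFA 0-5)."""
    q = compute_qsofa(v)
    ratio = compute_sf_ratio(v.spo2, v.fio2)
    sf = sf_points(ratio, dialect)
    return ScorePair(qsofa=q, sf_points=sf, mqsofa=q + sf, sf_ratio=ratio)


def assign_risk_group(s: ScorePair) -> RiskGroup:
    """Map a score pair to low / reclassified-high / high risk at cutoff 2."""
    if s.qsofa >= 2 and s.mqsofa < 2:
        raise ValidationError(
            f"impossible score pair (qsofa={s.qsofa}, mqsofa={s.mqsofa}): MqSOFA >= qSOFA"
        )
    if s.mqsofa < 2:
        return RiskGroup.LOW
    if s.qsofa < 2:
        return RiskGroup.RECLASSIFIED_HIGH
    return RiskGroup.HIGH


def sf_to_pf(sf_ratio: float) -> float:
    """Convert S/F to an estimated P/F via log10(P/F) = 0.48 + 0.78 * log10(S/F)."""
    if not sf_ratio > 0:
        raise ValidationError(f"sf_ratio must be positive, got {sf_ratio}")
    return 10.0 ** (0.48 + 0.78 * math.log10(sf_ratio))
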