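"""Cohort CSV input/output, record validation and the published joint score table.

Cohorts are plain CSV, one row per admission, with columns
``id, age, sex, sbp, rr, altered_mentation, spo2, fio2, outcome, los_days``
and an optional ``intubated`` column.  Records with missing or invalid fields
are excluded listwise (never imputed) and tallied by reason, mirroring the
source study's retention of 1001 of 1137 retrieved records.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scores import (
    RiskGroup,
    ScorePair,
    SFBandDialect,
    ValidationError,
    VitalSigns,
    assign_risk_group,
    compute_mqsofa,
)

__all__ = [
    "PatientRecord",
    "JointScoreTable",
    "ExclusionReport",
    "read_cohort",
    "write_cohort",
    "tabulate_joint",
    "table2_fixture",
    "filter_age_subgroup",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = (
    "id",
    "age",
    "sex",
    "sbp",
    "rr",
    "altered_mentation",
    "spo2",
    "fio2",
    "outcome",
    "los_days",
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


@dataclass(frozen=True)
class PatientRecord:
    """One admission: demographics, triage vitals, outcome and stay length."""

    id: str
    age: int
    sex: str  # "M" or "F"
    vitals: VitalSigns
    outcome: str  # "died" or "discharged"
    los_days: float
    intubated: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if self.outcome not in ("died", "discharged"):
            raise ValidationError(f"outcome must be died or discharged, got {self.outcome!r}")
        if not self.los_days > 0:
            raise ValidationError(f"los_days must be positive, got {self.los_days}")
        if not 18 <= self.age <= 120:
            raise ValidationError(f"age must be in [18, 120], got {self.age}")

    @property
    def died(self) -> bool:
        return self.outcome == "died"

    def score(self, dialect: SFBandDialect | str = SFBandDialect.TABLE) -> ScorePair:
        return compute_mqsofa(self.vitals, dialect)

    def risk_group(self, dialect: SFBandDialect | str = SFBandDialect.TABLE) -> RiskGroup:
        return assign_risk_group(self.score(dialect))


@dataclass(frozen=True)
class JointScoreTable:
    """6x4 counts of MqSOFA (rows 0-5) by qSOFA (columns 0-3).

    Cells with qSOFA > MqSOFA are structurally empty because MqSOFA adds
    non-negative S/F points to qSOFA.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (6, 4):
            raise ValidationError(f"joint table must be 6x4, got {c.shape}")
        if (c < 0).any():
            raise ValidationError("joint table counts must be non-negative")
        for m in range(6):
            for q in range(4):
                if q > m and c[m, q] != 0:
                    raise ValidationError(
                        f"cell (mqsofa={m}, qsofa={q}) must be empty: MqSOFA >= qSOFA"
                    )
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        """Counts per MqSOFA value 0-5."""
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        """Counts per qSOFA value 0-3."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(range(6), name="mqsofa"),
            columns=[f"qsofa_{q}" for q in range(4)],
        )

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "JointScoreTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=int))


@dataclass
class ExclusionReport:
    """Accounting of records dropped while reading a cohort."""

    n_input: int
    n_retained: int
    reasons: Counter = field(default_factory=Counter)

    def check(self) -> None:
        if self.n_input != self.n_retained + sum(self.reasons.values()):
            raise AssertionError(
                f"exclusion accounting broken: {self.n_input} != "
                f"{self.n_retained} + {sum(self.reasons.values())}"
            )


def _parse_bool(value: object, field_name: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"{field_name} must be boolean-like, got {value!r}")


def _record_from_row(row: pd.Series) -> PatientRecord:
    required = [c for c in REQUIRED_COLUMNS]
    for col in required:
        val = row.get(col)
        if val is None or (isinstance(val, float) and np.isnan(val)) or str(val).strip() == "":
            raise KeyError(col)
    vitals = VitalSigns(
        sbp=float(row["sbp"]),
        rr=float(row["rr"]),
        altered_mentation=_parse_bool(row["altered_mentation"], "altered_mentation"),
        spo2=float(row["spo2"]),
        fio2=float(row["fio2"]),
    )
    intubated = False
    if "intubated" in row.index and not pd.isna(row["intubated"]) and str(row["intubated"]).strip():
        intubated = _parse_bool(row["intubated"], "intubated")
    return PatientRecord(
        id=str(row["id"]),
        age=int(row["age"]),
        sex=str(row["sex"]).strip(),
        vitals=vitals,
        outcome=str(row["outcome"]).strip().lower(),
        los_days=float(row["los_days"]),
        intubated=intubated,
    )


def read_cohort(path: str | Path | io.TextIOBase) -> tuple[list[PatientRecord], ExclusionReport]:
    """Read a cohort CSV, excluding invalid rows with per-reason tallies.

    Exclusion reasons: ``missing_field`` (a required cell is empty),
    ``invalid_value`` (a cell fails domain validation) and ``intubated``
    (the study excluded intubated patients).
    """
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise IOError(f"cohort file missing required columns: {missing_cols}")
    records: list[PatientRecord] = []
    reasons: Counter = Counter()
    for _, row in df.iterrows():
        try:
            rec = _record_from_row(row)
        except KeyError:
            reasons["missing_field"] += 1
            continue
        except (ValidationError, ValueError):
            reasons["invalid_value"] += 1
            continue
        if rec.intubated:
            reasons["intubated"] += 1
            continue
        records.append(rec)
    report = ExclusionReport(n_input=len(df), n_retained=len(records), reasons=reasons)
    report.check()
    return records, report


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "sbp": r.vitals.sbp,
            "rr": r.vitals.rr,
            "altered_mentation": str(r.vitals.altered_mentation).lower(),
            "spo2": r.vitals.spo2,
            "fio2": r.vitals.fio2,
            "outcome": r.outcome,
            "los_days": r.los_days,
            "intubated": str(r.intubated).lower(),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["intubated"])


def write_cohort(records: Sequence[PatientRecord], path: str | Path | io.TextIOBase) -> None:
    """Write records as the canonical cohort CSV (lossless round-trip)."""
    cohort_to_frame(records).to_csv(path, index=False)


def tabulate_joint(
    records: Sequence[PatientRecord], dialect: SFBandDialect | str = SFBandDialect.TABLE
) -> JointScoreTable:
    """Cross-tabulate scored records into the 6x4 MqSOFA-by-qSOFA table."""
    if len(records) == 0:
        raise ValidationError("cannot tabulate an empty cohort")
    counts = np.zeros((6, 4), dtype=int)
    for r in records:
        s = r.score(dialect)
        counts[s.mqsofa, s.qsofa] += 1
    return JointScoreTable(counts)


# Published joint distribution of the 1001-patient validation cohort:
# rows MqSOFA 0-5, columns qSOFA 0-3; column totals 278/334/254/135.
_TABLE2 = np.array(
    [
        [252, 0, 0, 0],
        [11, 264, 0, 0],
        [15, 43, 136, 0],
        [0, 27, 50, 31],
        [0, 0, 68, 37],
        [0, 0, 0, 67],
    ],
    dtype=int,
)


def table2_fixture() -> JointScoreTable:
    """The packaged 1001-patient MqSOFA-by-qSOFA count table."""
    return JointScoreTable(_TABLE2.copy())


def filter_age_subgroup(
    records: Sequence[PatientRecord], mode: str = "all"
) -> list[PatientRecord]:
    """Age sensitivity subgroups: under70 (age < 70), over90 (age >= 90), all."""
    if mode == "all":
        return list(records)
    if mode == "under70":
        return [r for r in records if r.age < 70]
    if mode == "over90":
        return [r for r in records if r.age >= 90]
    raise ValueError(f"unknown subgroup mode {mode!r}; use all, under70 or over90")
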