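"""Kaplan-Meier estimation, k-group log-rank tests and rank-based LOS tests.

Time is measured in hospital days: death in hospital is the event and
discharge alive censors the stay.  Deaths are processed before censorings at
tied times (the standard product-limit convention).  Length-of-stay
comparisons are restricted to survivors and use midrank statistics with tie
corrections: Wilcoxon-Mann-Whitney for two groups, Kruskal-Wallis for more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

from .cohort_io import PatientRecord
from .scores import RiskGroup, SFBandDialect, ValidationError

__all__ = [
    "SurvivalInput",
    "KMCurve",
    "LogRankResult",
    "LosSummary",
    "km_estimate",
    "logrank_test",
    "mann_whitney",
    "kruskal_wallis",
    "los_by_group",
    "survival_inputs",
]


@dataclass(frozen=True)
class SurvivalInput:
    time: float
    event: bool  # True = died in hospital; False = discharged (censored)
    group: RiskGroup

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(f"survival time must be positive, got {self.time}")


@dataclass(frozen=True)
class KMCurve:
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    groups: tuple


@dataclass(frozen=True)
class LosSummary:
    medians: Mapping[str, float]
    iqrs: Mapping[str, tuple[float, float]]
    n_per_group: Mapping[str, int]
    statistic: float
    p: float
    test: str  # "mann_whitney" or "kruskal_wallis"


def survival_inputs(
    records: Sequence[PatientRecord], dialect: SFBandDialect | str = SFBandDialect.TABLE
) -> list[SurvivalInput]:
    """Build survival rows from a cohort: LOS as time, death as the event."""
    return [
        SurvivalInput(time=r.los_days, event=r.died, group=r.risk_group(dialect))
        for r in records
    ]


def km_estimate(
    data: Sequence[SurvivalInput], group: RiskGroup | None = None
) -> KMCurve:
    """Product-limit estimator S(t) = prod over event times <= t of (1 - d/n)."""
    rows = [d for d in data if group is None or d.group == group]
    if not rows:
        raise ValidationError("no subjects in the requested group")
    times = np.array([d.time for d in rows])
    events = np.array([d.event for d in rows])
    order = np.lexsort((~events, times))  # deaths first at tied times
    times, events = times[order], events[order]
    n = times.size
    uniq = np.unique(times[events])
    ev_counts, risk_counts, surv = [], [], []
    s = 1.0
    for t in uniq:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / at_risk
        ev_counts.append(d)
        risk_counts.append(at_risk)
        surv.append(s)
    return KMCurve(
        event_times=uniq,
        survival=np.array(surv),
        at_risk=np.array(risk_counts, dtype=int),
        events=np.array(ev_counts, dtype=int),
    )


def logrank_test(
    data: Sequence[SurvivalInput], groups: Sequence[RiskGroup] | None = None
) -> LogRankResult:
    """k-group log-rank test under the hypergeometric model at each event time.

    The chi-square uses the first k-1 components of the observed-minus-
    expected score vector with the corresponding variance block (a
    generalized inverse guards rank deficiency for k > 2); df = k - 1.
    """
    if groups is None:
        groups = tuple(sorted({d.group for d in data}, key=lambda g: g.value))
    else:
        groups = tuple(groups)
        data = [d for d in data if d.group in groups]
    k = len(groups)
    if k < 2:
        raise ValidationError("log-rank test needs at least 2 groups")
    sizes = {g: sum(1 for d in data if d.group == g) for g in groups}
    if any(s == 0 for s in sizes.values()):
        raise ValidationError(f"empty group in log-rank input: {sizes}")
    gi = {g: i for i, g in enumerate(groups)}
    times = np.array([d.time for d in data])
    events = np.array([d.event for d in data])
    labels = np.array([gi[d.group] for d in data])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for t in np.unique(times[events]):
        at_risk_mask = times >= t
        n_t = int(at_risk_mask.sum())
        d_t = int((events & (times == t)).sum())
        n_g = np.array([(at_risk_mask & (labels == i)).sum() for i in range(k)], dtype=float)
        o_g = np.array(
            [(events & (times == t) & (labels == i)).sum() for i in range(k)], dtype=float
        )
        observed += o_g
        expected += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            var += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[: k - 1]
    vsub = var[: k - 1, : k - 1]
    chi2 = float(diff @ np.linalg.pinv(vsub) @ diff)
    df = k - 1
    return LogRankResult(
        chi2=chi2,
        df=df,
        p=float(chi2_dist.sf(chi2, df=df)),
        observed=observed,
        expected=expected,
        groups=groups,
    )


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Wilcoxon-Mann-Whitney via midranks with tie-corrected normal p.

    Returns (U, z, two-sided p).  U counts the pairs in which the second
    group exceeds the first (plus half the ties), so U / (nA * nB) is the
    probability-of-superiority of B over A — the same quantity the ROC AUC
    measures with B as the positive group.  No continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney needs both groups nonempty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)  # midranks
    r_b = ranks[n_a:].sum()
    u = r_b - n_b * (n_b + 1) / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return float(u), 0.0, 1.0
    z = (u - n_a * n_b / 2.0) / math.sqrt(var_u)
    return float(u), float(z), float(2 * norm.sf(abs(z)))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with the tie-correction divisor 1 - sum(t^3 - t)/(N^3 - N).

    Two groups delegate to :func:`mann_whitney` (reporting its chi-square
    equivalent z^2 with 1 df).
    """
    if any(len(g) == 0 for g in groups):
        raise ValidationError("Kruskal-Wallis needs every group nonempty")
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if len(groups) == 2:
        _, z, p = mann_whitney(groups[0], groups[1])
        return float(z**2), 1, p
    sizes = [len(g) for g in groups]
    combined = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = combined.size
    ranks = rankdata(combined)
    h = 0.0
    start = 0
    for sz in sizes:
        r = ranks[start : start + sz].sum()
        h += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(combined, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    if correction <= 0:
        return 0.0, len(groups) - 1, 1.0
    h /= correction
    df = len(groups) - 1
    return float(h), df, float(chi2_dist.sf(h, df=df))


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    """(q1, median, q3) with linear interpolation between order statistics."""
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def los_by_group(
    records: Sequence[PatientRecord],
    dialect: SFBandDialect | str = SFBandDialect.TABLE,
) -> LosSummary:
    """Survivor length-of-stay medians/IQRs per risk group with the omnibus test.

    Restricted to discharged patients; Kruskal-Wallis across three groups,
    Mann-Whitney when only two are populated.  A populated single-member
    group still reports its median, but the test needs every group with at
    least 2 subjects.
    """
    survivors = [r for r in records if not r.died]
    by_group: dict[str, list[float]] = {}
    for r in survivors:
        by_group.setdefault(r.risk_group(dialect).value, []).append(r.los_days)
    if not by_group:
        raise ValidationError("no survivors to analyse")
    medians, iqrs, sizes = {}, {}, {}
    for g, vals in by_group.items():
        arr = np.asarray(vals)
        q1, med, q3 = _quartiles(arr)
        medians[g] = med
        iqrs[g] = (q1, q3)
        sizes[g] = arr.size
    ordered = [by_group[g.value] for g in RiskGroup if g.value in by_group]
    if len(ordered) < 2:
        raise ValidationError("LOS comparison needs at least 2 populated risk groups")
    if any(len(g) < 2 for g in ordered):
        raise ValidationError("every risk group needs at least 2 survivors for the rank test")
    if len(ordered) == 2:
        _, z, p = mann_whitney(ordered[0], ordered[1])
        stat, test = float(z), "mann_whitney"
    else:
        stat, _, p = kruskal_wallis(ordered)
        test = "kruskal_wallis"
    return LosSummary(
        medians=medians, iqrs=iqrs, n_per_group=sizes, statistic=stat, p=p, test=test
    )
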