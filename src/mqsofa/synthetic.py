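"""Synthetic sepsis-cohort generator calibrated to the published summaries.

The generator reproduces the validation study's printed structure so every
downstream stage (diagnostics, regression, ROC, survival, LOS) can run with
no access to the original patient data:

* the 6x4 MqSOFA-by-qSOFA joint score distribution (n = 1001), exactly in
  ``exact`` mode or as one multinomial draw in ``sampled`` mode;
* a logistic mortality surface in MqSOFA with per-unit odds ratio 2.38 whose
  intercept is calibrated so the table-weighted mortality equals 333/1001;
* outcome-conditional ages (died 82.4 +/- 10.7 vs discharged 77.9 +/- 13.6,
  truncated to [18, 110]) and a 462/1001 male fraction;
* survivor length of stay, log-normal per risk group with medians/IQRs
  8.5 [6-13], 10 [6-13] and 10 [7-14] days.

The cell-level mortality surface is unpublished; logistic-in-MqSOFA is the
simplest surface consistent with the printed slope and marginal rate.  The
non-survivor stay distribution is likewise unpublished and is taken as
exponential with mean 7 days truncated to [1, 60].

All draws come from one seeded ``numpy.random.Generator`` in a fixed
per-patient order (qSOFA item assignment, SBP, RR, S/F ratio, FiO2, death,
age, sex, LOS), so a seed fully determines the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .cohort_io import JointScoreTable, PatientRecord, table2_fixture
from .scores import RiskGroup, ScorePair, ValidationError, VitalSigns, assign_risk_group

__all__ = [
    "GeneratorParams",
    "CalibratedModel",
    "calibrate_intercept",
    "generate_cohort",
    "los_lognormal_params",
]

# Upper-quartile deviate of the standard normal; maps an IQR on the log scale
# to a log-normal sigma.
_Z75 = 0.67449

# Interior margin kept between a sampled S/F ratio and the 235/315 band edges
# so the spo2 = ratio * fio2 -> spo2 / fio2 float round-trip cannot change the
# band.
_BAND_EPS = 1e-3

#: S/F sampling windows per S/F point value (2, 1, 0).
_SF_WINDOWS = {
    2: (100.0, 235.0 - _BAND_EPS),
    1: (235.0 + _BAND_EPS, 315.0 - _BAND_EPS),
    0: (315.0 + _BAND_EPS, 470.0),
}


@dataclass(frozen=True)
class LosQuartiles:
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not 0 < self.q1 <= self.median <= self.q3:
            raise ValidationError(
                f"LOS quartiles must satisfy 0 < q1 <= median <= q3, got {self}"
            )


@dataclass(frozen=True)
class GeneratorParams:
    """Everything the cohort generator needs; defaults are the study conditions."""

    joint_table: JointScoreTable = field(default_factory=table2_fixture)
    mode: str = "exact"  # "exact" or "sampled"
    n: int | None = None  # sampled-mode cohort size (defaults to table total)
    scale: int = 1  # exact-mode multiplier on every cell count
    beta1: float = math.log(2.38)  # per-unit log-odds of death on MqSOFA
    target_mortality: float = 333 / 1001
    age_beta: float = 0.0  # optional per-year log-odds (~ln 1.03 when enabled)
    age_died: tuple[float, float] = (82.4, 10.7)
    age_discharged: tuple[float, float] = (77.9, 13.6)
    age_marginal: tuple[float, float] = (79.4, 12.9)  # used only with age_beta != 0
    age_bounds: tuple[float, float] = (18.0, 110.0)
    male_prob: float = 462 / 1001
    los_quartiles: Mapping[RiskGroup, LosQuartiles] = field(
        default_factory=lambda: {
            RiskGroup.LOW: LosQuartiles(8.5, 6.0, 13.0),
            RiskGroup.RECLASSIFIED_HIGH: LosQuartiles(10.0, 6.0, 13.0),
            RiskGroup.HIGH: LosQuartiles(10.0, 7.0, 14.0),
        }
    )
    death_los_mean: float = 7.0
    death_los_bounds: tuple[float, float] = (1.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "sampled"):
            raise ValidationError(f"mode must be exact or sampled, got {self.mode!r}")
        if not 0 < self.target_mortality < 1:
            raise ValidationError(f"target_mortality must be in (0,1), got {self.target_mortality}")
        if not math.isfinite(self.beta1):
            raise ValidationError("beta1 must be finite")
        if self.scale < 1:
            raise ValidationError("scale must be a positive integer")


@dataclass(frozen=True)
class CalibratedModel:
    """Mortality model bound to a score table: p(death | m) = expit(alpha + beta1*m)."""

    alpha: float
    beta1: float
    cell_probs: Mapping[tuple[int, int], float]

    def prob(self, mqsofa: int) -> float:
        return float(expit(self.alpha + self.beta1 * mqsofa))


class CalibrationError(RuntimeError):
    pass


def _weighted_mortality(alpha: float, p: GeneratorParams, age_nodes=None, age_wts=None) -> float:
    weights = p.joint_table.counts.sum(axis=1) / p.joint_table.total
    m = np.arange(6)
    if p.age_beta == 0.0:
        return float(np.sum(weights * expit(alpha + p.beta1 * m)))
    # Age enters the linear predictor; integrate over the truncated marginal
    # age density (Gauss-Legendre on the bounded support).
    probs = expit(alpha + p.beta1 * m[:, None] + p.age_beta * (age_nodes[None, :] - p.age_marginal[0]))
    return float(np.sum(weights * (probs @ age_wts)))


def _age_quadrature(p: GeneratorParams, n_nodes: int = 200):
    lo, hi = p.age_bounds
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    nodes = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    mu, sd = p.age_marginal
    dens = norm.pdf(nodes, mu, sd)
    wts = w * 0.5 * (hi - lo) * dens
    wts /= wts.sum()  # renormalize for the truncation
    return nodes, wts


def calibrate_intercept(p: GeneratorParams) -> CalibratedModel:
    """Solve for the intercept matching the table-weighted mortality by bisection.

    The weighted mean of expit(alpha + beta1*m) over the table's MqSOFA
    margin is monotone increasing in alpha; bisection on [-20, 20] drives it
    to ``target_mortality`` within 1e-10.
    """
    age_nodes = age_wts = None
    if p.age_beta != 0.0:
        age_nodes, age_wts = _age_quadrature(p)
    lo, hi = -20.0, 20.0
    f_lo = _weighted_mortality(lo, p, age_nodes, age_wts) - p.target_mortality
    f_hi = _weighted_mortality(hi, p, age_nodes, age_wts) - p.target_mortality
    if f_lo > 0 or f_hi < 0:
        raise CalibrationError("no intercept in [-20, 20] matches the target mortality")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _weighted_mortality(mid, p, age_nodes, age_wts) - p.target_mortality
        if abs(f_mid) <= 1e-12 or hi - lo < 1e-14:
            break
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    achieved = _weighted_mortality(alpha, p, age_nodes, age_wts)
    if abs(achieved - p.target_mortality) > 1e-10:
        raise CalibrationError(
            f"calibration failed: achieved {achieved}, target {p.target_mortality}"
        )
    cell_probs = {
        (m, q): float(expit(alpha + p.beta1 * m))
        for m in range(6)
        for q in range(4)
        if q <= m
    }
    return CalibratedModel(alpha=alpha, beta1=p.beta1, cell_probs=cell_probs)


def los_lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) whose median and quartiles match the given days.

    mu = ln(median); sigma = (ln q3 - ln q1) / (2 * 0.67449).  A degenerate
    IQR (q1 = q3) yields sigma = 0.
    """
    if not 0 < q1 <= median <= q3:
        raise ValidationError(f"need 0 < q1 <= median <= q3, got {(median, q1, q3)}")
    return math.log(median), (math.log(q3) - math.log(q1)) / (2 * _Z75)


def _truncnorm_draw(rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float) -> float:
    """Inverse-CDF draw from a truncated normal (deterministic given the rng state)."""
    a = norm.cdf(lo, mu, sd)
    b = norm.cdf(hi, mu, sd)
    u = rng.uniform(a, b)
    return float(norm.ppf(u, mu, sd))


def _truncexp_draw(rng: np.random.Generator, mean: float, lo: float, hi: float) -> float:
    a = math.exp(-lo / mean)
    b = math.exp(-hi / mean)
    u = rng.uniform()
    return -mean * math.log(a - u * (a - b))


# qSOFA item subsets, indexed by point total, in a fixed order: each inner
# tuple flags (sbp_point, rr_point, mentation_point).
_QSOFA_COMBOS = {
    0: [(False, False, False)],
    1: [(True, False, False), (False, True, False), (False, False, True)],
    2: [(True, True, False), (True, False, True), (False, True, True)],
    3: [(True, True, True)],
}


def _draw_vitals(rng: np.random.Generator, qsofa: int, sf_pts: int) -> VitalSigns:
    combos = _QSOFA_COMBOS[qsofa]
    sbp_pt, rr_pt, ment = combos[rng.integers(len(combos))]
    sbp = rng.uniform(70.0, 100.0) if sbp_pt else rng.uniform(100.0 + 1e-9, 160.0)
    sbp = min(sbp, 160.0)
    rr = rng.uniform(22.0, 40.0) if rr_pt else rng.uniform(10.0, 21.0)
    lo, hi = _SF_WINDOWS[sf_pts]
    ratio = rng.uniform(lo, hi)
    # FiO2 anywhere in the window keeping SpO2 = ratio * FiO2 inside [60, 100].
    f_lo = max(0.21, 60.0 / ratio)
    f_hi = min(1.0, 100.0 / ratio)
    if f_lo > f_hi:  # pragma: no cover - unreachable with the windows above
        raise RuntimeError(f"infeasible FiO2 window for S/F ratio {ratio}")
    fio2 = rng.uniform(f_lo, f_hi)
    spo2 = min(ratio * fio2, 100.0)
    return VitalSigns(sbp=sbp, rr=rr, altered_mentation=ment, spo2=spo2, fio2=fio2)


def _cell_counts(p: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    base = p.joint_table.counts
    if p.mode == "exact":
        return base * p.scale
    n = p.n if p.n is not None else p.joint_table.total
    probs = (base / base.sum()).ravel()
    return rng.multinomial(n, probs).reshape(base.shape)


def generate_cohort(p: GeneratorParams) -> list[PatientRecord]:
    """Generate one patient-level cohort under the configured study conditions.

    Patients are emitted in cell order (MqSOFA 0..5, then qSOFA 0..m within a
    row); scores recomputed from the generated vitals always equal the
    assigned cell.
    """
    rng = np.random.default_rng(p.seed)
    model = calibrate_intercept(p)
    counts = _cell_counts(p, rng)
    records: list[PatientRecord] = []
    idx = 0
    for m in range(6):
        for q in range(4):
            if q > m:
                continue
            for _ in range(int(counts[m, q])):
                idx += 1
                vit = _draw_vitals(rng, q, m - q)
                if p.age_beta == 0.0:
                    died = rng.uniform() < model.cell_probs[(m, q)]
                    mu, sd = p.age_died if died else p.age_discharged
                    age = _truncnorm_draw(rng, mu, sd, *p.age_bounds)
                else:
                    age = _truncnorm_draw(rng, *p.age_marginal, *p.age_bounds)
                    prob = expit(model.alpha + p.beta1 * m + p.age_beta * (age - p.age_marginal[0]))
                    died = rng.uniform() < prob
                sex = "M" if rng.uniform() < p.male_prob else "F"
                if died:
                    los = _truncexp_draw(rng, p.death_los_mean, *p.death_los_bounds)
                else:
                    group = assign_risk_group(
                        ScorePair(qsofa=q, sf_points=m - q, mqsofa=m, sf_ratio=vit.spo2 / vit.fio2)
                    )
                    lq = p.los_quartiles[group]
                    mu_l, sig_l = los_lognormal_params(lq.median, lq.q1, lq.q3)
                    los = math.exp(mu_l + sig_l * rng.standard_normal())
                records.append(
                    PatientRecord(
                        id=f"S{idx:06d}",
                        age=int(round(min(max(age, 18.0), 110.0))),
                        sex=sex,
                        vitals=vit,
                        outcome="died" if died else "discharged",
                        los_days=round(max(los, 0.05), 2),
                    )
                )
    return records
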