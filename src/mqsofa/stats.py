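"""Discrimination and regression statistics, implemented from first principles.

ROC area via the Mann-Whitney kernel with half-credit for ties (the scores
are ordinal 0-5, so ties are the norm), DeLong placement-value variances and
the paired DeLong test for two ROC areas estimated on the same subjects,
maximum-likelihood logistic regression by Newton-Raphson with Wald inference,
and the Hosmer-Lemeshow goodness-of-calibration test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .scores import ValidationError

__all__ = [
    "RocResult",
    "DeLongComparison",
    "LogisticFit",
    "HLResult",
    "SeparationError",
    "auc_mann_whitney",
    "delong_roc",
    "delong_compare",
    "logistic_fit",
    "logistic_age_adjusted",
    "hosmer_lemeshow",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    degenerate_variance: bool = False


@dataclass(frozen=True)
class DeLongComparison:
    auc1: float
    auc2: float
    var1: float
    var2: float
    cov: float
    z: float
    p: float


@dataclass(frozen=True)
class LogisticFit:
    """Newton-Raphson maximum-likelihood logistic regression result.

    ``coefficients[0]`` is the intercept; slopes follow in predictor order.
    Odds ratios and their 95% intervals exponentiate the Wald interval.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    or_ci95: np.ndarray  # shape (k, 2)
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int


@dataclass(frozen=True)
class HLResult:
    statistic: float
    df: int
    p: float
    table: np.ndarray  # per-bin columns: n, observed, expected, mean_prob


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: for each case, the win fraction over the other group."""
    diff = pos[:, None] - neg[None, :]
    kernel = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return kernel.mean(axis=1), kernel.mean(axis=0)


def auc_mann_whitney(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """AUC as the mean over all (positive, negative) pairs of the 1/0.5/0 kernel.

    Higher score = higher death risk; ties earn half credit.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("AUC needs at least one case in each outcome group")
    diff = pos[:, None] - neg[None, :]
    kernel = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    # single division of an exactly representable sum of halves: matches
    # brute-force pair counting bit for bit
    return float(kernel.sum() / (pos.size * neg.size))


def delong_roc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> RocResult:
    """AUC with the DeLong variance Var = S10/n1 + S01/n0 and a Wald 95% CI.

    S10 and S01 are the sample variances (n-1 divisor) of the positive- and
    negative-side placement values.  The CI is clamped to [0, 1].
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("DeLong variance needs at least 2 cases per group")
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    degenerate = var <= 0
    se = math.sqrt(max(var, 0.0))
    return RocResult(
        auc=auc,
        se=se,
        ci95=(max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)),
        n_pos=pos.size,
        n_neg=neg.size,
        degenerate_variance=degenerate,
    )


def delong_compare(
    scoresA_pos: Sequence[float],
    scoresA_neg: Sequence[float],
    scoresB_pos: Sequence[float],
    scoresB_neg: Sequence[float],
) -> DeLongComparison:
    """Paired DeLong test for two correlated AUCs scored on the same subjects.

    The covariance pools the paired placement-value covariances from each
    outcome group; z = (AUC_A - AUC_B) / sqrt(varA + varB - 2 cov).
    """
    a_pos = np.asarray(scoresA_pos, dtype=float)
    a_neg = np.asarray(scoresA_neg, dtype=float)
    b_pos = np.asarray(scoresB_pos, dtype=float)
    b_neg = np.asarray(scoresB_neg, dtype=float)
    if a_pos.size != b_pos.size or a_neg.size != b_neg.size:
        raise ValidationError("paired DeLong comparison requires identically ordered subjects")
    if a_pos.size < 2 or a_neg.size < 2:
        raise ValidationError("DeLong comparison needs at least 2 cases per group")
    va10, va01 = _placements(a_pos, a_neg)
    vb10, vb01 = _placements(b_pos, b_neg)
    n1, n0 = a_pos.size, a_neg.size
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    var_a = va10.var(ddof=1) / n1 + va01.var(ddof=1) / n0
    var_b = vb10.var(ddof=1) / n1 + vb01.var(ddof=1) / n0
    cov = (
        float(np.cov(va10, vb10, ddof=1)[0, 1]) / n1
        + float(np.cov(va01, vb01, ddof=1)[0, 1]) / n0
    )
    denom = var_a + var_b - 2 * cov
    if denom <= 0:
        z = 0.0
    else:
        z = (auc_a - auc_b) / math.sqrt(denom)
    return DeLongComparison(
        auc1=auc_a,
        auc2=auc_b,
        var1=var_a,
        var2=var_b,
        cov=cov,
        z=z,
        p=float(2 * norm.sf(abs(z))),
    )


def logistic_fit(
    outcome: Sequence[int],
    predictors: Sequence[Sequence[float]] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticFit:
    """Fit death ~ predictors by Newton-Raphson on the binomial log-likelihood.

    Parameters
    ----------
    outcome : 0/1 sequence.
    predictors : one sequence per predictor (or a 2-D array, one column per
        predictor); the intercept is added internally.

    Iterates beta <- beta + (X'WX)^-1 X'(y - p) from the zero vector until
    the largest coefficient update is below ``tol``.  Any coefficient
    exceeding 15 in absolute value during iteration raises
    :class:`SeparationError`.
    """
    y = np.asarray(outcome, dtype=float)
    X_raw = np.asarray(predictors, dtype=float)
    if X_raw.ndim == 1:
        X_raw = X_raw[:, None]
    elif X_raw.shape[0] != y.size and X_raw.shape[1] == y.size:
        X_raw = X_raw.T
    n, k = X_raw.shape
    if n != y.size:
        raise ValidationError("outcome and predictor lengths differ")
    if n < 10:
        raise ValidationError("logistic fit needs at least 10 observations")
    if np.any(np.ptp(X_raw, axis=0) == 0):
        raise ValidationError("constant predictor column")
    X = np.column_stack([np.ones(n), X_raw])
    beta = np.zeros(k + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = p * (1 - p)
        info = X.T @ (X * w[:, None])
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix at iteration {it}") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 15:
            raise SeparationError("coefficient diverged (|beta| > 15): separation likely")
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations; last beta {beta}"
        )
    p = expit(X @ beta)
    info = X.T @ (X * (p * (1 - p))[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    eps = 1e-12
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    z = beta / se
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        odds_ratios=np.exp(beta),
        or_ci95=np.exp(np.column_stack([beta - 1.96 * se, beta + 1.96 * se])),
        p_values=2 * norm.sf(np.abs(z)),
        log_likelihood=ll,
        converged=converged,
        n_iterations=it,
    )


def logistic_age_adjusted(
    outcome: Sequence[int], score: Sequence[float], age: Sequence[float]
) -> LogisticFit:
    """Two-predictor fit: death ~ score + age (the age-adjusted model)."""
    return logistic_fit(outcome, np.column_stack([score, age]))


def hosmer_lemeshow(
    outcome: Sequence[int], fitted_probs: Sequence[float], g: int = 10
) -> HLResult:
    """Hosmer-Lemeshow calibration test on ``g`` equal-count risk bins.

    Subjects are sorted by fitted probability and split into ``g`` groups;
    tied probabilities stay together, so fewer bins may result (typical for
    ordinal scores).  statistic = sum over bins of (O - E)^2 / (n p(1-p))
    with p the bin mean probability; df = bins - 2.
    """
    y = np.asarray(outcome, dtype=float)
    p = np.asarray(fitted_probs, dtype=float)
    if y.size != p.size:
        raise ValidationError("outcome and probability lengths differ")
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("fitted probabilities must lie strictly in (0, 1)")
    if np.unique(p).size < 3:
        raise ValidationError("Hosmer-Lemeshow undefined with fewer than 3 distinct risks")
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    # Tentative equal-count cut points, then merged so ties never straddle bins.
    edges = [int(round(i * y.size / g)) for i in range(1, g)]
    bins: list[tuple[int, int]] = []
    start = 0
    for e in edges:
        # push the boundary right past any run of tied probabilities
        while 0 < e < y.size and ps[e] == ps[e - 1]:
            e += 1
        if e <= start or e >= y.size:
            continue
        bins.append((start, e))
        start = e
    bins.append((start, y.size))
    rows = []
    stat = 0.0
    for lo, hi in bins:
        nb = hi - lo
        obs = float(ys[lo:hi].sum())
        pbar = float(ps[lo:hi].mean())
        exp = nb * pbar
        stat += (obs - exp) ** 2 / (nb * pbar * (1 - pbar))
        rows.append((nb, obs, exp, pbar))
    df = max(len(bins) - 2, 1)
    return HLResult(
        statistic=stat,
        df=df,
        p=float(chi2_dist.sf(stat, df=df)),
        table=np.array(rows),
    )
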