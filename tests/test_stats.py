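"""ROC/AUC, DeLong, logistic regression and Hosmer-Lemeshow tests.

Independent oracles: brute-force pair enumeration for the AUC, a bootstrap
for the DeLong variance, a permutation test for the paired AUC comparison,
and statsmodels for the logistic maximum-likelihood fit.
"""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from mqsofa.diagnostics import ConfusionTable, dichotomized_or
from mqsofa.scores import ValidationError
from mqsofa.stats import (
    SeparationError,
    auc_mann_whitney,
    delong_compare,
    delong_roc,
    hosmer_lemeshow,
    logistic_fit,
)


def brute_force_auc(pos, neg):
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_worked_example():
    assert auc_mann_whitney([3, 2], [1, 2]) == pytest.approx(0.875)


def test_auc_degenerate_cases():
    assert auc_mann_whitney([5, 6], [1, 2]) == 1.0
    assert auc_mann_whitney([3, 3], [3, 3]) == 0.5


def test_auc_equals_brute_force_on_random_instances(rng):
    for _ in range(200):
        n1 = int(rng.integers(1, 30))
        n0 = int(rng.integers(1, 30))
        pos = rng.integers(0, 6, n1).astype(float)
        neg = rng.integers(0, 6, n0).astype(float)
        assert auc_mann_whitney(pos, neg) == brute_force_auc(pos, neg)


def test_auc_negation_symmetry(rng):
    pos = rng.normal(1, 1, 25)
    neg = rng.normal(0, 1, 40)
    assert auc_mann_whitney(pos, neg) == pytest.approx(
        1.0 - auc_mann_whitney(-pos, -neg), abs=1e-12
    )


def test_delong_worked_example():
    r = delong_roc([3, 2], [1, 2])
    assert r.auc == pytest.approx(0.875)
    assert r.se == pytest.approx(math.sqrt(0.03125), abs=1e-4)


def test_delong_perfect_separation_zero_se():
    r = delong_roc([10, 11, 12], [1, 2, 3])
    assert r.auc == 1.0
    assert r.se == 0.0
    assert r.degenerate_variance


def test_delong_variance_close_to_bootstrap(rng):
    pos = rng.normal(1.0, 1.0, 120)
    neg = rng.normal(0.0, 1.0, 200)
    r = delong_roc(pos, neg)
    boots = []
    for _ in range(2000):
        bp = rng.choice(pos, pos.size, replace=True)
        bn = rng.choice(neg, neg.size, replace=True)
        boots.append(auc_mann_whitney(bp, bn))
    boot_var = np.var(boots, ddof=1)
    assert r.se**2 == pytest.approx(boot_var, rel=0.15)


def test_delong_se_shrinks_with_n(rng):
    ses = []
    for n in (100, 400, 1600):
        pos = rng.normal(0.8, 1.0, n // 3)
        neg = rng.normal(0.0, 1.0, n - n // 3)
        ses.append(delong_roc(pos, neg).se)
    assert ses[0] > ses[1] > ses[2]


def test_delong_compare_identical_scores():
    pos, neg = [3.0, 2.0, 4.0], [1.0, 2.0, 0.0]
    c = delong_compare(pos, neg, pos, neg)
    assert c.z == 0.0 and c.p == 1.0


def test_delong_compare_ci_consistency(rng):
    x_pos = rng.normal(1, 1, 60)
    x_neg = rng.normal(0, 1, 90)
    noisy_pos = x_pos + rng.normal(0, 2, 60)
    noisy_neg = x_neg + rng.normal(0, 2, 90)
    c = delong_compare(x_pos, x_neg, noisy_pos, noisy_neg)
    assert abs(c.cov) <= math.sqrt(c.var1 * c.var2) + 1e-12
    assert 0 <= c.p <= 1


def test_delong_compare_matches_permutation_oracle(rng):
    """Under exchangeable scores A/B, the DeLong p is roughly uniform; on a
    small worked pair the permutation distribution of the AUC difference
    brackets the observed z consistently."""
    y = np.array([1] * 8 + [0] * 12)
    a = rng.normal(y * 1.0, 1.0)
    b = rng.normal(y * 1.0, 1.0)
    obs = delong_compare(a[y == 1], a[y == 0], b[y == 1], b[y == 0])
    diffs = []
    for _ in range(2000):
        swap = rng.uniform(size=y.size) < 0.5
        aa = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        d = auc_mann_whitney(aa[y == 1], aa[y == 0]) - auc_mann_whitney(
            bb[y == 1], bb[y == 0]
        )
        diffs.append(d)
    obs_diff = obs.auc1 - obs.auc2
    perm_p = np.mean(np.abs(diffs) >= abs(obs_diff) - 1e-12)
    # both tests must agree on significance at a generous band
    assert (obs.p < 0.2) == (perm_p < 0.2) or abs(obs.p - perm_p) < 0.15


def test_delong_unpaired_lengths_error():
    with pytest.raises(ValidationError):
        delong_compare([1, 2, 3], [0, 1], [1, 2], [0, 1])


def test_logistic_on_saturated_2x2_equals_cross_product_or():
    ct = ConfusionTable(203, 186, 130, 482)
    y = [1] * ct.tp + [0] * ct.fp + [1] * ct.fn + [0] * ct.tn
    x = [1.0] * (ct.tp + ct.fp) + [0.0] * (ct.fn + ct.tn)
    fit = logistic_fit(y, x)
    assert fit.odds_ratios[1] == pytest.approx(dichotomized_or(ct).oddsratio, abs=1e-6)


def test_logistic_matches_statsmodels(rng):
    n = 400
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x1 - 0.3 * x2)))
    y = (rng.uniform(size=n) < p).astype(int)
    fit = logistic_fit(y, np.column_stack([x1, x2]))
    oracle = sm.Logit(y, sm.add_constant(np.column_stack([x1, x2]))).fit(disp=0)
    assert fit.coefficients == pytest.approx(oracle.params, abs=1e-6)
    assert fit.standard_errors == pytest.approx(oracle.bse, abs=1e-6)
    assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-4)


def test_logistic_null_slope(rng):
    n = 500
    x = rng.normal(size=n)
    y = rng.integers(0, 2, n)
    fit = logistic_fit(y, x)
    assert abs(fit.coefficients[1]) < 3 * fit.standard_errors[1] + 0.2
    assert fit.odds_ratios[1] == pytest.approx(1.0, abs=0.5)


def test_logistic_separation_detected():
    y = [0] * 10 + [1] * 10
    x = list(range(10)) + list(range(20, 30))
    with pytest.raises(SeparationError):
        logistic_fit(y, [float(v) for v in x])


def test_logistic_collinear_design_errors(rng):
    n = 100
    age = rng.normal(70, 10, n)
    y = rng.integers(0, 2, n)
    with pytest.raises((SeparationError, RuntimeError)):
        logistic_fit(y, np.column_stack([age, age]))


def test_logistic_rejects_tiny_or_constant():
    with pytest.raises(ValidationError):
        logistic_fit([0, 1] * 3, [1.0] * 6)
    with pytest.raises(ValidationError):
        logistic_fit([0, 1] * 10, [1.0] * 20)


def test_hl_zero_statistic_when_perfectly_matched():
    # two deaths out of four at p=0.5 in every bin pattern
    y = [0, 1, 0, 1, 0, 1] * 10
    p = [0.3, 0.3, 0.5, 0.5, 0.7, 0.7] * 10
    # arrange so that each probability level's observed rate equals the level
    y = []
    p = []
    for level, k in ((0.2, 10), (0.5, 10), (0.8, 10)):
        deaths = int(level * k)
        y += [1] * deaths + [0] * (k - deaths)
        p += [level] * k
    res = hosmer_lemeshow(y, p, g=3)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_hl_bins_follow_distinct_ordinal_values(rng):
    probs = np.array([0.1, 0.2, 0.3, 0.5, 0.7, 0.9])
    p = np.repeat(probs, 40)
    y = (rng.uniform(size=p.size) < p).astype(int)
    res = hosmer_lemeshow(y, p, g=10)
    assert len(res.table) <= 6
    assert res.df == len(res.table) - 2
    # bins partition the sample
    assert int(res.table[:, 0].sum()) == p.size


def test_hl_requires_three_distinct_values():
    with pytest.raises(ValidationError):
        hosmer_lemeshow([0, 1] * 10, [0.3, 0.6] * 10)
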