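"""Kaplan-Meier, log-rank and rank-test checks against oracles.

Oracles: hand product-limit arithmetic, lifelines (KM and multivariate
log-rank), an exact permutation log-rank on a tiny instance, and
scipy.stats for the rank tests.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from mqsofa.scores import RiskGroup, ValidationError
from mqsofa.stats import auc_mann_whitney
from mqsofa.survival import (
    SurvivalInput,
    km_estimate,
    kruskal_wallis,
    logrank_test,
    los_by_group,
    mann_whitney,
    survival_inputs,
)

G = RiskGroup.LOW


def _si(times, events, group=G):
    return [SurvivalInput(t, bool(e), group) for t, e in zip(times, events)]


def test_km_hand_example():
    curve = km_estimate(_si([1, 2, 3, 4], [1, 1, 0, 0]))
    assert curve.survival_at(1) == pytest.approx(0.75)
    assert curve.survival_at(2) == pytest.approx(0.50)
    assert curve.survival_at(10) == pytest.approx(0.50)  # censoring holds the level


def test_km_all_censored_flat():
    curve = km_estimate(_si([2, 5, 9], [0, 0, 0]))
    assert curve.event_times.size == 0
    assert curve.survival_at(100) == 1.0


def test_km_no_censoring_equals_empirical_survival(rng):
    times = rng.exponential(5, 200) + 0.01
    curve = km_estimate(_si(times, np.ones(200)))
    for t in curve.event_times:
        assert curve.survival_at(t) == pytest.approx(np.mean(times > t), abs=1e-12)


def test_km_at_risk_conservation(rng):
    times = np.round(rng.exponential(5, 150), 1) + 0.1
    events = rng.uniform(size=150) < 0.6
    curve = km_estimate(_si(times, events))
    # at each event time, the at-risk count equals subjects with time >= t
    for t, n_r in zip(curve.event_times, curve.at_risk):
        assert n_r == np.sum(times >= t)


def test_km_matches_lifelines(rng):
    times = np.round(rng.exponential(7, 120), 1) + 0.1
    events = rng.uniform(size=120) < 0.5
    curve = km_estimate(_si(times, events))
    kmf = KaplanMeierFitter().fit(times, events)
    for t in curve.event_times:
        assert curve.survival_at(t) == pytest.approx(
            float(kmf.predict(t)), abs=1e-10
        )


def test_logrank_identical_groups_null():
    a = _si([1, 2, 3, 4], [1, 1, 0, 1], RiskGroup.LOW)
    b = _si([1, 2, 3, 4], [1, 1, 0, 1], RiskGroup.HIGH)
    res = logrank_test(a + b)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_observed_minus_expected_conserved(rng):
    data = []
    for g, lam in ((RiskGroup.LOW, 10), (RiskGroup.RECLASSIFIED_HIGH, 6), (RiskGroup.HIGH, 4)):
        times = rng.exponential(lam, 40) + 0.01
        events = rng.uniform(size=40) < 0.7
        data += _si(times, events, g)
    res = logrank_test(data)
    assert res.observed.sum() == pytest.approx(res.expected.sum(), abs=1e-10)
    assert res.df == 2


def test_logrank_matches_lifelines(rng):
    times, events, labels = [], [], []
    for i, (g, lam) in enumerate(
        ((RiskGroup.LOW, 12), (RiskGroup.RECLASSIFIED_HIGH, 6), (RiskGroup.HIGH, 5))
    ):
        t = np.round(rng.exponential(lam, 50), 1) + 0.1
        e = rng.uniform(size=50) < 0.65
        times += list(t)
        events += list(e)
        labels += [i] * 50
    data = [
        SurvivalInput(t, bool(e), list(RiskGroup)[l])
        for t, e, l in zip(times, events, labels)
    ]
    res = logrank_test(data)
    oracle = multivariate_logrank_test(times, labels, events)
    assert res.chi2 == pytest.approx(oracle.test_statistic, rel=1e-6)
    assert res.p == pytest.approx(oracle.p_value, rel=1e-6)


def test_logrank_two_group_permutation_oracle():
    """Exact permutation reference on n = 8 with no censoring."""
    times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
    events = [1] * 8
    obs_labels = (0, 0, 0, 1, 0, 1, 1, 1)

    def chi2_for(labels):
        data = [
            SurvivalInput(t, bool(e), RiskGroup.LOW if l == 0 else RiskGroup.HIGH)
            for t, e, l in zip(times, events, labels)
        ]
        return logrank_test(data).chi2

    obs = chi2_for(obs_labels)
    perm_stats = [
        chi2_for(lab)
        for lab in set(itertools.permutations(obs_labels))
    ]
    perm_p = np.mean([s >= obs - 1e-12 for s in perm_stats])
    analytic_p = logrank_test(
        [
            SurvivalInput(t, True, RiskGroup.LOW if l == 0 else RiskGroup.HIGH)
            for t, l in zip(times, obs_labels)
        ]
    ).p
    # the chi-square approximation should land in the permutation ballpark
    assert abs(analytic_p - perm_p) < 0.15


def test_logrank_empty_group_errors():
    with pytest.raises(ValidationError):
        logrank_test(_si([1, 2], [1, 1], RiskGroup.LOW), [RiskGroup.LOW, RiskGroup.HIGH])


def test_mann_whitney_orientation_and_enumeration():
    u, z, p = mann_whitney([1, 2], [3, 4])
    assert u == 4.0  # every B exceeds every A
    # exact two-sided p from enumerating all C(4,2)=6 rank splits is 1/3;
    # the normal approximation without continuity correction is cruder
    assert 0.05 < p < 0.35


def test_mann_whitney_all_ties():
    u, z, p = mann_whitney([5, 5, 5], [5, 5])
    assert z == 0.0 and p == 1.0


def test_mann_whitney_matches_scipy(rng):
    a = rng.integers(0, 10, 30).astype(float)
    b = rng.integers(0, 10, 25).astype(float)
    u, z, p = mann_whitney(a, b)
    oracle = scipy.stats.mannwhitneyu(
        b, a, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    assert u == pytest.approx(oracle.statistic)
    assert p == pytest.approx(oracle.pvalue, rel=1e-9)


def test_u_auc_identity(rng):
    for _ in range(50):
        a = rng.integers(0, 6, int(rng.integers(2, 20))).astype(float)
        b = rng.integers(0, 6, int(rng.integers(2, 20))).astype(float)
        u, _, _ = mann_whitney(a, b)
        assert u / (a.size * b.size) == pytest.approx(
            auc_mann_whitney(b, a), abs=1e-12
        )


def test_kruskal_wallis_hand_example():
    h, df, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    # rank sums 3, 7, 11: H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 21 = 32/7
    assert h == pytest.approx(32 / 7, abs=1e-10)
    assert df == 2
    oracle = scipy.stats.kruskal([1, 2], [3, 4], [5, 6])
    assert h == pytest.approx(oracle.statistic, abs=1e-10)


def test_kruskal_wallis_identical_groups():
    h, _, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert h == pytest.approx(0.0, abs=1e-10)


def test_kruskal_wallis_ties_match_scipy(rng):
    groups = [rng.integers(0, 5, 20).astype(float) for _ in range(3)]
    h, df, p = kruskal_wallis(groups)
    oracle = scipy.stats.kruskal(*groups)
    assert h == pytest.approx(oracle.statistic, rel=1e-10)
    assert p == pytest.approx(oracle.pvalue, rel=1e-9)


def test_los_by_group_structure(default_cohort):
    res = los_by_group(default_cohort)
    assert res.test == "kruskal_wallis"
    assert set(res.medians) == {"low", "reclassified_high", "high"}
    for g in res.medians:
        q1, q3 = res.iqrs[g]
        assert q1 <= res.medians[g] <= q3
    assert sum(res.n_per_group.values()) == sum(1 for r in default_cohort if not r.died)


def test_los_medians_near_configured(big_cohort):
    res = los_by_group(big_cohort)
    assert res.medians["low"] == pytest.approx(8.5, abs=0.4)
    assert res.medians["reclassified_high"] == pytest.approx(10.0, abs=0.6)
    assert res.medians["high"] == pytest.approx(10.0, abs=0.5)


def test_survival_inputs_from_records(default_cohort):
    data = survival_inputs(default_cohort)
    assert len(data) == len(default_cohort)
    assert sum(d.event for d in data) == sum(r.died for r in default_cohort)
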