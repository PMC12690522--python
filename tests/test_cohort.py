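"""Kaplan-Meier, Mann-Whitney, growth alignment and box summaries.

Independent oracles: lifelines for the product-limit estimator, brute-force
rank enumeration and scipy for the Mann-Whitney test.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from scipy import stats as sps

import ifquant as q


def survival_frame(times, events, group="g"):
    return pd.DataFrame({"animal_id": [f"a{i}" for i in range(len(times))],
                         "group": group, "time_days": times, "event": events})


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_four_events_no_censoring():
    curve = q.km_estimate(survival_frame([10, 20, 30, 40], [True] * 4))
    assert np.allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
    assert list(curve.at_risk) == [4, 3, 2, 1]
    assert curve.median == 20


def test_km_all_censored_median_undefined():
    curve = q.km_estimate(survival_frame([5, 9, 11], [False] * 3))
    assert curve.times.size == 0
    assert curve.survival_at(100.0) == 1.0
    assert curve.median is None


def test_km_hand_worked_censoring_case():
    """Times {5, 8c, 12, 16}: S(5)=0.75, S(12)=0.375, median=12."""
    curve = q.km_estimate(survival_frame([5, 8, 12, 16], [True, False, True, True]))
    assert curve.survival_at(5) == pytest.approx(0.75)
    assert curve.survival_at(12) == pytest.approx(0.375)
    assert curve.median == 12


def test_km_row_permutation_invariance():
    rng = np.random.default_rng(3)
    times = rng.exponential(30, size=25)
    events = rng.random(25) < 0.7
    base = q.km_estimate(survival_frame(times, events))
    perm = rng.permutation(25)
    shuffled = q.km_estimate(survival_frame(times[perm], events[perm]))
    assert base.median == shuffled.median
    assert np.allclose(base.survival, shuffled.survival)


@pytest.mark.parametrize("seed", range(6))
def test_km_equals_empirical_survival_without_censoring(seed):
    rng = np.random.default_rng(seed)
    times = rng.exponential(30, size=rng.integers(3, 40))
    curve = q.km_estimate(survival_frame(times, [True] * len(times)))
    for t in np.quantile(times, [0.1, 0.5, 0.9]):
        empirical = np.mean(times > t)
        assert curve.survival_at(t) == pytest.approx(empirical, abs=1e-12)


@pytest.mark.parametrize("seed", range(4))
def test_km_matches_lifelines(seed):
    rng = np.random.default_rng(10 + seed)
    n = int(rng.integers(5, 60))
    times = rng.exponential(30, size=n).round(1) + 0.1
    events = rng.random(n) < 0.6
    if not events.any():
        events[0] = True
    curve = q.km_estimate(survival_frame(times, events))
    kmf = KaplanMeierFitter().fit(times, events)
    for t, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(float(kmf.predict(t)), abs=1e-10)
    expected_median = float(kmf.median_survival_time_)
    if math.isinf(expected_median):
        assert curve.median is None
    else:
        assert curve.median == pytest.approx(expected_median)


def test_km_rejects_nonpositive_times():
    with pytest.raises(ValueError):
        q.km_estimate(survival_frame([0.0, 5.0], [True, True]))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def enumeration_p(x, y):
    """Oracle: two-sided exact p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [sum(c) - n1 * (n1 + 1) / 2
          for c in itertools.combinations(range(1, len(pooled) + 1), n1)]
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lower, upper))


def test_identical_samples_are_maximally_nonsignificant():
    x = [1.0, 2.0, 3.0, 4.0]
    result = q.mann_whitney(x, x)
    assert result.u == len(x) ** 2 / 2
    assert result.p == 1.0
    assert not result.significant


def test_fully_separated_small_samples_exact_p():
    """x={1,2,3} below y={4,5,6}: U=0, two-sided p = 2/C(6,3) = 0.1."""
    result = q.mann_whitney([1, 2, 3], [4, 5, 6])
    assert result.u == 0
    assert result.method == "exact"
    assert result.p == pytest.approx(0.1, abs=1e-12)


def test_exact_matches_enumeration_for_all_small_tie_free_inputs():
    """Every rank pattern with n1+n2 <= 10 agrees with the enumeration oracle."""
    for n in range(2, 11):
        for n1 in range(1, n):
            n2 = n - n1
            for subset in itertools.combinations(range(1, n + 1), n1):
                x = np.array(subset, dtype=float)
                y = np.array(sorted(set(range(1, n + 1)) - set(subset)), dtype=float)
                result = q.mann_whitney(x, y)
                assert result.method == "exact"
                assert result.p == pytest.approx(enumeration_p(x, y), abs=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_exact_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=5)
    y = rng.normal(size=5)
    result = q.mann_whitney(x, y)
    expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert result.method == "exact"
    assert result.p == pytest.approx(expected.pvalue, abs=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_normal_approximation_close_to_exact_at_n6(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=6)
    y = rng.normal(0.5, size=6)
    exact = q.mann_whitney(x, y, max_exact=12)
    approx = q.mann_whitney(x, y, max_exact=0)
    assert approx.method == "normal"
    assert abs(approx.p - exact.p) < 0.02


def test_ties_disable_exact_method():
    result = q.mann_whitney([1, 2, 2, 3], [2, 4, 5])
    assert result.method == "normal"
    assert 0 < result.p <= 1


def test_u_statistic_within_bounds():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.normal(size=rng.integers(2, 30))
        y = rng.normal(size=rng.integers(2, 30))
        r = q.mann_whitney(x, y)
        assert 0 <= r.u <= len(x) * len(y)


# ---------------------------------------------------------------------------
# growth alignment
# ---------------------------------------------------------------------------

def growth_frame(rows):
    return pd.DataFrame(rows, columns=["animal_id", "group", "day",
                                       "induction_day", "size"])


def test_alignment_shifts_induction_to_zero():
    table = growth_frame([("a", "g", 30, 30, 5.0), ("a", "g", 37, 30, 9.0)])
    aligned, excluded = q.align_growth(table)
    assert list(aligned["day"]) == [0, 7]
    assert excluded == []


def test_identical_trajectories_have_zero_sd():
    rows = [(f"a{i}", "g", d, 0, 2.0 * d) for i in range(3) for d in (0, 5, 10)]
    aligned, _ = q.align_growth(growth_frame(rows))
    assert (aligned["n"] == 3).all()
    assert np.allclose(aligned["sd"], 0.0)


def test_singleton_days_carry_undefined_sd():
    table = growth_frame([("a", "g", 0, 0, 5.0), ("b", "g", 0, 0, 6.0),
                          ("a", "g", 7, 0, 8.0)])
    aligned, _ = q.align_growth(table)
    by_day = aligned.set_index("day")
    assert by_day.loc[0, "sd"] == pytest.approx(np.std([5, 6], ddof=1))
    assert np.isnan(by_day.loc[7, "sd"])


def test_series_without_post_induction_measurements_excluded():
    table = growth_frame([("pre", "g", 5, 30, 1.0), ("ok", "g", 35, 30, 2.0)])
    aligned, excluded = q.align_growth(table)
    assert excluded == ["pre"]
    assert set(aligned["day"]) == {5.0}


# ---------------------------------------------------------------------------
# box summary
# ---------------------------------------------------------------------------

def test_box_summary_small_example():
    med, q25, q75 = q.box_summary([1, 2, 3, 4, 5])
    assert (med, q25, q75) == (3.0, 2.0, 4.0)


def test_box_summary_single_value():
    assert q.box_summary([7.5]) == (7.5, 7.5, 7.5)


def test_box_summary_normal_quartiles():
    rng = np.random.default_rng(1)
    _, q25, q75 = q.box_summary(rng.standard_normal(100_000))
    assert q25 == pytest.approx(-0.6745, abs=0.02)
    assert q75 == pytest.approx(0.6745, abs=0.02)


@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
@settings(max_examples=50, deadline=None)
def test_box_summary_ordering(values):
    med, q25, q75 = q.box_summary(values)
    assert q25 <= med <= q75
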