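import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methreprog import stats as S


# ---------------------------------------------------------------------------
# region means
# ---------------------------------------------------------------------------

def test_region_mean_level_examples(rng):
    assert S.region_mean_level([2, 4], [4, 4]) == pytest.approx(75.0)
    assert S.region_mean_level([0], [7]) == 0.0
    assert math.isnan(S.region_mean_level([], []))
    # unweighted vs read-weighted differ with unequal depths
    assert S.region_mean_level([1, 9], [10, 10]) == pytest.approx(50.0)
    assert S.region_mean_level([1, 90], [10, 100], weighted=True) == pytest.approx(
        100 * 91 / 110)
    # 1000 CpGs at p=0.6, depth 20: mean within 60 +- 1.5
    total = np.full(1000, 20)
    meth = rng.binomial(total, 0.6)
    assert S.region_mean_level(meth, total) == pytest.approx(60.0, abs=1.5)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def test_t_test_identical_and_degenerate():
    v = [10.0, 20.0, 30.0, 40.0]
    assert S.student_t_test(v, v).p_value == pytest.approx(1.0)
    assert S.student_t_test(v, v, mode="paired").statistic == 0.0
    r = S.student_t_test([0, 0, 0, 0], [100, 100, 100, 100])
    assert r.p_value == 0.0  # zero-variance degenerate case
    assert math.isnan(S.student_t_test([1.0], [2.0, 3.0]).p_value)


def test_t_test_symmetric_in_argument_order(rng):
    a = rng.normal(50, 10, 15)
    b = rng.normal(55, 10, 12)
    assert S.student_t_test(a, b).p_value == pytest.approx(
        S.student_t_test(b, a).p_value)


def test_t_test_type_one_error_calibration(rng):
    """Same-distribution groups rejected at alpha=0.05 about 5% of the time."""
    n_rep, n = 10_000, 20
    a = rng.normal(0, 1, (n_rep, n))
    b = rng.normal(0, 1, (n_rep, n))
    _, p = S.t_test_from_summary(a.mean(1), a.var(1, ddof=1), np.full(n_rep, n),
                                 b.mean(1), b.var(1, ddof=1), np.full(n_rep, n))
    assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)


def test_summary_t_matches_scipy(rng):
    a = rng.normal(40, 12, 18)
    b = rng.normal(52, 9, 14)
    ref = S.student_t_test(a, b)
    t, p = S.t_test_from_summary([a.mean()], [a.var(ddof=1)], [len(a)],
                                 [b.mean()], [b.var(ddof=1)], [len(b)])
    assert t[0] == pytest.approx(ref.statistic)
    assert p[0] == pytest.approx(ref.p_value)


# ---------------------------------------------------------------------------
# BH correction
# ---------------------------------------------------------------------------

def test_bh_examples():
    np.testing.assert_allclose(S.bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])
    assert S.bh_adjust([0.2])[0] == pytest.approx(0.2)
    np.testing.assert_allclose(S.bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        S.bh_adjust([0.5, 1.5])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_dominates_p_and_preserves_order(ps):
    q = S.bh_adjust(ps)
    assert (q >= np.asarray(ps) - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()
    # step-up adjustment preserves the ranking of the raw p-values
    order = np.argsort(ps, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()
    # reapplication can only move q-values further from the raw p's
    assert (S.bh_adjust(q) >= q - 1e-12).all()


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_chi_square_printed_enrichment_table():
    """Uncorrected Pearson on 11/44 gDMRs vs 1763/27718 CGIs gives a p of
    order 4e-7."""
    r = S.chi_square_2x2(11, 33, 1763, 25955)
    assert r.p_value == pytest.approx(4.1e-7, rel=0.15)


def test_chi_square_proportional_and_errors():
    r = S.chi_square_2x2(10, 10, 20, 20)
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError, match="marginal"):
        S.chi_square_2x2(0, 0, 5, 5)


def test_chi_square_invariant_under_swaps():
    base = S.chi_square_2x2(7, 12, 30, 9).statistic
    assert S.chi_square_2x2(30, 9, 7, 12).statistic == pytest.approx(base)
    assert S.chi_square_2x2(12, 7, 9, 30).statistic == pytest.approx(base)


def test_chi_square_vs_permutation_null(rng):
    """Uncorrected chi-square p agrees with a Monte-Carlo permutation null
    (margins fixed) within MC error on a moderate table."""
    a, b, c, d = 30, 20, 18, 32
    obs = S.chi_square_2x2(a, b, c, d)
    n1, total_with = a + b, a + c
    n = a + b + c + d
    labels = np.zeros(n, bool)
    labels[:total_with] = True
    count = 0
    n_mc = 4000
    for _ in range(n_mc):
        rng.shuffle(labels)
        aa = labels[:n1].sum()
        stat = S.chi_square_2x2(aa, n1 - aa, total_with - aa,
                                n - n1 - (total_with - aa)).statistic
        count += stat >= obs.statistic - 1e-9
    assert count / n_mc == pytest.approx(obs.p_value, abs=0.02)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mwu_exact_example_and_ties():
    r = S.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert r.statistic == 0.0
    assert r.p_value == pytest.approx(0.1)  # 2/C(6,3) * ... exact
    assert S.mann_whitney_u([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)
    with pytest.raises(ValueError, match="empty"):
        S.mann_whitney_u([], [1.0])


def _enumerate_mwu_p(x, y):
    """Exhaustive two-sided p over all label assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = S.mann_whitney_u(x, y).statistic
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(n), n1):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        ranks_x = sum(np.searchsorted(np.sort(pooled), v) + 1 for v in xs)
        u = ranks_x - n1 * (n1 + 1) / 2
        total += 1
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
    return count / total


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_mwu_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    x = rng.permutation(np.arange(30.0))[:5]
    y = rng.permutation(np.arange(100.0, 130.0))[:6] - rng.uniform(0, 90)
    r = S.mann_whitney_u(x, y)
    assert r.p_value == pytest.approx(_enumerate_mwu_p(x, y), abs=1e-9)


def test_mwu_power_at_one_sd_shift(rng):
    hits = 0
    for _ in range(300):
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        hits += S.mann_whitney_u(x, y).p_value < 0.05
    assert hits / 300 > 0.9


# ---------------------------------------------------------------------------
# Pearson r
# ---------------------------------------------------------------------------

def test_pearson_examples(rng):
    x = np.arange(10.0)
    assert S.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert S.pearson_r(x, -x) == pytest.approx(-1.0)
    assert math.isnan(S.pearson_r(x, np.zeros(10)))
    y = rng.normal(0, 1, 30)
    x2 = rng.normal(0, 1, 30)
    brute = (np.mean(x2 * y) - x2.mean() * y.mean()) / (x2.std() * y.std())
    assert S.pearson_r(x2, y) == pytest.approx(brute, abs=1e-12)
    # listwise deletion of undefined pairs
    xx = np.array([1.0, 2, 3, np.nan, 5])
    yy = np.array([2.0, 4, 6, 8, np.nan])
    assert S.pearson_r(xx, yy) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# passive demethylation model
# ---------------------------------------------------------------------------

def test_passive_dilution_bound_is_25_percent():
    """A fully maternally methylated, paternally unmethylated region after
    one replication-dependent demethylation event sits at exactly 25%."""
    m = S.DemethylationModel(m_maternal=1.0, m_paternal=0.0, rounds=1)
    assert S.passive_demethylation_expectation(m) == 25.0


def test_passive_model_no_division_and_monotonicity():
    for level in (0.0, 0.3, 1.0):
        m = S.DemethylationModel(level, level, rounds=0)
        assert S.passive_demethylation_expectation(m) == pytest.approx(100 * level)
    prev = math.inf
    for k in range(6):
        v = S.passive_demethylation_expectation(
            S.DemethylationModel(0.8, 0.4, rounds=k))
        assert v <= prev
        prev = v
    # halving law on the maternal term
    for k in range(4):
        a = S.passive_demethylation_expectation(S.DemethylationModel(1.0, 0.0, k))
        b = S.passive_demethylation_expectation(S.DemethylationModel(1.0, 0.0, k + 1))
        assert b == pytest.approx(a / 2)
    with pytest.raises(ValueError):
        S.DemethylationModel(1.2, 0.0)
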