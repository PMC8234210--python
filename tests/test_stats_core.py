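"""Oracle-backed tests for the self-implemented statistical primitives.

The independent oracles are brute-force permutation enumerations over the
*values* (not the ranks), written here and never shared with the
implementation, plus scipy/statsmodels as external cross-checks.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from nfypipe.stats_core import bh_adjust, jonckheere_test, rank_sum_test

from oracles import brute_force_bh, brute_force_jt, brute_force_ranksum_p


# --- rank-sum ---------------------------------------------------------------

def test_ranksum_two_by_two_exact():
    res = rank_sum_test([1, 2], [3, 4], alternative="two_sided")
    assert res.statistic == 0.0
    assert res.method == "exact"
    assert res.p_value == pytest.approx(1 / 3, abs=1e-12)


def test_ranksum_identical_multisets_p_one():
    res = rank_sum_test([1, 2, 3], [1, 2, 3])
    assert res.p_value == pytest.approx(1.0, abs=0.05)


def test_ranksum_group_swap_symmetry(rng):
    x = rng.normal(size=15)
    y = rng.normal(0.8, size=12)
    assert rank_sum_test(x, y).p_value == pytest.approx(
        rank_sum_test(y, x).p_value, abs=1e-12)


def test_ranksum_degenerate_all_identical():
    res = rank_sum_test([5.0, 5.0], [5.0, 5.0, 5.0])
    assert res.degenerate and res.p_value == 1.0


@pytest.mark.parametrize("alternative", ["two_sided", "less", "greater"])
def test_ranksum_exact_matches_enumeration_all_small_instances(alternative, rng):
    """Every split with pooled n <= 8, distinct values: exact p equals the
    brute-force enumeration exactly."""
    for n1 in range(1, 8):
        for n2 in range(1, 9 - n1):
            values = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = values[:n1], values[n1:]
            res = rank_sum_test(x, y, alternative=alternative)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(
                brute_force_ranksum_p(x, y, alternative), abs=1e-12)


def test_ranksum_normal_matches_scipy_asymptotic(rng):
    x = rng.normal(size=30)
    y = rng.normal(0.4, size=25)
    mine = rank_sum_test(x, y)
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def test_ranksum_normal_with_ties_matches_scipy(rng):
    x = rng.integers(0, 5, size=25).astype(float)
    y = rng.integers(0, 5, size=30).astype(float)
    mine = rank_sum_test(x, y)
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def test_ranksum_exact_vs_normal_agreement_n8(rng):
    """Exact and normal-approximation paths stay within 0.02 at n1=n2=8."""
    for _ in range(20):
        values = rng.permutation(np.arange(1.0, 17.0))
        x, y = values[:8], values[8:]
        p_exact = rank_sum_test(x, y, method="exact").p_value
        p_norm = rank_sum_test(x, y, method="normal").p_value
        assert abs(p_exact - p_norm) <= 0.02


# --- Jonckheere -------------------------------------------------------------

def test_jt_perfectly_ordered_and_reversed():
    up = jonckheere_test([[1, 2], [3, 4], [5, 6]], alternative="increasing")
    assert up.statistic == 12.0  # maximum sum n_i * n_j
    assert up.p_value == pytest.approx(1 / 90, abs=1e-12)
    assert up.method == "exact"
    down = jonckheere_test([[5, 6], [3, 4], [1, 2]], alternative="increasing")
    assert down.statistic == 0.0
    assert down.p_value == pytest.approx(1.0, abs=1e-12)


def test_jt_requires_three_groups():
    with pytest.raises(ValueError):
        jonckheere_test([[1, 2], [3, 4]])


@pytest.mark.parametrize("alternative", ["increasing", "decreasing", "two_sided"])
def test_jt_exact_matches_enumeration_with_ties(alternative):
    groups = [[1.0, 2.0, 2.0], [2.0, 3.0], [3.0, 5.0, 5.0]]
    res = jonckheere_test(groups, alternative=alternative)
    assert res.method == "exact"
    assert res.p_value == pytest.approx(
        brute_force_jt(groups, alternative), abs=1e-12)


def test_jt_normal_close_to_exact_333(rng):
    """Normal approximation within 0.01 of exact enumeration at sizes (3,3,3)."""
    from nfypipe import stats_core

    for _ in range(10):
        values = rng.permutation(np.arange(1.0, 10.0))
        groups = [values[:3], values[3:6], values[6:]]
        exact = jonckheere_test(groups, alternative="increasing")
        assert exact.method == "exact"
        # force the approximation by temporarily lowering the exact cap
        old = stats_core.EXACT_JONCKHEERE_MAX_ARRANGEMENTS
        stats_core.EXACT_JONCKHEERE_MAX_ARRANGEMENTS = 1
        try:
            approx = jonckheere_test(groups, alternative="increasing")
        finally:
            stats_core.EXACT_JONCKHEERE_MAX_ARRANGEMENTS = old
        assert approx.method == "normal_approx"
        assert abs(exact.p_value - approx.p_value) <= 0.01


def test_jt_degenerate_identical_values():
    res = jonckheere_test([[2.0, 2.0], [2.0], [2.0, 2.0]])
    assert res.degenerate and res.p_value == 1.0


# --- Benjamini–Hochberg -----------------------------------------------------

def test_bh_hand_example():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
        [0.04, 0.04, 0.04, 0.04], abs=1e-12)


def test_bh_single_and_degenerate():
    assert bh_adjust([0.37]) == pytest.approx([0.37])
    assert bh_adjust([0.0, 0.0, 0.0]) == pytest.approx([0.0, 0.0, 0.0])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_matches_bruteforce_and_statsmodels(rng):
    for _ in range(50):
        p = rng.random(rng.integers(1, 40))
        q = bh_adjust(p)
        assert q == pytest.approx(brute_force_bh(p), abs=1e-12)
        ref = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx(ref, abs=1e-10)


def test_bh_never_below_raw_p_and_monotone(rng):
    p = rng.random(200)
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)
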