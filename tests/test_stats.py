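"""Oracle-equivalence and property tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from spongenet.stats import (
    ConstantVectorError,
    P_FLOOR,
    bh_fdr,
    fisher_share_test,
    fishers_method,
    mann_whitney_two_tailed,
    pearson_one_tailed,
)


def hypergeom_upper_tail(k, m, n, N):
    """Brute-force P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = 0
    for j in range(k, min(m, n) + 1):
        total += math.comb(n, j) * math.comb(N - n, m - j)
    return total / math.comb(N, m)


def bh_oracle(p):
    """Literal step-up definition: q_i = min_{j >= rank(i)} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(1.0, running)
    return q


class TestFisherShare:
    def test_zero_shared_gives_p_one(self):
        assert fisher_share_test(0, 8, 10, 20).p_value == 1.0

    def test_worked_enumeration_example(self):
        # N=20, m=8, n=10, k=7: (C(10,7)C(10,1) + C(10,8)C(10,0)) / C(20,8)
        res = fisher_share_test(7, 8, 10, 20)
        assert res.p_value == pytest.approx(1245 / 125970, abs=1e-15)
        assert res.statistic == 7

    def test_matches_enumeration_on_all_small_tables(self):
        for N in range(2, 13):
            for m in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(m, n) + 1):
                        expected = hypergeom_upper_tail(k, m, n, N) if k > 0 else 1.0
                        got = fisher_share_test(k, m, n, N).p_value
                        assert got == pytest.approx(min(1.0, expected), abs=1e-12)

    def test_bound_violation_raises(self):
        with pytest.raises(ValueError):
            fisher_share_test(5, 3, 10, 20)
        with pytest.raises(ValueError):
            fisher_share_test(1, 3, 25, 20)


class TestPearsonOneTailed:
    def test_perfect_correlation_floors_p(self):
        x = np.arange(10.0)
        res = pearson_one_tailed(x, x)
        assert res.statistic == pytest.approx(1.0)
        assert 0 < res.p_value <= 1e-200

    def test_worked_example_r09(self):
        res = pearson_one_tailed([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert res.statistic == pytest.approx(0.9, abs=1e-12)
        # t = 0.9 * sqrt(3 / 0.19) on 3 df
        t = 0.9 * math.sqrt(3 / (1 - 0.81))
        assert res.p_value == pytest.approx(float(sps.t.sf(t, 3)), abs=1e-12)
        assert res.p_value == pytest.approx(0.019, abs=2e-3)

    def test_permutation_null_agrees_for_small_example(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 2, 3, 5, 4])
        r_obs = pearson_one_tailed(x, y).statistic
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            r = np.corrcoef(x, perm)[0, 1]
            count += r >= r_obs - 1e-12
            total += 1
        # the permutation null at n=5 is coarse (120 atoms), so the
        # parametric tail can only agree loosely
        assert pearson_one_tailed(x, y).p_value == pytest.approx(count / total, abs=0.03)

    def test_anticorrelation_one_sided(self):
        x = np.arange(10.0)
        res = pearson_one_tailed(x, -x)
        assert res.statistic == pytest.approx(-1.0)
        assert res.p_value > 0.999

    def test_matches_scipy_greater_alternative(self, rng):
        for _ in range(20):
            x = rng.standard_normal(15)
            y = rng.standard_normal(15)
            ours = pearson_one_tailed(x, y)
            ref = sps.pearsonr(x, y, alternative="greater")
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_is_signalled(self):
        with pytest.raises(ConstantVectorError):
            pearson_one_tailed([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestFishersMethod:
    def test_identity_case(self):
        chi2, p = fishers_method(1.0, 1.0)
        assert chi2 == 0.0
        assert p == 1.0

    def test_worked_example(self):
        chi2, p = fishers_method(0.01, 0.02)
        assert chi2 == pytest.approx(-2 * (math.log(0.01) + math.log(0.02)), abs=1e-12)
        assert chi2 == pytest.approx(17.0344, abs=1e-4)
        assert p == pytest.approx(1.90e-3, rel=5e-3)

    def test_closed_form_equals_chi2_df4_tail(self):
        for p1 in (1e-8, 1e-3, 0.04, 0.3, 0.77, 1.0):
            for p2 in (1e-6, 0.02, 0.5, 1.0):
                chi2, p = fishers_method(p1, p2)
                assert p == pytest.approx(float(sps.chi2.sf(chi2, 4)), abs=1e-12)

    def test_monotone_in_each_argument(self):
        grid = [0.001, 0.01, 0.1, 0.5, 0.9, 1.0]
        for p2 in grid:
            ps = [fishers_method(p1, p2)[1] for p1 in grid]
            assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            fishers_method(0.0, 0.5)


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03, abs=1e-15)

    def test_hand_computed_stepup(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5], abs=1e-12)

    def test_matches_literal_oracle_on_random_vectors(self, rng):
        for _ in range(25):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            assert bh_fdr(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_q_dominates_p_and_preserves_order(self, rng):
        p = rng.uniform(1e-6, 1.0, size=30)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(np.sign(np.diff(q[np.argsort(p)])) >= 0)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=50))
    def test_stepup_properties_hold_for_arbitrary_vectors(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        assert q == pytest.approx(bh_oracle(p), abs=1e-12)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_complete_separation_exact(self):
        res = mann_whitney_two_tailed([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_exact_path_equals_label_enumeration(self, rng):
        pooled = rng.standard_normal(8) * 3
        a, b = pooled[:4], pooled[4:]
        res = mann_whitney_two_tailed(a, b)

        def u_stat(x, y):
            return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)

        u_obs = u_stat(a, b)
        mean_u = len(a) * len(b) / 2
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            x = pooled[list(idx)]
            y = pooled[[i for i in range(8) if i not in idx]]
            u = u_stat(x, y)
            count += abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_exact_and_asymptotic_agree_at_n9(self, rng):
        for _ in range(10):
            a = rng.standard_normal(9)
            b = rng.standard_normal(9) + 0.5
            exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            approx = mann_whitney_two_tailed(a, b).p_value  # n=9 -> asymptotic path
            assert approx == pytest.approx(exact, abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_two_tailed([], [1.0])


def test_all_p_values_positive():
    """No primitive ever reports a p-value of exactly zero."""
    assert P_FLOOR > 0
    x = np.arange(50.0)
    assert pearson_one_tailed(x, x).p_value >= P_FLOOR
    assert fishers_method(P_FLOOR, P_FLOOR)[1] >= P_FLOOR
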