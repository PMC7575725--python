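"""Statistical primitives against closed forms and enumeration oracles."""

import math
from fractions import Fraction
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from cernascreen import (
    HypergeomParams,
    benjamini_hochberg,
    correlation_p,
    hypergeom_upper_tail,
    pearson_r,
    two_sample_t,
)
from cernascreen.errors import InvalidInputError, ZeroVarianceError


def hypergeom_tail_oracle(N, K, n, k):
    """Exact P(X >= k) by rational enumeration of the PMF."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(total)


def bh_oracle(p):
    """Direct step-up formula: q_(i) = min_{j>=i}(p_(j) * m / j), capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestTwoSampleT:
    def test_identical_groups_give_zero_statistic_and_p_one(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_pooled_matches_closed_form_df2(self):
        # closed-form survival at df=2: p = 1 - |t|/sqrt(2 + t^2)
        res = two_sample_t([1.0, 1.2], [2.0, 2.2], variant="pooled")
        assert res.statistic == pytest.approx(-7.0711, abs=1e-4)
        assert res.df == 2
        assert res.p == pytest.approx(1 - 7.0711 / math.sqrt(2 + 7.0711**2), rel=1e-4)
        assert res.p == pytest.approx(0.01942, abs=1e-5)

    def test_swapping_groups_negates_statistic_keeps_p(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 8)
        a, b = two_sample_t(x, y), two_sample_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_degenerate_equal_constants_flagged_p_one(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0 and res.degenerate

    def test_too_few_observations_rejected(self):
        with pytest.raises(InvalidInputError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_welch_df_below_pooled_under_unequal_variance(self):
        x = [0.0, 0.1, -0.1, 0.05]
        y = [0.0, 5.0, -5.0, 2.0]
        assert two_sample_t(x, y, "welch").df < two_sample_t(x, y, "pooled").df


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_r([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / math.sqrt(84))

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=12),
        st.floats(0.1, 5.0),
        st.floats(-10, 10),
    )
    def test_affine_invariance(self, x, a, b):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, len(x))
        x = np.asarray(x)
        if np.var(x) == 0 or np.var(y) == 0:
            return
        assert pearson_r(x, a * y + b) == pytest.approx(pearson_r(x, y), abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationP:
    def test_zero_correlation_gives_p_one(self):
        assert correlation_p(0.0, 10) == pytest.approx(1.0)

    def test_df1_closed_form(self):
        # at df=1 the two-sided p is 1 - (2/pi) * arctan(|t|)
        r = 9 / math.sqrt(84)
        t = r * math.sqrt(1) / math.sqrt(1 - r**2)
        assert t == pytest.approx(5.196, abs=1e-3)
        assert correlation_p(r, 3) == pytest.approx(1 - (2 / math.pi) * math.atan(t), rel=1e-10)
        assert correlation_p(r, 3) == pytest.approx(0.121, abs=5e-4)

    def test_perfect_correlation_degenerate(self):
        with pytest.warns(RuntimeWarning):
            assert correlation_p(1.0, 5) == 0.0

    def test_agrees_with_independent_t_transform_on_random_pairs(self):
        # the r -> p transform must equal a two-sample-style t survival
        # computed independently from scipy's t distribution
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
            r = pearson_r(x, y)
            t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
            expected = 2 * sps.t.sf(abs(t), n - 2)
            assert correlation_p(r, n) == pytest.approx(expected, rel=1e-12)


class TestHypergeomUpperTail:
    def test_k_zero_is_exactly_one(self):
        assert hypergeom_upper_tail(HypergeomParams(N=50, K=10, n=7, k=0)) == 1.0

    @pytest.mark.parametrize(
        "params,expected",
        [
            ((10, 5, 4, 4), 5 / 210),
            ((10, 5, 4, 3), 55 / 210),
        ],
    )
    def test_enumeration_examples(self, params, expected):
        N, K, n, k = params
        assert hypergeom_upper_tail(HypergeomParams(N, K, n, k)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_enumeration_oracle_on_random_grid(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            N = int(rng.integers(1, 30))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            got = hypergeom_upper_tail(HypergeomParams(N, K, n, k))
            assert got == pytest.approx(hypergeom_tail_oracle(N, K, n, k), rel=1e-10)

    def test_non_increasing_in_k(self):
        N, K, n = 40, 12, 15
        tails = [
            hypergeom_upper_tail(HypergeomParams(N, K, n, k))
            for k in range(min(K, n) + 1)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_stable_for_large_universe(self):
        # log-gamma arithmetic must agree with scipy's survival function
        # far beyond factorial overflow range
        params = HypergeomParams(N=100_000, K=300, n=250, k=5)
        expected = sps.hypergeom.sf(params.k - 1, params.N, params.K, params.n)
        got = hypergeom_upper_tail(params)
        assert math.isfinite(got)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            HypergeomParams(N=10, K=11, n=2, k=1)
        with pytest.raises(InvalidInputError):
            HypergeomParams(N=10, K=5, n=4, k=5)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.123])[0] == pytest.approx(0.123)

    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.005, 0.04, 0.9], [0.015, 0.06, 0.9]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert benjamini_hochberg(p) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_matches_direct_oracle_and_order_invariant(self, p):
        p = np.asarray(p)
        expected = bh_oracle(p)
        assert benjamini_hochberg(p) == pytest.approx(expected, rel=1e-12)
        for perm in list(permutations(range(len(p))))[:24]:
            perm = list(perm)
            got = benjamini_hochberg(p[perm])
            assert got == pytest.approx(expected[perm], rel=1e-12)

    def test_missing_entries_excluded_and_restored(self):
        q = benjamini_hochberg([0.005, np.nan, 0.04, 0.9])
        assert np.isnan(q[1])
        assert q[[0, 2, 3]] == pytest.approx([0.015, 0.06, 0.9])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            benjamini_hochberg([0.5, 1.2])
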