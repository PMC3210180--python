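"""Statistical kernels against independent oracles and closed forms."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from chromenh.stats import (
    TestResult,
    chi2_gof,
    hypergeom_left,
    oneway_anova,
    poisson_sf,
    spearman_rho,
    spearman_significance,
    wilcoxon_signed_rank,
)


class TestSpearman:
    def test_identity_permutation(self):
        assert spearman_rho([3, 1, 2], [3, 1, 2]) == pytest.approx(1.0)

    def test_tied_example_equals_closed_form(self):
        # mid-rank Pearson of (1..5) vs ranks of (5,6,7,8,7) gives 8/sqrt(95)
        rho = spearman_rho([1, 2, 3, 4, 5], [5, 6, 7, 8, 7])
        assert rho == pytest.approx(8 / math.sqrt(95), abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert math.isnan(spearman_rho([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_matches_scipy_on_tie_heavy_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 4, n).astype(float)  # heavy ties, like bin counts
            y = rng.integers(0, 4, n).astype(float)
            ours = spearman_rho(x, y)
            ref = sps.spearmanr(x, y).statistic
            if math.isnan(ours):
                assert math.isnan(ref)
            else:
                assert ours == pytest.approx(ref, abs=1e-12)

    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=25),
        st.randoms(use_true_random=False),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_symmetry_and_sign_flip(self, xs, rand):
        ys = list(xs)
        rand.shuffle(ys)
        a = spearman_rho(xs, ys)
        b = spearman_rho(ys, xs)
        if not math.isnan(a):
            assert a == pytest.approx(b, abs=1e-12)
            neg = spearman_rho(xs, [-v for v in ys])
            assert a == pytest.approx(-neg, abs=1e-12)
            assert -1.0 <= a <= 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert spearman_rho(x, y) == pytest.approx(
            spearman_rho(np.exp(x), y**3), abs=1e-12
        )


class TestSpearmanSignificance:
    def test_zero_rho(self):
        res = spearman_significance(0.0, 100)
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_published_cutoff_magnitude(self):
        # rho = 0.5 with n = 98 bins gives t = 0.5 sqrt(96/0.75) ~ 5.657
        res = spearman_significance(0.5, 98)
        assert res.statistic == pytest.approx(0.5 * math.sqrt(96 / 0.75), rel=1e-12)
        assert res.statistic == pytest.approx(5.657, abs=1e-3)
        # the corresponding two-tailed p is of order 1e-7
        assert 1e-8 < res.pvalue < 1e-6

    def test_small_n_arithmetic(self):
        res = spearman_significance(0.9, 5)
        assert res.statistic == pytest.approx(0.9 * math.sqrt(3 / 0.19), rel=1e-12)

    def test_perfect_correlation_convention(self):
        res = spearman_significance(1.0, 10)
        assert math.isinf(res.statistic) and res.pvalue == 0.0


class TestPoissonTail:
    def test_k_zero_is_one(self):
        assert poisson_sf(0, 0.001) == 1.0
        assert poisson_sf(0, 1e6) == 1.0

    def test_partial_sum_example(self):
        # 1 - e^-1 (1 + 1 + 1/2 + 1/6 + 1/24) = 1 - e^-1 * 65/24
        assert poisson_sf(5, 1.0) == pytest.approx(1 - math.exp(-1) * 65 / 24,
                                                   rel=1e-12)

    def test_matches_partial_sums(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            mean = float(rng.uniform(0.01, 50))
            k = int(rng.integers(0, 80))
            acc = sum(
                math.exp(-mean + j * math.log(mean) - math.lgamma(j + 1))
                for j in range(k)
            )
            assert poisson_sf(k, mean) == pytest.approx(1 - acc, abs=1e-10)

    def test_monotone_in_k(self):
        for mean in (0.5, 3.0, 40.0):
            vals = [poisson_sf(k, mean) for k in range(30)]
            assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            poisson_sf(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_sf(0, 0.0)


class TestHypergeom:
    def test_closed_form_example(self):
        # P(X = 0) drawing 5 from 10 with 5 marked = C(5,5)/C(10,5) = 1/252
        assert hypergeom_left(10, 5, 5, 0) == pytest.approx(1 / 252, rel=1e-12)

    def test_full_draw_is_certain(self):
        assert hypergeom_left(20, 7, 6, 6) == 1.0

    def test_small_enumeration(self):
        for N, K, n in [(8, 3, 4), (12, 6, 5), (15, 2, 9)]:
            denom = math.comb(N, n)
            cum = 0
            for k in range(n + 1):
                cum += math.comb(K, k) * math.comb(N - K, n - k)
                assert hypergeom_left(N, K, n, k) == pytest.approx(
                    cum / denom, abs=1e-12
                )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            hypergeom_left(5, 6, 2, 1)
        with pytest.raises(ValueError):
            hypergeom_left(5, 2, 3, 4)


def _brute_force_signed_rank(pairs):
    """Oracle: exact two-tailed p by enumerating every sign pattern."""
    d = [a - b for a, b in pairs if a != b]
    ranks = sps.rankdata([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    total = len(ws)
    lower = sum(1 for w in ws if w <= w_obs + 1e-9) / total
    upper = sum(1 for w in ws if w >= w_obs - 1e-9) / total
    return w_obs, min(1.0, 2 * min(lower, upper))


class TestWilcoxon:
    def test_example_statistic_and_exact_p(self):
        pairs = [(1, 0), (0, 2), (3, 0)]  # differences 1, -2, 3
        res = wilcoxon_signed_rank(pairs)
        w_ref, p_ref = _brute_force_signed_rank(pairs)
        assert res.statistic == 4.0 == w_ref
        assert res.pvalue == pytest.approx(p_ref, abs=1e-12)

    def test_all_positive_is_maximal(self):
        res = wilcoxon_signed_rank([(1, 0), (2, 0), (3, 0)])
        assert res.statistic == 6.0

    def test_pair_order_irrelevant(self):
        pairs = [(5, 1), (2, 4), (3, 3), (9, 2), (1, 1.5)]
        res1 = wilcoxon_signed_rank(pairs)
        res2 = wilcoxon_signed_rank(list(reversed(pairs)))
        assert (res1.statistic, res1.pvalue) == (res2.statistic, res2.pvalue)

    def test_all_ties_undefined(self):
        res = wilcoxon_signed_rank([(1, 1), (2, 2)])
        assert math.isnan(res.statistic) and math.isnan(res.pvalue)

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(2, 10))
            a = rng.integers(0, 4, n).astype(float)
            b = rng.integers(0, 4, n).astype(float)
            if np.all(a == b):
                continue
            res = wilcoxon_signed_rank(list(zip(a, b)))
            w_ref, p_ref = _brute_force_signed_rank(list(zip(a, b)))
            assert res.statistic == pytest.approx(w_ref)
            assert res.pvalue == pytest.approx(p_ref, abs=1e-12)

    def test_large_sample_near_scipy_normal_approx(self):
        rng = np.random.default_rng(11)
        a = rng.normal(1.0, 2.0, 60)
        b = rng.normal(0.0, 2.0, 60)
        res = wilcoxon_signed_rank(list(zip(a, b)))
        ref = sps.wilcoxon(a, b, correction=False, method="approx",
                           alternative="two-sided")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


class TestAnova:
    def test_identical_groups(self):
        res = oneway_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
        res = oneway_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.pvalue == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(size=6), rng.normal(size=8), rng.normal(size=5)]
        res = oneway_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-12)

    def test_null_pvalues_uniform(self):
        """Seeded simulation: null p-values pass a KS uniformity check."""
        rng = np.random.default_rng(12345)
        nsim, n = 3000, 6
        a = rng.normal(size=(nsim, n))
        b = rng.normal(size=(nsim, n))
        grand = (a.sum(1) + b.sum(1)) / (2 * n)
        ssb = n * ((a.mean(1) - grand) ** 2 + (b.mean(1) - grand) ** 2)
        ssw = ((a - a.mean(1, keepdims=True)) ** 2).sum(1) + (
            (b - b.mean(1, keepdims=True)) ** 2
        ).sum(1)
        f = (ssb / 1) / (ssw / (2 * n - 2))
        pvals = sps.f.sf(f, 1, 2 * n - 2)
        # spot-check the vectorized oracle against the implementation
        res = oneway_anova([a[0], b[0]])
        assert res.pvalue == pytest.approx(pvals[0], rel=1e-10)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_all_identical(self):
        res = oneway_anova([[2.0, 2.0], [2.0, 2.0]])
        assert math.isnan(res.statistic)


class TestChi2:
    def test_perfect_fit(self):
        res = chi2_gof([5, 5, 5], [5, 5, 5])
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_six_cells_df_five(self):
        res = chi2_gof([10, 20, 30, 5, 5, 30], [20, 20, 20, 10, 10, 20])
        assert res.df == 5
        ref = sps.chisquare([10, 20, 30, 5, 5, 30], [20, 20, 20, 10, 10, 20])
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-12)

    def test_two_cells_equal_binomial_z_squared(self):
        obs, exp = [30.0, 70.0], [50.0, 50.0]
        res = chi2_gof(obs, exp)
        z = (30 - 50) / math.sqrt(100 * 0.5 * 0.5)
        assert res.statistic == pytest.approx(z**2, rel=1e-12)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            chi2_gof([1, 2], [0, 3])


def test_testresult_validates_pvalue():
    with pytest.raises(ValueError):
        TestResult(1.0, 1.5)
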