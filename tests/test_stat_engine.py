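"""Fisher CMLE, Mann-Whitney, size-corrected regression, resampling null."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from constraintscope.stat_engine import (
    fisher_exact_cmle,
    fisher_exact_p,
    mann_whitney_u,
    resampling_null,
    size_corrected_regression,
)


def brute_force_fisher_p(a, b, c, d):
    """Exact-arithmetic two-sided Fisher p: enumerate the conditional support
    with rational hypergeometric probabilities and sum those <= observed."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, r1)
    pmf = [Fraction(math.comb(c1, x) * math.comb(n - c1, r1 - x), denom) for x in range(lo, hi + 1)]
    return float(min(sum(p for p in pmf if p <= pmf[a - lo]), Fraction(1)))


class TestFisherCMLE:
    @pytest.mark.parametrize(
        "table, or_printed, ci_printed",
        [
            ((34, 19, 2, 21), 18.1, (3.8, 175.4)),
            ((34, 19, 4, 5), 2.2, (0.4, 12.5)),
            ((7, 4567, 31, 125533), 6.2, (2.3, 14.3)),
            ((5, 121, 34, 124666), 151.3, (45.5, 397.6)),
        ],
    )
    def test_published_carrier_tables(self, table, or_printed, ci_printed):
        """Conditional-MLE odds ratios and exact CIs match published values."""
        res = fisher_exact_cmle(*table)
        assert round(res.odds_ratio, 1) == or_printed
        assert res.ci_lower == pytest.approx(ci_printed[0], abs=0.1)
        assert res.ci_upper == pytest.approx(ci_printed[1], abs=0.1)
        assert res.ci_lower <= res.odds_ratio <= res.ci_upper

    def test_symmetric_table(self):
        res = fisher_exact_cmle(1, 1, 1, 1)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_degenerate_cells_give_sentinels(self):
        res = fisher_exact_cmle(0, 10, 5, 5)
        assert res.odds_ratio == 0.0 and res.ci_lower == 0.0
        res = fisher_exact_cmle(5, 0, 3, 7)
        assert math.isinf(res.ci_upper)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_cmle(-1, 2, 3, 4)

    @pytest.mark.parametrize("table", [(3, 7, 9, 2), (12, 5, 8, 30), (1, 19, 4, 16)])
    def test_transpose_and_group_swap_invariance(self, table):
        a, b, c, d = table
        orig = fisher_exact_cmle(a, b, c, d)
        transposed = fisher_exact_cmle(a, c, b, d)
        swapped = fisher_exact_cmle(c, d, a, b)
        assert transposed.odds_ratio == pytest.approx(orig.odds_ratio, rel=1e-3)
        assert swapped.odds_ratio == pytest.approx(1.0 / orig.odds_ratio, rel=1e-3)
        assert swapped.p_two_sided == pytest.approx(orig.p_two_sided, rel=1e-9)

    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    @settings(max_examples=150, deadline=None)
    def test_p_matches_exact_enumeration(self, a, b, c, d):
        assert fisher_exact_p(a, b, c, d) == pytest.approx(brute_force_fisher_p(a, b, c, d), abs=1e-10)

    @pytest.mark.parametrize("table", [(8, 2, 1, 5), (34, 19, 2, 21), (3, 3, 3, 3)])
    def test_agrees_with_scipy_cross_checks(self, table):
        """Independent library route: scipy's exact p and conditional OR.

        scipy inverts the one-sided tests to machine precision, so its CI
        endpoints can differ from the R-convention ones in the flat region;
        the point estimate and p-value must agree tightly.
        """
        res = fisher_exact_cmle(*table)
        assert res.p_two_sided == pytest.approx(
            sps.fisher_exact([table[:2], table[2:]]).pvalue, rel=1e-9
        )
        orr = sps.contingency.odds_ratio([table[:2], table[2:]], kind="conditional")
        assert res.odds_ratio == pytest.approx(orr.statistic, rel=2e-3)


class TestMannWhitney:
    def test_exact_small_sample(self):
        """All 6 rank assignments of 2+2 values: the extreme split has p = 2/6."""
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_constant_samples(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_identical_distributions(self):
        x = np.arange(10.0)
        _, p = mann_whitney_u(x, x)
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, data):
        xs = data.draw(st.lists(st.floats(-50, 50), min_size=3, max_size=20, unique=True))
        ys = data.draw(st.lists(st.floats(-50, 50), min_size=3, max_size=20, unique=True))
        u1, p1 = mann_whitney_u(xs, ys)
        f = lambda v: np.expm1(np.asarray(v) / 25.0)  # strictly increasing
        u2, p2 = mann_whitney_u(f(xs), f(ys))
        assert u1 == u2
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestSizeCorrectedRegression:
    def test_exact_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        group = rng.integers(0, 2, 60)
        length = rng.integers(300, 9000, 60)
        values = 0.5 - 0.3 * group + 0.0 * length
        res = size_corrected_regression(values, group, length)
        assert res.coefficient == pytest.approx(-0.3, abs=1e-10)
        assert res.p_group < 1e-12
        assert abs(res.r) <= 1.0

    def test_simulated_parameter_recovery(self):
        """Planted group effect -0.4 with a real length effect and noise 0.1."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            group = rng.integers(0, 2, 200)
            length = rng.lognormal(np.log(1500), 0.6, 200)
            values = 0.9 - 0.4 * group - 5e-5 * length + rng.normal(0, 0.1, 200)
            res = size_corrected_regression(values, group, length)
            assert res.coefficient == pytest.approx(-0.4, abs=0.05)

    def test_null_p_values_uniform(self):
        """With permuted labels the group p-value is Uniform(0, 1)."""
        rng = np.random.default_rng(7)
        length = rng.lognormal(np.log(1500), 0.6, 120)
        values = 0.8 - 4e-5 * length + rng.normal(0, 0.1, 120)
        group = np.repeat([0, 1], 60)
        pvals = []
        for _ in range(500):
            pvals.append(size_corrected_regression(values, rng.permutation(group), length).p_group)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_design_named(self):
        with pytest.raises(ValueError, match="cds_length"):
            size_corrected_regression([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1], [500, 500, 500, 500])
        with pytest.raises(ValueError, match="group"):
            size_corrected_regression([1.0, 2.0, 3.0], [1, 1, 1], [100, 200, 300])


class TestResamplingNull:
    def test_matches_exhaustive_enumeration(self):
        """Pool of 5, k=2: null means hit all C(5,2)=10 subset means uniformly."""
        values = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        expected_means = sorted(np.mean(pair) for pair in itertools.combinations(values, 2))
        null = resampling_null(values, k=2, iterations=20_000, observed=0.0, seed=3)
        seen, counts = np.unique(np.round(null.null_values, 9), return_counts=True)
        assert list(seen) == pytest.approx(expected_means)
        # uniform occupancy of the 10 subsets within sampling error
        assert sps.chisquare(counts).pvalue > 0.001

    def test_add_one_rule_never_zero(self):
        values = np.linspace(1, 2, 50)
        null = resampling_null(values, k=5, iterations=999, observed=0.0, seed=0)
        assert null.empirical_p == pytest.approx(1.0 / 1000.0)
        assert null.empirical_p > 0

    def test_p_monotone_in_observed(self):
        values = np.linspace(0, 1, 60)
        ps = [
            resampling_null(values, k=10, iterations=2000, observed=obs, seed=1).empirical_p
            for obs in (0.2, 0.4, 0.6)
        ]
        assert ps[0] <= ps[1] <= ps[2]

    def test_reproducible_and_seed_sensitive(self):
        values = np.linspace(0, 1, 40)
        n1 = resampling_null(values, k=6, iterations=500, observed=0.5, seed=9)
        n2 = resampling_null(values, k=6, iterations=500, observed=0.5, seed=9)
        n3 = resampling_null(values, k=6, iterations=500, observed=0.5, seed=10)
        assert np.array_equal(n1.null_values, n2.null_values)
        assert not np.array_equal(n1.null_values, n3.null_values)

    def test_self_consistent_null(self):
        """Observations drawn from the null itself give uniform empirical p."""
        rng = np.random.default_rng(21)
        values = rng.normal(0, 1, 80)
        ps = []
        for rep in range(150):
            obs = values[rng.choice(80, 8, replace=False)].mean()
            ps.append(resampling_null(values, k=8, iterations=400, observed=obs, seed=rep).empirical_p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_k_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            resampling_null([1.0, 2.0], k=3, iterations=10, observed=1.0, seed=0)
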