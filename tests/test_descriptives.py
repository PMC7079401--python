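import itertools
import math

import numpy as np
import pytest
from scipy import stats

from stressproc.descriptives import (
    ContingencyTable,
    choose_test,
    crude_association,
    fisher_exact,
    inflate_for_attrition,
    pearson_chi_square,
    prevalence,
    sample_size_two_proportions,
    summarize_numeric,
)


def table(rows):
    return ContingencyTable(np.array(rows))


class TestPearson:
    def test_no_association_gives_zero(self):
        res = pearson_chi_square(table([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_formula_2x2(self):
        # margins 30/30 x 30/30: every expected count 15, four cells (5)^2/15
        res = pearson_chi_square(table([[20, 10], [10, 20]]))
        assert res.statistic == pytest.approx(4 * 25 / 15)
        assert res.df == 1

    def test_matches_scipy_without_correction(self, rng):
        counts = rng.integers(5, 80, size=(3, 4))
        res = pearson_chi_square(table(counts))
        ref = stats.chi2_contingency(counts, correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == 6

    def test_permutation_invariance(self):
        t1 = table([[16, 323], [47, 530]])
        t2 = table([[530, 47], [323, 16]])
        assert pearson_chi_square(t1).statistic == pytest.approx(
            pearson_chi_square(t2).statistic
        )

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square(table([[0, 0], [5, 5]]))


class TestFisher:
    def test_diagonal_three_by_three(self):
        # C(6,3) = 20 arrangements; point probabilities .05/.45/.45/.05
        assert fisher_exact(table([[3, 0], [0, 3]])).p_value == pytest.approx(0.10)

    def test_zero_margin_single_table(self):
        assert fisher_exact(table([[0, 0], [5, 3]])).p_value == 1.0

    @pytest.mark.parametrize(
        "counts", [[[2, 7], [8, 2]], [[1, 9], [11, 3]], [[13, 50], [25, 828]], [[5, 5], [5, 5]]]
    )
    def test_matches_scipy_2x2(self, counts):
        ours = fisher_exact(table(counts)).p_value
        ref = stats.fisher_exact(counts).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_food_access_table_significant(self):
        assert fisher_exact(table([[13, 50], [25, 828]])).p_value <= 0.001

    def test_hypergeometric_closed_form_2x2(self, rng):
        # the enumeration must reproduce the closed-form conditional null
        for _ in range(20):
            a, b, c, d = rng.integers(0, 12, size=4) + [1, 0, 0, 1]
            counts = np.array([[a, b], [c, d]])
            n, r0, c0 = counts.sum(), a + b, a + c
            probs = [
                math.comb(r0, x) * math.comb(n - r0, c0 - x) / math.comb(n, c0)
                for x in range(max(0, c0 - (n - r0)), min(r0, c0) + 1)
            ]
            obs = math.comb(r0, a) * math.comb(n - r0, c0 - a) / math.comb(n, c0)
            expected = sum(p for p in probs if p <= obs * (1 + 1e-12))
            assert fisher_exact(table(counts)).p_value == pytest.approx(expected)

    def test_two_by_three_against_enumeration(self):
        counts = np.array([[2, 3, 1], [5, 1, 6]])
        row, col = counts.sum(1), counts.sum(0)
        n = counts.sum()

        # independent brute force over all first rows via multivariate
        # hypergeometric probabilities
        def mvh_prob(top):
            bottom = col - np.array(top)
            if (bottom < 0).any() or sum(top) != row[0]:
                return 0.0
            num = math.prod(math.comb(c, t) for c, t in zip(col, top))
            return num / math.comb(n, row[0])

        all_tops = [
            t for t in itertools.product(*(range(c + 1) for c in col))
            if sum(t) == row[0]
        ]
        obs = mvh_prob(tuple(counts[0]))
        expected = sum(p for t in all_tops if (p := mvh_prob(t)) <= obs * (1 + 1e-12))
        assert fisher_exact(table(counts)).p_value == pytest.approx(expected)


class TestChooseTest:
    def test_small_expected_counts_pick_fisher(self):
        # margins 38/878 x 63/853: min expected 38*63/916 = 2.61
        assert choose_test(table([[13, 25], [50, 828]])) == "fisher_exact"

    def test_large_expected_counts_pick_pearson(self):
        assert choose_test(table([[16, 323], [47, 530]])) == "pearson_chi2"
        assert choose_test(table([[100, 100], [100, 100]])) == "pearson_chi2"

    def test_crude_association_dispatch(self):
        res = crude_association(table([[13, 50], [25, 828]]))
        assert res.method == "fisher_exact"


class TestPrevalence:
    def test_study_prevalence_block(self):
        assert prevalence(63, 916).as_percent() == (6.9, 5.3, 8.7)

    def test_zero_numerator_boundary(self):
        est = prevalence(0, 50)
        assert est.ci_low == 0.0 and est.proportion == 0.0
        assert prevalence(50, 50).ci_high == 1.0

    def test_interval_inverts_binomial_tails(self):
        # equal-tailed exact test inversion: at the bounds the binomial
        # tail probabilities equal alpha/2
        est = prevalence(5, 10)
        assert stats.binom.sf(4, 10, est.ci_low) == pytest.approx(0.025, abs=1e-9)
        assert stats.binom.cdf(5, 10, est.ci_high) == pytest.approx(0.025, abs=1e-9)

    def test_ordering_invariant(self):
        est = prevalence(7, 916)
        assert 0 <= est.ci_low <= est.proportion <= est.ci_high <= 1

    def test_exact_rational_proportion(self):
        assert prevalence(63, 916).proportion == 63 / 916

    def test_coverage_at_study_size(self, rng):
        # nominal-or-better coverage of the exact interval, p = .07, n = 916
        p, n, draws = 0.07, 916, 10_000
        ks = rng.binomial(n, p, size=draws)
        low = np.where(ks == 0, 0.0, stats.beta.ppf(0.025, ks, n - ks + 1))
        high = np.where(ks == n, 1.0, stats.beta.ppf(0.975, ks + 1, n - ks))
        assert np.mean((low <= p) & (p <= high)) >= 0.95

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            prevalence(5, 4)


class TestSummaries:
    def test_basic(self):
        s = summarize_numeric([1, 2, 3])
        assert s["mean"] == 2 and s["median"] == 2

    def test_constant_sd_zero(self):
        assert summarize_numeric([4.0] * 9)["sd"] == 0.0

    def test_six_value_quartiles(self):
        # order statistics of (1, 2, 4, 7, 11, 16): linear-interpolation
        # quartiles q1 = 2.5, median = 5.5, q3 = 10
        s = summarize_numeric([7, 1, 16, 2, 11, 4])
        assert s["q1"] == pytest.approx(2.5)
        assert s["median"] == pytest.approx(5.5)
        assert s["q3"] == pytest.approx(10.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_numeric([])


class TestSampleSize:
    def test_equal_proportions_signal(self):
        with pytest.raises(ValueError):
            sample_size_two_proportions(0.05, 0.9, 2, 0.25, 1.0)

    def test_matches_independent_power_calculation(self):
        # frozen from R stats::power.prop.test(p1=.375, p2=.25, power=.9):
        # 286.871 per group without continuity correction
        res = sample_size_two_proportions(
            0.05, 0.9, 1.0, 0.25, 1.5, continuity_correction=False
        )
        assert res["n_exposed"] == 287 == res["n_unexposed"]

    def test_study_parameterization_documented(self):
        # the study's stated inputs (alpha .05, power .90, 1:2 allocation,
        # p0 = .25, risk ratio 1.5) under the Fleiss rule with continuity
        # correction; the allocation doubles the unexposed group
        res = sample_size_two_proportions(0.05, 0.9, 2.0, 0.25, 1.5)
        assert res["n_unexposed"] == pytest.approx(2 * res["n_exposed"], abs=2)
        assert res["n_total"] == res["n_exposed"] + res["n_unexposed"]

    def test_attrition_inflation(self):
        assert inflate_for_attrition(809, 0.20) == math.ceil(809 * 1.2)
        with pytest.raises(ValueError):
            inflate_for_attrition(100, 1.0)
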