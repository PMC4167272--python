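"""Agreement statistics against hand computations and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dwcmr import (
    Contingency2x2,
    bland_altman,
    bonferroni_alpha,
    cohens_kappa,
    contingency,
    diagnostic_metrics,
    icc,
    pearson_r2,
    percent_agreement,
    wilcoxon_signed_rank,
)

# The four cross-tabulations of the worked example (two reviewers x two
# classifiers, 176 pooled AHA segments) with their published statistics.
WORKED_TABLES = [
    ((51, 1, 4, 120), 0.93, 171),
    ((52, 7, 8, 109), 0.81, 161),
    ((45, 2, 2, 127), 0.94, 172),
    ((53, 6, 9, 108), 0.81, 161),
]


def icc21_anova(x, y):
    """Brute-force two-way ANOVA ICC(2,1) (Shrout-Fleiss), independent of pingouin."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def wilcoxon_enumeration_p(d):
    """Exact two-sided p by enumerating all sign assignments (n <= 12)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [np.sum(np.array(signs) * ranks) for signs in itertools.product((0, 1), repeat=n)]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestKappa:
    @pytest.mark.parametrize("counts, expected_kappa, expected_agree", WORKED_TABLES)
    def test_published_tables_reproduce_kappa_and_agreement(self, counts, expected_kappa, expected_agree):
        t = Contingency2x2(*counts)
        assert round(cohens_kappa(t), 2) == expected_kappa
        assert t.a + t.d == expected_agree
        assert percent_agreement(t) == pytest.approx(expected_agree / 176)

    def test_perfect_agreement_is_one(self):
        assert cohens_kappa(Contingency2x2(30, 0, 0, 146)) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0))
    def test_kappa_is_symmetric_under_transposition(self, counts):
        t = Contingency2x2(*counts)
        try:
            k1 = cohens_kappa(t)
        except ValueError:
            return
        assert cohens_kappa(t.transposed()) == pytest.approx(k1, abs=1e-12)

    def test_degenerate_marginals(self):
        # a single occupied diagonal cell: perfect but chance-level marginals
        assert cohens_kappa(Contingency2x2(5, 0, 0, 0)) == 1.0
        assert cohens_kappa(Contingency2x2(0, 0, 0, 5)) == 1.0
        # one rater constant: no agreement beyond chance
        assert cohens_kappa(Contingency2x2(0, 5, 0, 5)) == pytest.approx(0.0)

    def test_matches_sklearn_on_random_tables(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, 4)
            t = Contingency2x2(int(a), int(b), int(c), int(d))
            y1 = [1] * (a + b) + [0] * (c + d)
            y2 = [1] * a + [0] * b + [1] * c + [0] * d
            assert cohens_kappa(t) == pytest.approx(cohen_kappa_score(y1, y2), abs=1e-12)


class TestContingency:
    def test_identical_scores(self):
        s = np.array([1, 0, 1, 0, 0])
        t = contingency([s], [s])
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 3)

    def test_complementary_scores(self):
        s = np.array([1, 0, 1])
        t = contingency([s], [1 - s])
        assert (t.a, t.d) == (0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contingency([np.ones(5, int)], [np.ones(4, int)])


class TestDiagnostics:
    def test_worked_table_standard_definitions(self):
        m = diagnostic_metrics(Contingency2x2(51, 1, 4, 120))
        assert m["sensitivity"] == pytest.approx(51 / 55)
        assert m["specificity"] == pytest.approx(120 / 121)
        assert m["ppv"] == pytest.approx(51 / 52)
        assert m["npv"] == pytest.approx(120 / 124)

    def test_perfect_table(self):
        m = diagnostic_metrics(Contingency2x2(10, 0, 0, 20))
        assert all(v == 1.0 for v in m.values())

    def test_zero_marginals_are_nan_not_zero(self):
        m = diagnostic_metrics(Contingency2x2(0, 0, 3, 7))
        assert m["sensitivity"] == 0.0
        assert math.isnan(m["ppv"])


class TestBlandAltman:
    def test_identical_series(self):
        bias, (lo, hi) = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_constant_offset(self):
        x = np.array([10.0, 11.0, 12.0])
        bias, _ = bland_altman(x, x + 0.2)
        assert bias == pytest.approx(-0.2)

    def test_plus_minus_one_differences(self):
        x = np.array([0.0, 0.0])
        y = np.array([1.0, -1.0])
        bias, (lo, hi) = bland_altman(x, y)
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * math.sqrt(2.0))
        assert lo == pytest.approx(-1.96 * math.sqrt(2.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestICC:
    def test_equal_series_give_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc(x, x) == pytest.approx(1.0)

    def test_offset_penalized_below_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 10.0
        r = stats.pearsonr(x, y).statistic
        assert icc(x, y) < r

    def test_uncorrelated_columns_near_zero(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        assert abs(icc(x, y)) < 0.12

    def test_matches_anova_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(10, 3, 10)
            y = x + rng.normal(0.5, 1.0, 10)
            assert icc(x, y) == pytest.approx(icc21_anova(x, y), abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            icc([1.0, 2.0], [1.0, 2.0])


class TestWilcoxon:
    def test_all_zero_differences_is_an_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_alternating_unit_differences_give_p_one(self):
        x = np.zeros(8)
        y = np.array([1.0, -1.0] * 4)
        res = wilcoxon_signed_rank(x, y)
        assert res.p_value == 1.0

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(8)
        for n in (5, 7, 9, 10):
            for _ in range(5):
                d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding makes ties
                d = np.where(d == 0, 0.1, d)
                res = wilcoxon_signed_rank(d, np.zeros(n))
                assert res.method == "exact"
                assert res.p_value == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(0.4, 1.0, 12)
            ref = stats.wilcoxon(x, method="exact").pvalue
            assert wilcoxon_signed_rank(x, np.zeros_like(x)).p_value == pytest.approx(ref, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0.3, 1.0, 40)
        res = wilcoxon_signed_rank(x, np.zeros_like(x))
        assert res.method == "approx"
        assert 0.0 <= res.p_value <= 1.0

    def test_bonferroni_level(self):
        assert bonferroni_alpha(0.05, 11) == pytest.approx(0.0045, abs=1e-4)
        res = wilcoxon_signed_rank(np.arange(1.0, 12.0), np.zeros(11), alpha=bonferroni_alpha())
        assert res.significant  # all-positive differences, p ~ 0.001


def test_pearson_r2_is_squared_correlation():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = 2 * x + np.array([0.1, -0.1, 0.05, 0.0])
    assert pearson_r2(x, y) == pytest.approx(stats.pearsonr(x, y).statistic ** 2)
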