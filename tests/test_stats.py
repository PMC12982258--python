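"""Oracle and property tests for the rank-based statistical battery.

scipy.stats and statsmodels serve as independent cross-checks; the
implementations under test never call them.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from nmoh.stats import (
    adjust_pvalues,
    chi_squared,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney_u,
    quade_ancova,
    spearman,
    welch_t,
)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestMannWhitney:
    def test_fully_separated_exact(self):
        # U = 0; only 2 of C(6,3)=20 arrangements are as extreme two-sided
        r = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert r.statistic == 0.0
        assert r.p_raw == pytest.approx(0.1)

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = mann_whitney_u(x, x)
        assert r.statistic == pytest.approx(len(x) ** 2 / 2)
        assert r.p_raw >= 0.99

    @given(
        st.lists(finite_floats, min_size=1, max_size=15),
        st.lists(finite_floats, min_size=1, max_size=15),
    )
    @settings(max_examples=100, deadline=None)
    def test_u_sum_identity(self, x, y):
        r = mann_whitney_u(x, y)
        assert r.notes["U1"] + r.notes["U2"] == pytest.approx(len(x) * len(y))

    def test_exact_matches_scipy(self, rng):
        for n1, n2 in [(3, 4), (5, 5), (6, 4)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + 0.5
            ours = mann_whitney_u(x, y, mode="exact").p_raw
            theirs = ss.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_normal_approx_matches_scipy_with_ties(self, rng):
        x = np.round(rng.normal(size=25), 1)
        y = np.round(rng.normal(size=30), 1)
        ours = mann_whitney_u(x, y, mode="normal_approx").p_raw
        theirs = ss.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided").pvalue
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(ValueError):
            mann_whitney_u([1, 1, 2], [3, 4], mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(4.5714, abs=1e-4)

    def test_h_equals_z_squared_for_two_groups(self, rng):
        # tie-free two-group H equals the squared untied normal deviate of U
        x, y = rng.normal(size=8), rng.normal(size=11)
        h = kruskal_wallis([x, y]).statistic
        n1, n2 = len(x), len(y)
        u1 = ss.rankdata(np.concatenate([x, y]))[:n1].sum() - n1 * (n1 + 1) / 2
        z = (u1 - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        assert h == pytest.approx(z**2, abs=1e-10)

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(size=n) for n in (5, 7, 6)]
        a = kruskal_wallis(groups).statistic
        b = kruskal_wallis(groups[::-1]).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        groups = [np.round(rng.normal(size=n), 1) for n in (10, 12, 8)]
        ours = kruskal_wallis(groups)
        theirs = ss.kruskal(*groups)
        assert ours.statistic == pytest.approx(theirs.statistic, rel=1e-12)
        assert ours.p_raw == pytest.approx(theirs.pvalue, rel=1e-10)

    def test_all_identical_values(self):
        r = kruskal_wallis([[5, 5], [5, 5, 5], [5]])
        assert r.statistic == 0.0 and r.p_raw == 1.0


class TestDunn:
    def test_hand_computed_pair(self):
        results = dunn_posthoc([[1, 2], [3, 4], [5, 6]], fwe="none")
        first_vs_third = next(r for r in results if r.notes["pair"] == ("group0", "group2"))
        assert abs(first_vs_third.notes["mean_rank_diff"]) == pytest.approx(4.0)
        assert abs(first_vs_third.statistic) == pytest.approx(4 / np.sqrt(3.5), abs=1e-3)

    def test_identical_groups_give_z_zero(self):
        results = dunn_posthoc([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert all(r.statistic == pytest.approx(0.0) for r in results)
        assert all(r.p_raw == pytest.approx(1.0) for r in results)

    def test_bonferroni_is_three_times_p(self, rng):
        results = dunn_posthoc([rng.normal(size=6) for _ in range(3)], fwe="bonferroni")
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))


class TestQuade:
    def test_no_covariates_equals_rank_anova(self, rng):
        y = rng.normal(size=30)
        g = np.repeat([0, 1, 2], 10)
        ours = quade_ancova(y, g, [])
        ranks = ss.rankdata(y)
        theirs = ss.f_oneway(*[ranks[g == k] for k in range(3)])
        assert ours.statistic == pytest.approx(theirs.statistic, abs=1e-10)
        assert ours.p_raw == pytest.approx(theirs.pvalue, abs=1e-10)

    def test_constant_covariate_dropped_equals_rank_anova(self, rng):
        y = rng.normal(size=24)
        g = np.repeat([0, 1, 2], 8)
        with_const = quade_ancova(y, g, [np.full(24, 7.0)])
        without = quade_ancova(y, g, [])
        assert with_const.statistic == pytest.approx(without.statistic, abs=1e-10)
        assert with_const.notes["constant_covariates_dropped"] == 1

    def test_covariate_equal_to_response_saturates(self, rng):
        y = rng.normal(size=30)
        g = np.repeat([0, 1, 2], 10)
        r = quade_ancova(y, g, [y.copy()])
        assert r.statistic == pytest.approx(0.0, abs=1e-10)

    def test_collinear_covariates_rejected(self, rng):
        y = rng.normal(size=20)
        g = np.repeat([0, 1], 10)
        c = rng.normal(size=20)
        with pytest.raises(ValueError, match="singular"):
            quade_ancova(y, g, [c, c.copy()])

    def test_adjusting_for_noise_keeps_a_strong_effect(self, rng):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        g = np.repeat([0, 1], 20)
        r = quade_ancova(y, g, [rng.normal(size=40)])
        assert r.p_raw < 0.001


class TestSpearman:
    def test_perfect_antitone(self):
        r = spearman([1, 2, 3], [3, 2, 1])
        assert r.rho == pytest.approx(-1.0) and r.p_raw == 0.0

    def test_monotone_transform_gives_plus_one(self, rng):
        x = rng.normal(size=20)
        r = spearman(x, np.exp(x))
        assert r.rho == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        x = np.round(rng.normal(size=40), 1)
        y = np.round(rng.normal(size=40), 1)
        ours = spearman(x, y)
        theirs = ss.spearmanr(x, y)
        assert ours.rho == pytest.approx(theirs.statistic, abs=1e-12)
        assert ours.p_raw == pytest.approx(theirs.pvalue, rel=1e-8)

    def test_null_rho_small_at_large_n(self, rng):
        r = spearman(rng.random(1000), rng.random(1000))
        assert abs(r.rho) < 0.1

    def test_constant_input_flagged(self):
        r = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(r.rho) and "undefined" in r.notes


class TestChiSquared:
    def test_perfect_independence(self):
        r = chi_squared([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p_raw == pytest.approx(1.0)

    def test_hand_computed_diagonal_table(self):
        assert chi_squared([[20, 0], [0, 20]]).statistic == pytest.approx(40.0)

    def test_transpose_invariance(self, rng):
        table = rng.integers(1, 30, size=(3, 4))
        a = chi_squared(table).statistic
        b = chi_squared(table.T).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_yates_matches_scipy(self):
        table = [[12, 5], [7, 16]]
        ours = chi_squared(table, yates=True)
        chi2, p, dof, _ = ss.chi2_contingency(table, correction=True)
        assert ours.statistic == pytest.approx(chi2, abs=1e-12)
        assert ours.p_raw == pytest.approx(p, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [5, 5]])


class TestWelch:
    def test_identical_samples(self):
        r = welch_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_raw == pytest.approx(1.0)

    def test_separated_samples(self, rng):
        r = welch_t(rng.normal(0, 0.01, 4), rng.normal(1, 0.01, 4))
        assert r.p_raw < 1e-6

    def test_matches_scipy_to_1e10(self, rng):
        x, y = rng.normal(size=13), rng.normal(0.4, 1.7, size=9)
        ours = welch_t(x, y)
        theirs = ss.ttest_ind(x, y, equal_var=False)
        assert ours.statistic == pytest.approx(theirs.statistic, abs=1e-10)
        assert ours.p_raw == pytest.approx(theirs.pvalue, abs=1e-10)


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh_fdr") == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        for method in ("bh_fdr", "bonferroni"):
            assert adjust_pvalues([0.037], method) == pytest.approx([0.037])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_bh_dominates_raw_and_preserves_order(self, p):
        adj = np.asarray(adjust_pvalues(p, "bh_fdr"))
        p = np.asarray(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        ours = adjust_pvalues(p, "bh_fdr")
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh_fdr")


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(-1000, 1000), min_size=3, max_size=12, unique=True),
    st.lists(st.integers(-1000, 1000), min_size=3, max_size=12, unique=True),
)
def test_rank_tests_invariant_under_monotone_transform(x, y):
    """Mann-Whitney, Kruskal-Wallis and Spearman depend on the data only
    through ranks, so a strictly increasing transform changes nothing."""
    x = [float(v) / 7.0 for v in x]
    y = [float(v) / 7.0 for v in y]
    f = lambda v: np.exp(np.asarray(v) / 25.0)
    a, b = mann_whitney_u(x, y), mann_whitney_u(f(x), f(y))
    assert a.statistic == pytest.approx(b.statistic) and a.p_raw == pytest.approx(b.p_raw)
    a, b = kruskal_wallis([x, y]), kruskal_wallis([f(x), f(y)])
    assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
    if len(x) == len(y):
        a, b = spearman(x, y), spearman(f(x), f(y))
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
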