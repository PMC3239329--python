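import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_cells
from concord import (
    PosteriorSummary,
    apply_rules,
    joint_cells,
    make_grid,
    posterior_curve,
    posterior_draws,
    r_statistic,
    ratio_curve,
    ratio_statistic,
    summarize_posterior,
    two_list_cells,
)
from conftest import random_matrix


class TestJointCells:
    def test_reconstruction_from_published_counts(self):
        # marginals (199, 233), common 39, n = 2912
        table = two_list_cells(39, 199, 233, 2912)
        # patterns ordered (00, 10, 01, 11)
        assert list(table.cells) == [2519, 160, 194, 39]
        assert table.common == 39
        assert list(table.marginals) == [199, 233]

    def test_nothing_significant(self, toy_matrix):
        table = joint_cells(toy_matrix, 0.001)
        assert table.cells[0] == toy_matrix.n
        assert table.cells[1:].sum() == 0

    def test_matches_brute_force_patterns(self):
        rng = np.random.default_rng(4)
        P = random_matrix(rng, 30, 3)
        for h in (0.1, 0.35, 0.8):
            table = joint_cells(P, h)
            assert list(table.cells) == brute_cells(P.values.tolist(), h)

    def test_consistent_with_frequentist_counts(self):
        rng = np.random.default_rng(9)
        P = random_matrix(rng, 60, 2)
        grid = make_grid(0.05, 1.0, 0.05)
        curve = ratio_curve(P, grid)
        for i, h in enumerate(grid.h_values):
            table = joint_cells(P, float(h))
            assert table.common == curve.common_count[i]
            assert list(table.marginals) == list(curve.marginal_counts[i])

    def test_inconsistent_cells_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            two_list_cells(50, 40, 60, 100)  # common > marginal1


class TestRStatistic:
    def test_uniform_table_is_independent(self):
        assert r_statistic(np.full(4, 0.25)) == pytest.approx(1.0)

    def test_concentrated_table(self):
        assert r_statistic(np.array([0.5, 0.0, 0.0, 0.5])) == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        m=st.lists(st.floats(0.05, 0.95), min_size=2, max_size=3),
    )
    def test_outer_product_gives_one(self, m):
        # build p as the product of independent per-list margins
        L = len(m)
        p = np.empty(2**L)
        for k in range(2**L):
            v = 1.0
            for l in range(L):
                v *= m[l] if (k >> l) & 1 else 1 - m[l]
            p[k] = v
        assert r_statistic(p) == pytest.approx(1.0, rel=1e-9)

    def test_zero_marginal_undefined(self):
        assert np.isnan(r_statistic(np.array([1.0, 0.0, 0.0, 0.0])))

    def test_batch_shape(self):
        p = np.tile(np.full(4, 0.25), (7, 1))
        out = r_statistic(p)
        assert out.shape == (7,)
        np.testing.assert_allclose(out, 1.0)


class TestPosteriorDraws:
    def test_seeded_determinism(self):
        table = two_list_cells(39, 199, 233, 2912)
        a = posterior_draws(table, n_draws=500, seed=3)
        b = posterior_draws(table, n_draws=500, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (500,)

    def test_no_degenerate_draws_with_unit_prior(self):
        # empty cells cannot zero a sampled marginal when alpha >= 1
        table = two_list_cells(0, 0, 0, 50)
        draws = posterior_draws(table, alpha=1.0, n_draws=2000, seed=0)
        assert draws.shape == (2000,)
        assert np.isfinite(draws).all()

    def test_posterior_concentrates_on_frequentist_ratio(self):
        # multiplying all counts shrinks the posterior around T of the table
        base = (68, 264, 299, 2912)
        T = ratio_statistic(base[0], base[1] * base[2] / base[3])
        gap_prev = np.inf
        for scale in (1, 10):
            table = two_list_cells(*(scale * c for c in base))
            med = np.median(posterior_draws(table, n_draws=20000, seed=1))
            gap = abs(med - T)
            assert gap < gap_prev
            gap_prev = gap

    def test_invalid_parameters(self):
        table = two_list_cells(1, 2, 3, 10)
        with pytest.raises(ValueError):
            posterior_draws(table, alpha=0.0)
        with pytest.raises(ValueError):
            posterior_draws(table, n_draws=0)


class TestSummarizePosterior:
    def test_known_order_statistics(self):
        draws = np.arange(1.0, 101.0)
        s = summarize_posterior(draws)
        assert s.median == pytest.approx(50.5)  # linear interpolation
        assert s.lower < s.median < s.upper
        assert s.n_draws == 100

    def test_degenerate_draws(self):
        s = summarize_posterior(np.full(10, 2.0))
        assert s.lower == s.median == s.upper == 2.0
        assert s.excludes_one

    def test_interval_containing_one(self):
        s = summarize_posterior(np.linspace(0.5, 1.5, 101))
        assert not s.excludes_one

    def test_quantiles_monotone_in_level(self):
        rng = np.random.default_rng(0)
        s = summarize_posterior(
            rng.gamma(2.0, size=5000), levels=(0.05, 0.25, 0.5, 0.75, 0.95)
        )
        vals = [s.quantiles[q] for q in sorted(s.quantiles)]
        assert vals == sorted(vals)


def _summary(h, median, lower, upper):
    return PosteriorSummary(
        h=h,
        quantiles={0.025: lower, 0.5: median, 0.975: upper},
        n_draws=1000,
        excludes_one=lower > 1 or upper < 1,
    )


class TestApplyRules:
    def test_hmax_is_argmax_over_excluding_intervals(self):
        summaries = [
            _summary(0.01, 2.40, 1.8, 3.0),
            _summary(0.02, 2.50, 2.0 + 1e-9, 3.1),
            _summary(0.03, 2.28, 1.9, 2.8),
        ]
        rules = apply_rules(summaries)
        assert rules.h_max_bayes == pytest.approx(0.02)
        assert rules.R_at_hmax == pytest.approx(2.50)

    def test_hmax_ignores_intervals_containing_one(self):
        summaries = [
            _summary(0.01, 3.0, 0.9, 5.0),  # wide, contains 1
            _summary(0.02, 2.0, 1.5, 2.6),
        ]
        assert apply_rules(summaries).h_max_bayes == pytest.approx(0.02)

    def test_hmax_not_applicable(self):
        summaries = [_summary(h, 1.2, 0.8, 1.8) for h in (0.01, 0.02)]
        rules = apply_rules(summaries)
        assert rules.h_max_bayes is None and rules.R_at_hmax is None

    def test_hmax_plateau_takes_smallest_h(self):
        summaries = [
            _summary(0.01, 2.5, 1.9, 3.1),
            _summary(0.02, 2.5, 1.9, 3.1),
        ]
        assert apply_rules(summaries).h_max_bayes == pytest.approx(0.01)

    def test_h2_is_largest_threshold_with_median_at_least_two(self):
        summaries = [
            _summary(0.01, 2.5, 1.9, 3.1),
            _summary(0.02, 2.2, 1.7, 2.8),
            _summary(0.03, 1.9, 1.5, 2.4),
        ]
        rules = apply_rules(summaries)
        assert rules.h2 == pytest.approx(0.02)
        assert rules.R_at_h2 == pytest.approx(2.2)

    def test_h2_not_applicable_when_median_never_reaches_two(self):
        summaries = [_summary(h, 1.7, 1.4, 2.0) for h in (0.01, 0.02, 0.03)]
        rules = apply_rules(summaries)
        assert rules.h2 is None and rules.R_at_h2 is None


class TestPosteriorCurve:
    def test_curve_summaries_cover_grid_and_reproduce(self):
        rng = np.random.default_rng(12)
        P = random_matrix(rng, 40, 2)
        grid = make_grid(0.2, 1.0, 0.2)
        a = posterior_curve(P, grid, n_draws=400, seed=8)
        b = posterior_curve(P, grid, n_draws=400, seed=8)
        assert [s.h for s in a] == pytest.approx(list(grid.h_values))
        for sa, sb in zip(a, b):
            assert sa.quantiles == sb.quantiles
            assert sa.lower <= sa.median <= sa.upper

    def test_independent_columns_intervals_mostly_contain_one(self):
        # null data: the credible interval should cover 1 at nearly all
        # thresholds (joint multinomial sampling makes per-h events dependent,
        # so only a coarse bound is asserted)
        rng = np.random.default_rng(21)
        P = random_matrix(rng, 1000, 2)
        grid = make_grid(0.05, 1.0, 0.05)
        summaries = posterior_curve(P, grid, n_draws=1000, seed=2)
        frac_excluding = np.mean([s.excludes_one for s in summaries])
        assert frac_excluding <= 0.15
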