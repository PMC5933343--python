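"""Random-encounter cannibalism model: step rules, expectation, chi-square."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import preyspectra as ps
from preyspectra.errors import DegenerateDataError, DegenerateModelError

from conftest import make_table


class TestSuccessProbability:
    @pytest.mark.parametrize(
        "pred,victim,expected",
        [
            (29.2, 20.0, 1.0),   # ratio exactly 1.46: "at least" => success
            (23.6, 20.0, 0.5),   # ratio exactly 1.18: intermediate band
            (29.1, 20.0, 0.5),   # just below 1.46
            (23.5, 20.0, 0.0),   # just below 1.18
            (20.0, 20.0, 0.0),   # self-sized pair cannot be subdued
            (50.0, 20.0, 1.0),
        ],
    )
    def test_step_function(self, pred, victim, expected):
        assert ps.success_probability(pred, victim) == expected

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            ps.success_probability(0.0, 20.0)
        with pytest.raises(ValueError):
            ps.success_probability(20.0, -1.0)

    def test_rules_validate_thresholds(self):
        with pytest.raises(ValueError):
            ps.RatioRules(success_threshold=1.1, failure_threshold=1.2)
        with pytest.raises(ValueError):
            ps.RatioRules(intermediate_probability=1.5)


class TestExpectedDistribution:
    def test_hand_enumerated_three_sizes(self):
        # ordered pairs of (20, 30, 50): 30/20=1.5 and 50/20=2.5 and
        # 50/30~1.67 all succeed; every inverse ratio is below 1.18.
        # Raw weights W = (0, 1, 2), already summing to the scale 3.
        grid = ps.SizeClassGrid(lower=15.0, width=15.0, n_classes=3)
        expected = ps.expected_cannibal_distribution([20, 30, 50], grid, scale_to=3)
        assert expected == pytest.approx([0.0, 1.0, 2.0])

    def test_identical_sizes_degenerate(self):
        with pytest.raises(DegenerateModelError):
            ps.expected_cannibal_distribution([30.0] * 5, scale_to=5)

    def test_scaling_conserves_total(self, default_table):
        expected = ps.expected_cannibal_distribution(
            default_table.predator_lengths, scale_to=31.0
        )
        assert expected.sum() == pytest.approx(31.0, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        sizes = np.round(rng.uniform(18, 57, 40), 1)
        a = ps.expected_cannibal_distribution(sizes, scale_to=10)
        b = ps.expected_cannibal_distribution(rng.permutation(sizes), scale_to=10)
        assert a == pytest.approx(b)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_growing_an_individual_never_lowers_its_weight(self, seed):
        rng = np.random.default_rng(seed)
        sizes = np.round(rng.uniform(18, 57, 15), 1)
        w = ps.cannibal_propensities(sizes)
        grown = sizes.copy()
        grown[0] = min(grown[0] + rng.uniform(0, 10), 60.9)
        w2 = ps.cannibal_propensities(grown)
        assert w2[0] >= w[0] - 1e-12

    @pytest.mark.parametrize("n_pool,seed", [(10, 0), (80, 1), (300, 2)])
    def test_monte_carlo_oracle_agreement(self, n_pool, seed):
        """Analytic per-class expectation matches a seeded pair-draw
        simulation within 3 standard errors in every class."""
        sizes = ps.generate_population_sizes(n_pool, seed=seed)
        grid = ps.SizeClassGrid()
        analytic = ps.expected_cannibal_distribution(sizes, grid, scale_to=1.0)
        counts, n_success = ps.simulate_cannibal_distribution(
            sizes, grid, n_draws=100_000, seed=seed + 1
        )
        assert n_success > 0
        frac = counts / n_success
        se = np.sqrt(np.maximum(analytic * (1 - analytic), 1e-12) / n_success)
        assert np.all(np.abs(frac - analytic) <= 3 * se + 1e-12)


class TestChiSquare:
    def test_exact_match_gives_zero(self):
        chi2, df = ps.chi_square_gof([5, 5, 5], [5.0, 5.0, 5.0])
        assert chi2 == 0.0 and df == 2

    def test_two_class_worked_example(self):
        chi2, df = ps.chi_square_gof([10, 0], [5.0, 5.0])
        assert chi2 == pytest.approx(10.0) and df == 1

    def test_eleven_all_positive_classes_give_df_ten(self):
        observed = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5]
        expected = np.full(11, sum(observed) / 11)
        chi2, df = ps.chi_square_gof(observed, expected)
        assert df == 10
        ref = scipy.stats.chisquare(observed, expected)
        assert chi2 == pytest.approx(ref.statistic)

    def test_double_zero_classes_are_skipped(self):
        chi2, df = ps.chi_square_gof([4, 0, 6], [5.0, 0.0, 5.0])
        assert df == 1
        assert chi2 == pytest.approx(0.2 + 0.2)

    def test_expected_zero_with_observed_positive_is_undefined(self):
        with pytest.raises(DegenerateModelError):
            ps.chi_square_gof([4, 1, 5], [5.0, 0.0, 5.0])

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            ps.chi_square_gof([10, 10], [5.0, 5.0])


class TestRunAnalysis:
    def test_synthetic_default_table(self, default_table):
        result = ps.run_cannibalism_analysis(default_table)
        n_cannibal = int(np.sum(default_table.prey_groups == "conspecific"))
        assert sum(result.observed) == n_cannibal
        assert sum(result.expected) == pytest.approx(n_cannibal, abs=1e-9)
        assert result.n_pool == len(default_table)
        assert result.chi_square > 0 and result.df >= 1
        # observed cannibals concentrate above 41 mm (classes 6+), while the
        # expectation leaves substantial mass at intermediate sizes
        obs_large = sum(result.observed[6:])
        assert obs_large >= 0.8 * n_cannibal
        exp_intermediate = sum(result.expected[2:6])
        assert exp_intermediate > 0.3 * n_cannibal

    def test_single_giant_takes_all_expected_mass(self):
        rows = [("bivalve", 20.0, 5.0)] * 5 + [("conspecific", 60.0, 20.0)]
        table = make_table(rows)
        grid = ps.SizeClassGrid(lower=17.0, width=4.0, n_classes=11)
        result = ps.run_cannibalism_analysis(table, grid)
        assert result.expected[10] == pytest.approx(1.0)
        assert sum(result.expected[:10]) == pytest.approx(0.0, abs=1e-12)

    def test_no_conspecific_events_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            ps.run_cannibalism_analysis(make_table([("bivalve", 30.0, 5.0)] * 4))
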