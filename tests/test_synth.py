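"""Synthetic-event generator: determinism, constraints, calibration."""

import numpy as np
import pytest
import scipy.stats

import preyspectra as ps
from preyspectra.errors import ConfigError
from preyspectra.synth import CannibalRule, GastropodRule


class TestPopulationSizes:
    def test_sizes_respect_truncation_bounds(self):
        sizes = ps.generate_population_sizes(2000, seed=0)
        assert sizes.min() >= 18.0 and sizes.max() <= 57.4

    def test_intermediate_sizes_make_up_three_quarters(self):
        # calibration target: ~76% of successful predators in 25-37 mm
        sizes = ps.generate_population_sizes(1000, seed=0)
        frac = np.mean((sizes >= 25.0) & (sizes < 37.0))
        assert frac == pytest.approx(0.76, abs=0.05)

    def test_single_draw_in_range(self):
        sizes = ps.generate_population_sizes(1, seed=5)
        assert sizes.shape == (1,) and 18.0 <= sizes[0] <= 57.4

    def test_different_seeds_differ(self):
        a = ps.generate_population_sizes(500, seed=1)
        b = ps.generate_population_sizes(500, seed=2)
        assert scipy.stats.ks_2samp(a, b).statistic > 0.0

    def test_sizes_on_tenth_mm_grid(self):
        sizes = ps.generate_population_sizes(200, seed=3)
        assert np.allclose(sizes * 10, np.round(sizes * 10))


class TestGenerateEvents:
    def test_same_seed_byte_identical_csv(self, tmp_path):
        paths = []
        for name in ("a.csv", "b.csv"):
            table, _ = ps.generate_events(ps.GeneratorConfig(seed=7))
            ps.write_events(table, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_report_counts_sum_to_n(self, default_report):
        assert default_report.total == 327

    def test_taxon_counts_within_binomial_envelope(self):
        # multinomial at the documented mix (165, 88, 43, 31)/327: each
        # realized count should sit inside its binomial 99% envelope
        table, report = ps.generate_events(ps.GeneratorConfig(n_events=327, seed=11))
        for group, expected in zip(
            ("gastropod", "bivalve", "crustacean", "conspecific"), (165, 88, 43, 31)
        ):
            lo, hi = scipy.stats.binom.ppf([0.005, 0.995], 327, expected / 327)
            assert lo <= report.group_counts[group] <= hi

    def test_pure_gastropod_mix(self):
        cfg = ps.GeneratorConfig(
            n_events=200,
            seed=3,
            taxon_mix=(1.0, 0.0, 0.0, 0.0),
            gastropod_rule=GastropodRule(outlier_probability=0.0),
        )
        table, _ = ps.generate_events(cfg)
        assert len(table) == 200
        assert set(table.prey_groups) == {"gastropod"}
        ratios = table.predator_lengths / table.prey_lengths
        assert ratios.min() >= 1.45

    def test_gastropod_constraints_exhaustive(self):
        """With outlier probability zero, no gastropod-prey event may sit
        below the 1.45 ratio floor; prey stays under 19 mm and predators
        under the 41 mm cap."""
        cfg = ps.GeneratorConfig(
            n_events=10_000,
            seed=13,
            taxon_mix=(1.0, 0.0, 0.0, 0.0),
            gastropod_rule=GastropodRule(outlier_probability=0.0),
        )
        table, _ = ps.generate_events(cfg)
        ratios = table.predator_lengths / table.prey_lengths
        assert np.all(ratios >= 1.45)
        assert table.prey_lengths.max() <= 19.0
        assert table.predator_lengths.max() <= 41.0

    def test_cannibal_constraints_exhaustive(self):
        """Conspecific events always respect the 1.45 ratio floor and the
        13 mm victim floor, at any small-cannibal share."""
        cfg = ps.GeneratorConfig(
            n_events=10_000,
            seed=17,
            taxon_mix=(0.0, 0.0, 0.0, 1.0),
        )
        table, _ = ps.generate_events(cfg)
        ratios = table.predator_lengths / table.prey_lengths
        assert np.all(ratios >= 1.45)
        assert table.prey_lengths.min() >= 13.0
        # small cannibals are rare; the bulk sits at/above 41 mm
        assert np.mean(table.predator_lengths >= 41.0) > 0.8

    def test_bivalve_window_bounds_and_widening(self):
        cfg = ps.GeneratorConfig(n_events=3000, seed=19, taxon_mix=(0.0, 1.0, 0.0, 0.0))
        table, _ = ps.generate_events(cfg)
        prey = table.prey_lengths
        pred = table.predator_lengths
        assert prey.min() >= 3.7
        assert prey.max() <= 40.0
        assert np.all(prey <= pred)
        r = np.corrcoef(pred, prey)[0, 1]
        assert r > 0  # window widening induces a positive size association
        small = pred < np.median(pred)
        assert prey[~small].std() > prey[small].std()

    def test_crustacean_bimodality(self):
        cfg = ps.GeneratorConfig(n_events=4000, seed=23, taxon_mix=(0.0, 0.0, 1.0, 0.0))
        table, _ = ps.generate_events(cfg)
        prey = table.prey_lengths
        pred = table.predator_lengths
        large = prey > 15.0  # the (15, 30) mm gap separates the two modes
        assert 0.01 < large.mean() < 0.10
        assert np.all(prey[large] >= 30.0)
        assert np.all((pred[large] >= 26.5) & (pred[large] <= 35.0))
        assert np.all((prey[~large] >= 4.0) & (prey[~large] <= 15.0))
        assert pred[~large].min() >= 23.0

    def test_all_sizes_inside_truncation(self, default_table):
        assert default_table.predator_lengths.min() >= 18.0
        assert default_table.predator_lengths.max() <= 57.4

    def test_infeasible_config_rejected_before_sampling(self):
        bad = ps.GeneratorConfig(
            cannibal_rule=CannibalRule(victim_floor_mm=45.0)
        )
        with pytest.raises(ConfigError, match="cannibal"):
            ps.generate_events(bad)
        with pytest.raises(ConfigError, match="sum to 1"):
            ps.generate_events(ps.GeneratorConfig(taxon_mix=(0.5, 0.5, 0.5, 0.0)))

    def test_config_from_plain_mapping(self):
        cfg = ps.GeneratorConfig.from_dict(
            {
                "n_events": 50,
                "seed": 2,
                "taxon_mix": [1.0, 0.0, 0.0, 0.0],
                "gastropod_rule": {"outlier_probability": 0.0},
            }
        )
        table, _ = ps.generate_events(cfg)
        assert len(table) == 50 and set(table.prey_groups) == {"gastropod"}
        with pytest.raises(ConfigError, match="unknown"):
            ps.GeneratorConfig.from_dict({"bogus": 1})
        with pytest.raises(ConfigError, match="unknown keys"):
            ps.GeneratorConfig.from_dict({"bivalve_rule": {"nope": 2}})

    def test_gastropod_outliers_appear_at_high_probability(self):
        cfg = ps.GeneratorConfig(
            n_events=500,
            seed=29,
            taxon_mix=(1.0, 0.0, 0.0, 0.0),
            gastropod_rule=GastropodRule(outlier_probability=0.5),
        )
        table, _ = ps.generate_events(cfg)
        ratios = table.predator_lengths / table.prey_lengths
        below = np.sum(ratios < 1.45)
        assert 150 < below < 350  # roughly half violate by construction
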