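"""Synthetic-data generators: dynamics, observation model, manifests."""

import numpy as np
import pytest

import ednascreen as es
from ednascreen.synthdata import StudyDesign, _baseline_growth


class TestTemperature:
    def test_flat_degenerate_case(self):
        temp = es.simulate_temperature(3, seed=0, mean=25.0, amplitude=0.0,
                                       noise_sd=0.0)
        assert temp.tolist() == [25.0, 25.0, 25.0]

    def test_deterministic_given_seed(self):
        a = es.simulate_temperature(50, seed=7)
        b = es.simulate_temperature(50, seed=7)
        assert np.array_equal(a, b)

    def test_season_mean_matches_configured_mean(self):
        """Monte-Carlo: mean over 100 seeds within 1 degC of the configured mean."""
        means = [es.simulate_temperature(122, seed=s).mean() for s in range(100)]
        assert abs(np.mean(means) - 25.0) < 1.0

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            es.simulate_temperature(0, seed=0)


class TestCommunity:
    def test_single_step_closed_form(self):
        """Uncoupled logistic update: 0.4 * 3.8 * 0.6 = 0.912."""
        x = 0.4
        r = 3.8
        assert x * (r - r * x) == pytest.approx(0.912)
        net = es.TrueNetwork(n_taxa=1, interaction_matrix=np.zeros((1, 1)),
                             intrinsic_rates=np.array([3.8]))
        traj = es.simulate_community(net, n_days=10, n_plots=1, seed=0,
                                     noise_sd=0.0)
        x0 = traj.states[0, 0, 0]
        assert traj.states[0, 1, 0] == pytest.approx(x0 * (3.8 - 3.8 * x0))

    def test_zero_coupling_gives_uncorrelated_taxa(self):
        """With no interactions, average cross-correlation ~ 0 over 100 seeds."""
        corrs = []
        for s in range(100):
            net = es.TrueNetwork(n_taxa=2, interaction_matrix=np.zeros((2, 2)),
                                 intrinsic_rates=np.array([3.8, 3.6]))
            traj = es.simulate_community(net, n_days=60, n_plots=1, seed=s)
            a, b = traj.states[0, :, 0], traj.states[0, :, 1]
            corrs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(corrs)) < 0.05

    def test_states_bounded_and_deterministic(self):
        net = es.make_network(n_taxa=5, seed=1)
        a = es.simulate_community(net, n_days=30, n_plots=2, seed=4)
        b = es.simulate_community(net, n_days=30, n_plots=2, seed=4)
        assert np.array_equal(a.states, b.states)
        assert (a.states >= 0).all() and (a.states <= 1).all()
        assert (a.abundances >= 0).all()

    def test_plots_differ(self):
        net = es.make_network(n_taxa=3, seed=2)
        traj = es.simulate_community(net, n_days=30, n_plots=2, seed=0)
        assert not np.array_equal(traj.states[0], traj.states[1])


class TestRiceGrowth:
    def test_null_effects_give_exact_baseline(self):
        net = es.TrueNetwork(n_taxa=2, interaction_matrix=np.zeros((2, 2)),
                             growth_drivers=[], climate_driver=(0, 0.0))
        traj = es.simulate_community(net, n_days=40, n_plots=2, seed=1)
        growth = es.simulate_rice_growth(traj, net, seed=0, noise_sd=0.0)
        expected = _baseline_growth(40)
        assert np.allclose(growth, np.tile(expected, (2, 1)))

    def test_planted_lag_maximises_cross_correlation(self):
        """Brute-force lag scan on growth residuals peaks at the planted lag."""
        drivers = [(0, 3, 0.8)]
        net = es.TrueNetwork(n_taxa=2, interaction_matrix=np.zeros((2, 2)),
                             growth_drivers=drivers, climate_driver=(0, 0.0),
                             intrinsic_rates=np.array([3.8, 3.5]))
        traj = es.simulate_community(net, n_days=100, n_plots=1, seed=5)
        growth = es.simulate_rice_growth(traj, net, seed=5, noise_sd=0.0)
        resid = growth[0] - _baseline_growth(100)
        state = traj.states[0, :, 0]
        corr = {lag: np.corrcoef(resid[lag:], state[:len(state) - lag])[0, 1]
                for lag in range(0, 8)}
        assert max(corr, key=corr.get) == 3

    def test_deterministic_given_seed(self):
        net = es.make_network(n_taxa=3, seed=0)
        traj = es.simulate_community(net, n_days=30, n_plots=2, seed=2)
        a = es.simulate_rice_growth(traj, net, seed=9).copy()
        b = es.simulate_rice_growth(traj, net, seed=9)
        assert np.array_equal(a, b)

    def test_lag_exceeding_series_rejected(self):
        net = es.TrueNetwork(n_taxa=1, interaction_matrix=np.zeros((1, 1)),
                             growth_drivers=[(0, 50, 1.0)])
        traj = es.simulate_community(net, n_days=30, n_plots=1, seed=0)
        with pytest.raises(ValueError, match="lag"):
            es.simulate_rice_growth(traj, net, seed=0)


class TestReadTable:
    def test_noiseless_reads_proportional(self):
        """Standards at copies [5,10,25,50,100] with slope 10 read 10x copies."""
        net = es.TrueNetwork(n_taxa=1, interaction_matrix=np.zeros((1, 1)))
        traj = es.simulate_community(net, n_days=10, n_plots=1, seed=0)
        reads, manifest = es.generate_read_table(
            traj, depth_factor=10.0, noise_model="none", seed=0, depth_sd_log=0.0)
        std = es.SpikeInDesign()
        assert np.allclose(reads[std.standard_ids].iloc[0],
                           10.0 * std.copies_per_ul)
        # taxon reads proportional to copies/ul (= copies/ml * 200 / 100)
        expected = 10.0 * traj.abundances[0, 0, 0] * 200.0 / 100.0
        assert reads.iloc[0, 0] == pytest.approx(expected)
        assert len(manifest) == len(reads)
        assert manifest["sample_id"].is_unique

    def test_poisson_mean_matches_rate(self):
        """1000 Poisson draws at slope*copies = 100 average to 100 +- 3."""
        rng = np.random.default_rng(0)
        draws = rng.poisson(100.0, size=1000)
        assert abs(draws.mean() - 100.0) <= 3.0

    def test_unknown_noise_model_rejected(self):
        net = es.TrueNetwork(n_taxa=1, interaction_matrix=np.zeros((1, 1)))
        traj = es.simulate_community(net, n_days=10, n_plots=1, seed=0)
        with pytest.raises(ValueError, match="noise_model"):
            es.generate_read_table(traj, noise_model="negbin", seed=0)

    def test_poisson_reads_deterministic_given_seed(self):
        net = es.TrueNetwork(n_taxa=2, interaction_matrix=np.zeros((2, 2)))
        traj = es.simulate_community(net, n_days=12, n_plots=1, seed=3)
        a, _ = es.generate_read_table(traj, seed=8)
        b, _ = es.generate_read_table(traj, seed=8)
        assert a.equals(b)


class TestManifests:
    def test_season_design_row_count(self):
        """122 days x 2 filter types x 5 plots = 1220 water samples."""
        man = es.generate_manifest(StudyDesign())
        assert len(man[man["sample_class"] == "sample"]) == 1220

    def test_controls_appended(self):
        man = es.generate_manifest(StudyDesign(n_days=2, n_plots=1,
                                               filter_types=("f",),
                                               n_field_negatives=3,
                                               n_pcr_negatives=2, n_positives=1))
        assert len(man) == 2 + 6
        assert (man["sample_class"] != "sample").sum() == 6

    def test_minimal_design_single_row(self):
        man = es.generate_manifest(StudyDesign(n_days=1, n_plots=1,
                                               filter_types=("f",)))
        assert len(man) == 1

    def test_seedling_design_count(self):
        """3 treatments x 3 replicates x 3 pots x 3 seedlings = 81."""
        seedlings = es.generate_seedling_manifest()
        assert len(seedlings) == 81
        assert seedlings["plot"].nunique() == 9
        assert seedlings["seedling_id"].is_unique
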