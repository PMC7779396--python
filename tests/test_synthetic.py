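"""Generator contracts: score distribution, planted effects, atlas blocks."""

import numpy as np
import pytest
from scipy import stats

from cpmnet import (
    InvalidParameterError,
    make_atlas,
    select_edges,
    simulate_behavior,
    simulate_cohort,
    simulate_timeseries_cohort,
)
from cpmnet.preprocess import connectivity
from cpmnet.synthetic import DEFAULT_REGION_COUNTS, SimulationConfig, default_network_counts


class TestSimulateBehavior:
    def test_moments_and_support(self):
        x = simulate_behavior(10000, mean=40.1, sd=22.3, lo=3, hi=95, seed=0)
        assert abs(x.mean() - 40.1) < 1.0
        assert x.min() >= 3 and x.max() <= 95

    def test_degenerate_spread_collapses_to_mean(self):
        x = simulate_behavior(5, mean=40.0, sd=1e-9, lo=3, hi=95, seed=1)
        assert np.allclose(x, 40.0, atol=1e-6)

    def test_same_seed_identical(self):
        a = simulate_behavior(50, seed=7)
        b = simulate_behavior(50, seed=7)
        assert np.array_equal(a, b)

    def test_skew_changes_shape_but_not_support(self):
        x = simulate_behavior(5000, seed=3, skew=4.0)
        assert x.min() >= 3 and x.max() <= 95
        assert stats.skew(x) > 0.2

    @pytest.mark.parametrize("kwargs", [dict(n=0), dict(n=5, sd=0.0), dict(n=5, lo=10, hi=5)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            simulate_behavior(**{"n": 10, **kwargs})


class TestSimulateCohort:
    def test_planted_edge_correlation_calibrated(self):
        cfg = SimulationConfig(
            n_subjects=200, n_nodes=10, planted_positive_edges=[(0, 1)],
            effect_size=0.8, seed=11,
        )
        cohort = simulate_cohort(cfg)
        w = np.array([m.z[0, 1] for m in cohort.subjects])
        rho, _ = stats.spearmanr(w, cohort.scores)
        assert 0.6 <= rho <= 0.9

    def test_negative_planted_edge_flips_sign(self):
        cfg = SimulationConfig(
            n_subjects=200, n_nodes=10, planted_negative_edges=[(2, 5)],
            effect_size=0.8, seed=12,
        )
        cohort = simulate_cohort(cfg)
        w = np.array([m.z[2, 5] for m in cohort.subjects])
        rho, _ = stats.spearmanr(w, cohort.scores)
        assert -0.9 <= rho <= -0.6

    def test_null_selection_rate_near_alpha(self):
        """With no planted effect ~5% of edges pass the p<0.05 screen."""
        hits = total = 0
        for seed in range(60):
            cfg = SimulationConfig(n_subjects=60, n_nodes=10, effect_size=0.0, seed=seed)
            cohort = simulate_cohort(cfg)
            sel = select_edges(cohort, 0.05)
            hits += len(sel.positive_edges) + len(sel.negative_edges)
            total += sel.rho.size
        frac = hits / total
        assert 0.03 < frac < 0.07

    def test_shapes_symmetry_zero_diagonal(self):
        cfg = SimulationConfig(n_subjects=3, n_nodes=4, seed=0)
        cohort = simulate_cohort(cfg)
        assert cohort.n_subjects == 3
        for m in cohort.subjects:
            assert m.z.shape == (4, 4)
            assert np.array_equal(m.z, m.z.T)
            assert np.all(np.diag(m.z) == 0)

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_subjects=5, n_nodes=6, planted_positive_edges=[(0, 1)],
                               effect_size=0.5, seed=42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(SimulationConfig(**{**cfg.__dict__}))
        assert np.array_equal(a.scores, b.scores)
        for ma, mb in zip(a.subjects, b.subjects):
            assert np.array_equal(ma.z, mb.z)

    def test_generator_calibration_mean_effect(self):
        """Mean empirical planted-edge correlation tracks effect_size within 0.05."""
        e = 0.6
        rhos = []
        for seed in range(50):
            cfg = SimulationConfig(n_subjects=150, n_nodes=6,
                                   planted_positive_edges=[(1, 3)],
                                   effect_size=e, seed=seed)
            cohort = simulate_cohort(cfg)
            w = np.array([m.z[1, 3] for m in cohort.subjects])
            rhos.append(stats.pearsonr(w, cohort.scores)[0])
        assert abs(np.mean(rhos) - e) < 0.05

    def test_planted_edge_out_of_range_errors(self):
        with pytest.raises(InvalidParameterError):
            SimulationConfig(n_nodes=4, planted_positive_edges=[(0, 9)])

    def test_overlapping_planted_lists_error(self):
        with pytest.raises(InvalidParameterError):
            SimulationConfig(planted_positive_edges=[(0, 1)],
                             planted_negative_edges=[(1, 0)])

    def test_labels_from_score_cutoff(self):
        cfg = SimulationConfig(n_subjects=50, n_nodes=4, seed=0, label_score_cutoff=40.0)
        cohort = simulate_cohort(cfg)
        assert np.array_equal(cohort.labels, (cohort.scores >= 40.0).astype(int))


class TestSimulateTimeseriesCohort:
    def test_planted_pair_survives_connectivity(self):
        cfg = SimulationConfig(n_subjects=200, n_nodes=5, n_timepoints=200,
                               planted_positive_edges=[(0, 1)], effect_size=0.8, seed=5)
        ts_list, scores = simulate_timeseries_cohort(cfg)
        z01 = np.array([connectivity(ts).z[0, 1] for ts in ts_list])
        rho, _ = stats.spearmanr(z01, scores)
        assert rho > 0.4

    def test_null_pair_uncorrelated(self):
        cfg = SimulationConfig(n_subjects=100, n_nodes=5, n_timepoints=100,
                               effect_size=0.0, seed=6)
        ts_list, scores = simulate_timeseries_cohort(cfg)
        z01 = np.array([connectivity(ts).z[0, 1] for ts in ts_list])
        rho, _ = stats.spearmanr(z01, scores)
        assert abs(rho) < 0.25

    def test_fd_spike_fraction(self):
        cfg = SimulationConfig(n_subjects=3, n_nodes=4, n_timepoints=100,
                               fd_spike_fraction=0.1, seed=1)
        ts_list, _ = simulate_timeseries_cohort(cfg)
        for ts in ts_list:
            assert int((ts.fd > 0.5).sum()) == 10

    def test_too_few_timepoints(self):
        with pytest.raises(InvalidParameterError):
            simulate_timeseries_cohort(SimulationConfig(n_timepoints=10))


class TestMakeAtlas:
    def test_default_region_counts_total_268(self):
        atlas = make_atlas()
        assert atlas.n_nodes == 268
        counts = atlas.table["region"].value_counts().to_dict()
        assert counts == DEFAULT_REGION_COUNTS
        assert len(set(atlas.table["network"])) == 8

    def test_block_assignment(self):
        atlas = make_atlas({"A": 2, "B": 1}, {"X": 3})
        assert list(atlas.table["region"]) == ["A", "A", "B"]
        assert list(atlas.table["node_id"]) == [1, 2, 3]

    def test_mismatched_totals_error(self):
        with pytest.raises(InvalidParameterError):
            make_atlas({"A": 10}, {"X": 9})

    def test_default_network_counts_sum(self):
        assert sum(default_network_counts(268).values()) == 268
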