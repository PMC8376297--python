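import numpy as np
import pytest

from conftest import dfs_components
from fcpipe import edges
from fcpipe.synthetic import (
    SimulationConfig,
    plant_edge_set,
    simulate_behavior,
    simulate_cohort,
    simulate_connectomes,
    simulate_timeseries,
)


class TestPlantEdgeSet:
    def test_complete_graph_is_the_only_option(self):
        pairs = plant_edge_set(5, 10, rng_seed=99)
        assert {tuple(p) for p in pairs} == {
            tuple(p) for p in edges.upper_tri_pairs(5)
        }

    def test_planted_subgraph_is_connected(self):
        pairs = plant_edge_set(116, 17, rng_seed=1)
        assert pairs.shape == (17, 2)
        comps = dfs_components(pairs, 116)
        assert len(comps) == 1

    def test_infeasible_count_errors_with_bound(self):
        with pytest.raises(ValueError, match="at most 3"):
            plant_edge_set(3, 4, rng_seed=0)

    @pytest.mark.parametrize("n,m", [(10, 9), (20, 40), (50, 3)])
    def test_connectivity_holds_across_sizes(self, n, m):
        for seed in range(5):
            pairs = plant_edge_set(n, m, rng_seed=seed)
            assert pairs.shape[0] == m
            assert len(dfs_components(pairs, n)) == 1


def _two_group_config(**kw):
    base = dict(
        n_regions=40,
        group_sizes={"HC": 32, "P": 36},
        control_group="HC",
        paired=False,
        n_disrupted_edges=17,
        n_pmn_edges=10,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateConnectomes:
    def test_no_effect_no_noise_gives_identical_matrices(self):
        cfg = _two_group_config(
            delta_z=0.0, noise_sd_z=0.0, subject_strength_sd=0.0
        )
        co = simulate_connectomes(cfg)
        ref = co.subjects[0].matrix.z
        assert all(np.array_equal(s.matrix.z, ref) for s in co.subjects)

    def test_group_difference_recovers_delta_on_planted_edges(self):
        cfg = _two_group_config(delta_z=0.5, noise_sd_z=0.1)
        co = simulate_connectomes(cfg)
        hc = co.edge_matrix("HC", "pre")
        pt = co.edge_matrix("P", "pre")
        idx = edges.pairs_to_index(np.array(co.truth["disrupted_edges"]), 40)
        diff = hc.mean(axis=0) - pt.mean(axis=0)
        se = 0.1 * np.sqrt(1 / 32 + 1 / 36)
        assert np.all(np.abs(diff[idx] - 0.5) < 3 * se)
        off = np.setdiff1d(
            np.setdiff1d(np.arange(diff.size), idx),
            edges.pairs_to_index(np.array(co.truth["pmn_edges"]), 40),
        )
        # off-planted edges: mean difference consistent with zero
        assert np.abs(diff[off]).max() < 5 * se

    def test_paired_sessions_differ_by_delta_on_disrupted_edges(self):
        cfg = SimulationConfig(
            n_regions=30,
            group_sizes={"HC": 4, "P": 20},
            control_group="HC",
            delta_z=0.6,
            noise_sd_z=0.05,
            n_disrupted_edges=8,
            n_pmn_edges=5,
            paired=True,
            seed=2,
        )
        co = simulate_connectomes(cfg)
        pre = co.edge_matrix("P", "pre")
        post = co.edge_matrix("P", "post")
        idx = edges.pairs_to_index(np.array(co.truth["disrupted_edges"]), 30)
        paired_diff = (post - pre)[:, idx].mean()
        se = 0.05 * np.sqrt(2) / np.sqrt(20 * 8)
        assert abs(paired_diff - 0.6) < 4 * se

    def test_seeded_output_is_bit_identical(self):
        cfg = _two_group_config()
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert all(
            np.array_equal(x.matrix.z, y.matrix.z) and x.dst == y.dst and x.nct == y.nct
            for x, y in zip(a.subjects, b.subjects)
        )

    def test_growing_the_cohort_preserves_existing_subjects(self):
        # per-subject RNG streams are keyed by a counter, so adding a group
        # must not reshuffle earlier groups' data
        small = simulate_connectomes(_two_group_config())
        big = simulate_connectomes(
            _two_group_config(group_sizes={"HC": 32, "P": 36, "X": 5})
        )
        for s_small, s_big in zip(small.subjects, big.subjects):
            assert s_small.subject_id == s_big.subject_id
            assert np.array_equal(s_small.matrix.z, s_big.matrix.z)

    def test_matrices_are_symmetric_zero_diagonal(self, small_cohort):
        for s in small_cohort.subjects:
            z = s.matrix.z
            assert np.array_equal(z, z.T)
            assert np.all(np.diag(z) == 0.0)


class TestSimulateBehavior:
    def test_zero_coupling_zero_noise_gives_intercepts(self):
        cfg = _two_group_config(coupling_beta=0.0, behavior_noise_sd=0.0)
        co = simulate_cohort(cfg)
        assert np.allclose(co.scores("dst"), cfg.dst_intercept)
        assert np.allclose(co.scores("nct"), cfg.nct_intercept)

    def test_noiseless_coupling_is_an_exact_linear_map(self):
        cfg = _two_group_config(coupling_beta=10.0, behavior_noise_sd=0.0)
        co = simulate_cohort(cfg)
        idx = edges.pairs_to_index(np.array(co.truth["pmn_edges"]), 40)
        strength = co.edge_matrix()[:, idx].mean(axis=1)
        dst = co.scores("dst")
        nct = co.scores("nct")
        assert np.corrcoef(strength, dst)[0, 1] == pytest.approx(1.0)
        # NCT couples negatively: stronger connectivity, faster completion
        assert np.corrcoef(strength, nct)[0, 1] == pytest.approx(-1.0)

    def test_moderate_noise_gives_expected_correlation(self):
        # behavior noise matched to the signal SD gives R^2 ~ 0.5, r ~ 0.7
        cfg = _two_group_config(
            group_sizes={"HC": 400}, seed=3,
        )
        co = simulate_cohort(cfg)
        idx = edges.pairs_to_index(np.array(co.truth["pmn_edges"]), 40)
        strength = co.edge_matrix()[:, idx].mean(axis=1)
        r = np.corrcoef(strength, co.scores("dst"))[0, 1]
        assert r == pytest.approx(np.sqrt(0.5), abs=0.1)

    def test_empty_pmn_rejected(self):
        cfg = _two_group_config(pmn_edges=np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError):
            simulate_behavior(simulate_connectomes(_two_group_config()), cfg)


class TestSimulateTimeseries:
    def test_output_shape(self):
        cfg = SimulationConfig(
            n_regions=10,
            group_sizes={"HC": 2, "P": 2},
            control_group="HC",
            paired=False,
            n_disrupted_edges=3,
            n_pmn_edges=3,
            timepoints=120,
            seed=4,
        )
        co = simulate_timeseries(cfg)
        for s in co.subjects:
            assert s.timeseries.values.shape == (120, 10)

    def test_null_target_gives_near_zero_correlations(self):
        cfg = SimulationConfig(
            n_regions=8,
            group_sizes={"HC": 2, "P": 2},
            control_group="HC",
            paired=False,
            base_mean_z=0.0,
            base_sd_z=0.0,
            noise_sd_z=0.0,
            subject_strength_sd=0.0,
            delta_z=0.0,
            n_disrupted_edges=2,
            n_pmn_edges=2,
            timepoints=4000,
            seed=5,
        )
        co = simulate_timeseries(cfg)
        r = np.corrcoef(co.subjects[0].timeseries.values, rowvar=False)
        off = r[np.triu_indices(8, 1)]
        assert np.abs(off).max() < 4.0 / np.sqrt(4000)

    def test_empirical_correlation_converges_to_tanh_of_target(self):
        # single planted pair with z = 0.55 -> r = tanh(0.55) ~ 0.50
        errs = []
        for t in (100, 1000, 10000):
            cfg = SimulationConfig(
                n_regions=4,
                group_sizes={"HC": 2, "P": 2},
                control_group="HC",
                paired=False,
                base_mean_z=0.0,
                base_sd_z=0.0,
                noise_sd_z=0.0,
                subject_strength_sd=0.55,  # latent shifts the 1-edge PMN
                delta_z=0.0,
                n_disrupted_edges=1,
                n_pmn_edges=1,
                timepoints=t,
                seed=6,
            )
            co = simulate_timeseries(cfg)
            # target z on the PMN edge of subject 0 = its latent draw
            target = np.tanh(
                np.random.default_rng([6, 1_000_000]).normal(0.0, 0.55)
            )
            i, j = co.truth["pmn_edges"][0]
            emp = np.corrcoef(co.subjects[0].timeseries.values, rowvar=False)[i, j]
            errs.append(abs(emp - target))
        assert errs[-1] < 3.0 / np.sqrt(10000) + 1e-3
        # mean absolute error shrinks as the series lengthens
        assert errs[2] < errs[0]
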