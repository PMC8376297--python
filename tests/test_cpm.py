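import numpy as np
import pytest

from fcpipe import edges
from fcpipe.cpm import (
    apply_network,
    combine_networks,
    cpm_crossval,
    network_strength,
    select_edges,
)
from fcpipe.synthetic import SimulationConfig, simulate_cohort


def _cohort_xy(seed=0, n=32, n_regions=40, **cfg_kw):
    cfg = SimulationConfig(
        n_regions=n_regions,
        group_sizes={"HC": n},
        control_group="HC",
        paired=False,
        n_disrupted_edges=5,
        n_pmn_edges=10,
        seed=seed,
        **cfg_kw,
    )
    co = simulate_cohort(cfg)
    x = co.edge_matrix("HC", "pre")
    return co, x


class TestSelectEdges:
    def test_score_equal_to_an_edge_lands_in_positive_tail(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 50))
        sel = select_edges(x, x[:, 7], threshold_p=0.01)
        assert 7 in sel.positive_edges
        assert sel.p[7] < 1e-20

    def test_null_selection_rate_near_threshold(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 6670))
        y = rng.normal(size=30)
        sel = select_edges(x, y, threshold_p=0.01)
        n_sel = sel.positive_edges.size + sel.negative_edges.size
        # expectation ~ E * threshold = 66.7; generous stochastic band
        assert 20 <= n_sel <= 140

    def test_negating_scores_swaps_tails_exactly(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(25, 200))
        y = rng.normal(size=25)
        a = select_edges(x, y)
        b = select_edges(x, -y)
        assert np.array_equal(a.positive_edges, b.negative_edges)
        assert np.array_equal(a.negative_edges, b.positive_edges)

    def test_tails_are_disjoint(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 300))
        y = x[:, :30].mean(axis=1)
        sel = select_edges(x, y, threshold_p=0.05)
        assert np.intersect1d(sel.positive_edges, sel.negative_edges).size == 0

    def test_constant_edge_skipped(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 10))
        x[:, 5] = 3.0
        sel = select_edges(x, rng.normal(size=20), threshold_p=0.5)
        assert 5 not in sel.positive_edges and 5 not in sel.negative_edges
        assert np.isnan(sel.r[5])


class TestNetworkStrength:
    def test_single_edge(self):
        v = np.zeros(10)
        v[4] = 0.7
        assert network_strength(v, [4]) == pytest.approx(0.7)

    def test_mean_of_edges(self):
        v = np.array([0.2, 0.4, 0.6, 9.9])
        assert network_strength(v, [0, 1, 2]) == pytest.approx(0.4)

    def test_linear_in_matrix_scale(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 15))
        idx = [0, 3, 7]
        assert np.allclose(
            network_strength(3.0 * x, idx), 3.0 * network_strength(x, idx)
        )

    def test_empty_edge_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            network_strength(np.zeros(10), [])


class TestCrossval:
    def test_noiseless_linear_coupling_recovered(self):
        co, x = _cohort_xy(seed=1, behavior_noise_sd=0.0, noise_sd_z=0.0)
        y = co.scores("dst")
        res = cpm_crossval(x, y, k=5, tail="positive", seed=1)
        assert res.r_pred_obs >= 0.99

    def test_every_subject_predicted_exactly_once(self):
        co, x = _cohort_xy(seed=2)
        y = co.scores("dst")
        res = cpm_crossval(x, y, k=5, seed=0)
        assert np.isfinite(res.predictions).all()
        seen = np.concatenate([f.test_ids for f in res.folds])
        assert sorted(seen.tolist()) == list(range(32))

    def test_leave_one_out_accepted(self):
        co, x = _cohort_xy(seed=3, n=12)
        y = co.scores("dst")
        res = cpm_crossval(x, y, k=12, seed=0)
        assert np.isfinite(res.predictions).all()

    def test_consensus_is_subset_of_every_fold(self):
        co, x = _cohort_xy(seed=4)
        y = co.scores("dst")
        res = cpm_crossval(x, y, k=5, seed=1)
        for f in res.folds:
            assert set(res.consensus_positive) <= set(f.selection.positive_edges)
            assert set(res.consensus_negative) <= set(f.selection.negative_edges)

    def test_prediction_invariant_to_affine_connectome_rescaling(self):
        co, x = _cohort_xy(seed=5)
        y = co.scores("dst")
        r1 = cpm_crossval(x, y, k=5, seed=2).r_pred_obs
        r2 = cpm_crossval(2.5 * x, y, k=5, seed=2).r_pred_obs
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_sign_convention_dst_positive_nct_negative(self):
        # the generator couples DST positively and NCT negatively to
        # psychomotor-network strength, so selected edges land in the
        # matching tails
        co, x = _cohort_xy(seed=6, behavior_noise_sd=2.0)
        pmn_idx = set(
            edges.pairs_to_index(np.array(co.truth["pmn_edges"]), 40).tolist()
        )
        res_dst = cpm_crossval(x, co.scores("dst"), k=5, tail="positive", seed=0)
        res_nct = cpm_crossval(x, co.scores("nct"), k=5, tail="negative", seed=0)
        assert pmn_idx <= set(res_dst.consensus_positive.tolist())
        assert pmn_idx <= set(res_nct.consensus_negative.tolist())

    def test_empty_tail_fold_predicts_train_mean(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        res = cpm_crossval(x, y, k=5, threshold_p=1e-12, seed=0)
        assert all(f.used_train_mean for f in res.folds)
        for f in res.folds:
            assert np.allclose(res.predictions[f.test_ids], y[f.train_ids].mean())


class TestCombineNetworks:
    def test_disjoint_six_and_twelve_make_eighteen(self):
        a = np.arange(6)
        b = np.arange(10, 22)
        net = combine_networks(a, b, n_regions=30)
        assert net.size == 18
        assert all(net.provenance[int(e)] == "from-a" for e in a)
        assert all(net.provenance[int(e)] == "from-b" for e in b)

    def test_identical_sets_collapse(self):
        a = np.array([1, 5, 9])
        net = combine_networks(a, a, n_regions=10)
        assert net.size == 3
        assert all(v == "both" for v in net.provenance.values())

    def test_empty_set_is_identity(self):
        b = np.array([2, 4])
        net = combine_networks(np.empty(0, dtype=int), b, n_regions=10)
        assert np.array_equal(net.edge_index, b)

    def test_node_degrees_reported(self):
        # edges (0,1) and (0,2) -> node 0 has degree 2
        idx = edges.pairs_to_index(np.array([[0, 1], [0, 2]]), 5)
        net = combine_networks(idx, np.empty(0, dtype=int), n_regions=5)
        assert net.node_degrees()[0] == 2


class TestApplyNetwork:
    def test_exact_linear_map_recovered(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(15, 20))
        idx = np.array([0, 4, 9])
        s = x[:, idx].mean(axis=1)
        y = 2.0 * s + 5.0
        res = apply_network(x, idx, y)
        assert res.r == pytest.approx(1.0)
        assert res.beta == pytest.approx(2.0)

    def test_f_statistic_identity(self):
        # F = (n-2) r^2 / (1 - r^2) with df (1, n-2)
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=(n, 12))
            idx = np.array([1, 3])
            y = rng.normal(size=n)
            res = apply_network(x, idx, y)
            expected = (n - 2) * res.r**2 / (1 - res.r**2)
            assert res.F == pytest.approx(expected, rel=1e-10)
            assert res.df == (1, n - 2)

    def test_null_calibration_of_f_test(self):
        # with no true coupling, p is uniform: ~5% of runs below 0.05
        rng = np.random.default_rng(10)
        rejections = 0
        runs = 400
        for _ in range(runs):
            x = rng.normal(size=(23, 10))
            y = rng.normal(size=23)
            res = apply_network(x, np.array([0, 1, 2]), y)
            rejections += res.p < 0.05
        assert 0.02 <= rejections / runs <= 0.08

    def test_zero_strength_variance_rejected(self):
        x = np.ones((10, 5))
        with pytest.raises(ValueError, match="variance"):
            apply_network(x, np.array([0]), np.arange(10.0))
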