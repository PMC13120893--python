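"""Variance-peak subsampling, L1 k-means, elbow selection, temporal metrics
and centroid summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynconn import (
    ClusterConfig,
    DynamicConnectome,
    assign_all_windows,
    cohort_temporal_metrics,
    elbow_select,
    fit_state_model,
    kmeans_l1,
    match_centroids,
    temporal_metrics,
    top_edges,
)
from dynconn.states import (
    centroid_contrasts,
    cluster_validity_index,
    group_centroids,
    icc_2_1,
    subsample_variance_peaks,
    upper_tri_vec,
    vec_to_matrix,
)


def _dc_from_variance(var_values, n_nodes=4, subject_id="s"):
    """Build a stack whose per-window upper-triangle variance follows
    ``var_values`` (scaling a fixed random pattern)."""
    rng = np.random.default_rng(0)
    E = n_nodes * (n_nodes - 1) // 2
    base = rng.normal(size=E)
    base = (base - base.mean()) / base.std()
    stack = np.stack([
        vec_to_matrix(np.sqrt(v) * base, n_nodes) for v in var_values
    ])
    return DynamicConnectome(subject_id, stack, np.arange(len(var_values)), 3, 0.1)


class TestSubsample:
    def test_interior_local_maxima(self):
        dc = _dc_from_variance([1, 3, 2, 5, 4])
        np.testing.assert_array_equal(subsample_variance_peaks(dc), [1, 3])

    def test_monotone_series_falls_back_to_all(self):
        dc = _dc_from_variance([1, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="no interior variance peaks"):
            idx = subsample_variance_peaks(dc)
        np.testing.assert_array_equal(idx, np.arange(5))

    def test_plateau_contributes_first_index(self):
        dc = _dc_from_variance([1, 4, 4, 4, 2, 1])
        np.testing.assert_array_equal(subsample_variance_peaks(dc), [1])

    def test_subsample_much_smaller_than_windows(self, tiny_connectomes):
        _, dcs, _ = tiny_connectomes
        for dc in dcs:
            idx = subsample_variance_peaks(dc)
            assert 0 < len(idx) < dc.n_windows / 2


class TestKmeansL1:
    def test_k1_centroid_is_median(self, rng):
        X = rng.normal(size=(40, 7))
        centroids, labels, _ = kmeans_l1(X, 1, n_replicates=3, seed=0)
        np.testing.assert_allclose(centroids[0], np.median(X, axis=0))

    def test_separated_blobs_recovered(self, rng):
        a = rng.normal(0.0, 0.2, size=(60, 5))
        b = rng.normal(4.0, 0.2, size=(60, 5))
        X = np.vstack([a, b])
        centroids, labels, _ = kmeans_l1(X, 2, n_replicates=10, seed=1)
        meds = np.sort([np.median(a, axis=0)[0], np.median(b, axis=0)[0]])
        got = np.sort(centroids[:, 0])
        assert np.abs(np.sort(centroids, axis=0) -
                      np.sort(np.vstack([np.median(a, 0), np.median(b, 0)]), axis=0)
                      ).max() < 0.1

    def test_identical_point_groups_zero_inertia(self):
        X = np.repeat(np.eye(3), 5, axis=0)
        _, _, inertia = kmeans_l1(X, 3, n_replicates=10, seed=2)
        assert inertia == 0.0

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 6))
        a = kmeans_l1(X, 3, n_replicates=5, seed=7)
        b = kmeans_l1(X, 3, n_replicates=5, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[2] == b[2]

    def test_best_inertia_non_increasing_in_replicates(self, rng):
        X = rng.normal(size=(80, 6))
        inertias = [kmeans_l1(X, 4, n_replicates=n, seed=3)[2]
                    for n in (1, 5, 20)]
        assert inertias[0] >= inertias[1] >= inertias[2]

    def test_more_exemplars_than_k_required(self, rng):
        with pytest.raises(ValueError):
            kmeans_l1(rng.normal(size=(2, 4)), 3)


class TestElbow:
    def test_second_difference_arithmetic(self):
        curve = {2: 10.0, 3: 4.0, 4: 3.5, 5: 3.3, 6: 3.2}
        assert elbow_select(curve) == 3

    def test_linear_curve_warns_smallest_k(self):
        curve = {k: 10.0 - k for k in range(2, 7)}
        with pytest.warns(UserWarning, match="no knee"):
            assert elbow_select(curve) == 2

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            elbow_select({2: 1.0, 3: 0.5})


class TestAssignment:
    def test_window_equal_to_centroid(self):
        centroids = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        dc = DynamicConnectome("s", np.stack([vec_to_matrix(c, 3) for c in centroids]),
                               np.arange(2), 2, 0.1)
        vecs = assign_all_windows([dc], centroids)
        np.testing.assert_array_equal(vecs["s"], [1, 2])

    def test_equidistant_tie_goes_to_lowest_index(self):
        centroids = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        mid = vec_to_matrix(np.full(3, 0.5), 3)
        dc = DynamicConnectome("s", mid[None], np.arange(1), 2, 0.1)
        assert assign_all_windows([dc], centroids)["s"][0] == 1


class TestTemporalMetrics:
    def test_single_state_occupancy(self):
        fw, mdt, nt = temporal_metrics(np.array([3, 3, 3, 3]), k=4)
        assert fw[2] == 100.0 and nt == 0
        assert mdt[2] == 4.0
        assert np.isnan(mdt[[0, 1, 3]]).all()
        assert fw[[0, 1, 3]].sum() == 0.0

    def test_run_length_enumeration(self):
        fw, mdt, nt = temporal_metrics(np.array([1, 1, 2, 2, 2, 1]), k=2)
        assert fw[0] == 50.0 and fw[1] == 50.0
        assert mdt[0] == 1.5 and mdt[1] == 3.0
        assert nt == 2

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            temporal_metrics(np.array([1, 5]), k=4)

    @given(st.lists(st.integers(1, 4), min_size=1, max_size=200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identities_for_any_sequence(self, labels):
        s = np.array(labels)
        W = len(s)
        fw, mdt, nt = temporal_metrics(s, k=4)
        assert fw.sum() == pytest.approx(100.0, abs=1e-9)
        runs = np.count_nonzero(np.diff(s)) + 1
        assert nt == runs - 1
        assert nt <= W - 1
        # FW_s * W / 100 == (#runs of s) * MDT_s, exactly per state
        boundaries = np.flatnonzero(np.diff(s)) + 1
        starts = np.r_[0, boundaries]
        run_states = s[starts]
        for state in range(1, 5):
            n_runs = np.count_nonzero(run_states == state)
            if n_runs:
                assert fw[state - 1] * W / 100 == pytest.approx(
                    n_runs * mdt[state - 1], abs=1e-9
                )
            else:
                assert np.isnan(mdt[state - 1])

    def test_cohort_frame_shapes(self):
        vecs = {"a": np.array([1, 2, 2]), "b": np.array([2, 2, 2])}
        m = cohort_temporal_metrics(vecs, k=3)
        assert m.fw.shape == (2, 3)
        assert m.nt["a"] == 1 and m.nt["b"] == 0
        np.testing.assert_allclose(m.fw.sum(axis=1), 100.0)

    def test_mdt_seconds_conversion(self):
        m = cohort_temporal_metrics({"a": np.array([1, 1, 2])}, k=2)
        sec = m.mdt_seconds(tr_seconds=0.72, step=1)
        assert sec.loc["a", 1] == pytest.approx(2 * 0.72)


class TestCentroidSummaries:
    def test_identical_centroids_zero_diff_full_similarity(self):
        from dynconn.states import StateModel

        c = np.random.default_rng(1).normal(size=45)
        model = StateModel(2, np.vstack([c, c]), 10, {}, {}, {}, 0.0)
        diffs, sim = centroid_contrasts(model)
        assert np.abs(diffs[(1, 2)]).max() == 0.0
        assert sim.loc[1, 2] == pytest.approx(1.0)

    def test_antisymmetric_differences(self, rng):
        from dynconn.states import StateModel

        C = rng.normal(size=(3, 45))
        model = StateModel(3, C, 10, {}, {}, {}, 0.0)
        diffs, _ = centroid_contrasts(model)
        np.testing.assert_array_equal(diffs[(1, 2)], -diffs[(2, 1)])

    def test_random_high_dim_centroids_nearly_orthogonal(self, rng):
        from dynconn.states import StateModel

        C = rng.normal(size=(2, 903))  # edge count for 43 nodes
        model = StateModel(2, C, 43, {}, {}, {}, 0.0)
        _, sim = centroid_contrasts(model)
        assert abs(sim.loc[1, 2]) < 0.1

    def test_top_edges_fraction_one_returns_all(self, rng):
        cent = rng.normal(size=45)
        assert len(top_edges(cent, 1.0, 10)) == 45

    def test_top_edges_ceiling_count(self, rng):
        cent = rng.normal(size=903)
        assert len(top_edges(cent, 0.05, 43)) == 46  # ceil(0.05 * 903)

    def test_top_edges_tie_break_index_order(self):
        cent = np.ones(6)
        edges = top_edges(cent, 0.5, 4)  # ceil(3) of 6 equal edges
        np.testing.assert_array_equal(edges["node_i"], [1, 1, 1])
        np.testing.assert_array_equal(edges["node_j"], [2, 3, 4])

    def test_top_edges_ranked_by_magnitude_with_sign(self):
        cent = np.array([0.1, -0.9, 0.5, -0.2, 0.05, 0.3])
        edges = top_edges(cent, 0.34, 4)  # top 3
        np.testing.assert_allclose(edges["z"], [-0.9, 0.5, 0.3])


class TestGroupCentroids:
    def test_identical_subjects_full_agreement(self, rng):
        stack = np.stack([vec_to_matrix(rng.normal(size=45), 10)
                          for _ in range(6)])
        dcs = [DynamicConnectome(s, stack.copy(), np.arange(6), 3, 0.1)
               for s in ("a", "b")]
        vec = np.array([1, 1, 2, 2, 1, 2])
        svs = {"a": vec, "b": vec}
        cents, agree = group_centroids(dcs, svs, {"a": "g1", "b": "g2"}, k=2)
        for st_ in (1, 2):
            assert agree[st_].loc["g1", "g2"] == pytest.approx(1.0)

    def test_unvisited_state_excluded_from_group_mean(self, rng):
        stack = np.stack([vec_to_matrix(rng.normal(size=45), 10)
                          for _ in range(4)])
        dcs = [DynamicConnectome("a", stack, np.arange(4), 3, 0.1),
               DynamicConnectome("b", stack, np.arange(4), 3, 0.1)]
        svs = {"a": np.array([1, 1, 1, 1]), "b": np.array([1, 2, 1, 2])}
        cents, _ = group_centroids(dcs, svs, {"a": "g", "b": "g"}, k=2)
        # state 2 mean must come from subject b alone
        expected = upper_tri_vec(stack[[1, 3]]).mean(axis=0)
        np.testing.assert_allclose(cents["g"][1], expected)

    def test_icc_perfect_agreement(self):
        x = np.linspace(0, 1, 50)
        assert icc_2_1(np.column_stack([x, x])) == pytest.approx(1.0)


class TestValidityIndex:
    def test_tight_clusters_score_low(self, rng):
        centers = np.array([[0.0] * 4, [5.0] * 4])
        X = np.vstack([c + 0.01 * rng.normal(size=(30, 4)) for c in centers])
        labels = np.repeat([0, 1], 30)
        cvi = cluster_validity_index(X, centers, labels)
        assert cvi < 0.05


class TestRobustnessOverK:
    def test_alternative_cluster_numbers(self, tiny_connectomes):
        from dynconn import planted_z_patterns
        from dynconn.states import robustness_over_k

        cfg, dcs, _ = tiny_connectomes
        ccfg = ClusterConfig(k_range=(2, 6), n_replicates=10, seed=0)
        primary = fit_state_model(dcs, ccfg, k_fixed=4)
        out = robustness_over_k(dcs, ccfg, [3, 4, 5], primary)
        ref = planted_z_patterns(cfg)

        # same k and seed policy -> identical model
        np.testing.assert_allclose(
            out[4]["primary_match"]["similarity"], 1.0, atol=1e-12
        )
        # over-clustering refines: every planted state keeps a close centroid
        m5 = match_centroids(out[5]["model"].centroids, ref)
        assert (m5["similarity"] > 0.8).all()
        # under-clustering merges: some planted state loses its match
        m3 = match_centroids(out[3]["model"].centroids, ref)
        assert (m3["similarity"] < 0.8).any()
        # metrics recomputed per k
        assert out[3]["metrics"].fw.shape[1] == 3


class TestEndToEndRecovery:
    def test_planted_states_recovered(self, tiny_connectomes):
        cfg, dcs, truth = tiny_connectomes
        from dynconn import planted_z_patterns

        model = fit_state_model(
            dcs, ClusterConfig(k_range=(2, 6), n_replicates=10, seed=0)
        )
        assert model.k == 4
        matches = match_centroids(model.centroids, planted_z_patterns(cfg))
        assert (matches["similarity"] > 0.8).all()
        # all four planted states matched by distinct centroids
        assert matches["best_centroid"].nunique() == 4
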