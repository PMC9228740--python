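"""CAMs, affinity graphs and random-walk region correction."""

import numpy as np
import pytest

import bloomspec as bs
from bloomspec import affinity as aff


class TestComputeCam:
    def test_one_hot_weight_projects_single_channel(self):
        rng = np.random.default_rng(0)
        feats = rng.random((4, 5, 3))
        w = np.array([[0.0, 1.0, 0.0]])
        cams = aff.compute_cam(feats, w)
        expected = feats[:, :, 1] / feats[:, :, 1].max()
        np.testing.assert_allclose(cams.maps[0], expected)

    def test_zero_weights_give_zero_map(self):
        feats = np.ones((3, 3, 4))
        cams = aff.compute_cam(feats, np.zeros((2, 4)))
        np.testing.assert_array_equal(cams.maps, 0.0)

    def test_hand_dot_products(self):
        # four pixels with features (1,0), (0,1), (1,1), (0,0); W = (1,1)
        feats = np.array([[[1, 0], [0, 1]], [[1, 1], [0, 0]]], dtype=float)
        cams = aff.compute_cam(feats, np.array([[1.0, 1.0]]))
        np.testing.assert_allclose(
            cams.maps[0], [[0.5, 0.5], [1.0, 0.0]]
        )  # raw [1,1,2,0] max-normalized

    def test_negative_activations_clipped(self):
        feats = np.full((2, 2, 1), -3.0)
        cams = aff.compute_cam(feats, np.array([[1.0]]))
        np.testing.assert_array_equal(cams.maps, 0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aff.compute_cam(np.ones((2, 2, 3)), np.ones((1, 4)))


class TestAffinityLabels:
    def test_uniform_raster_all_ones(self, scheme):
        labels = bs.LabelRaster(data=np.zeros((4, 4), int), scheme=scheme)
        g = aff.affinity_labels(labels, radius=1)
        assert g.n_edges == 2 * 4 * 3  # horizontal + vertical 4-neighbour pairs
        np.testing.assert_array_equal(g.weights, 1.0)

    def test_checkerboard_radius_one_all_zero(self, scheme):
        ii, jj = np.indices((6, 6))
        board = ((ii + jj) % 2).astype(int)  # water / bloom checkerboard
        labels = bs.LabelRaster(data=board, scheme=scheme)
        g = aff.affinity_labels(labels, radius=1)
        # brute force over all within-radius pairs
        flat = board.ravel()
        expected = (flat[g.edges_i] == flat[g.edges_j]).astype(float)
        np.testing.assert_array_equal(g.weights, expected)
        np.testing.assert_array_equal(g.weights, 0.0)

    def test_pairs_touching_ignore_dropped(self, scheme):
        data = np.zeros((3, 3), int)
        data[1, 1] = scheme.ignore_index
        labels = bs.LabelRaster(data=data, scheme=scheme)
        g = aff.affinity_labels(labels, radius=1)
        centre = 4  # flat index of (1,1)
        assert centre not in g.edges_i and centre not in g.edges_j

    def test_radius_below_one_rejected(self, scheme):
        labels = bs.LabelRaster(data=np.zeros((3, 3), int), scheme=scheme)
        with pytest.raises(ValueError):
            aff.affinity_labels(labels, radius=0.5)

    def test_graph_symmetric_no_self_edges(self, scheme):
        rng = np.random.default_rng(1)
        labels = bs.LabelRaster(
            data=rng.integers(0, 3, (5, 5)), scheme=scheme
        )
        g = aff.affinity_labels(labels, radius=2)
        assert np.all(g.edges_i < g.edges_j)
        a = g.to_sparse()
        assert (a != a.T).nnz == 0


class TestPredictAffinity:
    def test_identical_features_give_unit_affinity(self):
        g = aff.predict_affinity(np.full((4, 4, 2), 0.7), radius=2, beta=2)
        np.testing.assert_allclose(g.weights, 1.0)

    def test_large_beta_drives_distinct_features_to_zero(self):
        feats = np.zeros((2, 2, 1))
        feats[0, 0] = 5.0
        g_small = aff.predict_affinity(feats, radius=1, beta=1)
        g_large = aff.predict_affinity(feats, radius=1, beta=50)
        mixed = g_small.weights < 1.0
        assert np.all(g_large.weights[mixed] < 1e-12)
        assert np.all(g_large.weights[mixed] < g_small.weights[mixed])

    def test_within_cluster_beats_cross_cluster(self):
        feats = np.zeros((4, 4, 1))
        feats[:, 2:] = 1.0  # two feature clusters, left/right
        g = aff.predict_affinity(feats, radius=1, beta=2)
        flat = feats.reshape(-1)
        same = flat[g.edges_i] == flat[g.edges_j]
        assert g.weights[same].min() > g.weights[~same].max()


class TestRandomWalkRefine:
    def _chain_graph(self):
        """3-pixel chain (1x3 raster) with uniform unit affinities."""
        return aff.AffinityGraph(
            shape=(1, 3),
            edges_i=np.array([0, 1]),
            edges_j=np.array([1, 2]),
            weights=np.array([1.0, 1.0]),
            radius=1.0,
        )

    def test_transition_rows_sum_to_one(self, scheme):
        rng = np.random.default_rng(2)
        labels = bs.LabelRaster(data=rng.integers(0, 3, (6, 6)), scheme=scheme)
        t = aff.transition_matrix(aff.affinity_labels(labels, radius=2))
        np.testing.assert_allclose(np.asarray(t.sum(axis=1)).ravel(), 1.0)

    def test_zero_iterations_identity(self):
        rng = np.random.default_rng(3)
        cams = aff.CAMStack.from_raw(rng.random((2, 1, 3)))
        out = aff.random_walk_refine(cams, self._chain_graph(), iterations=0)
        np.testing.assert_array_equal(out.maps, cams.maps)

    def test_edgeless_graph_identity_for_any_t(self):
        g = aff.AffinityGraph(
            shape=(2, 2), edges_i=np.empty(0, int), edges_j=np.empty(0, int),
            weights=np.empty(0), radius=1.0,
        )
        rng = np.random.default_rng(4)
        cams = aff.CAMStack.from_raw(rng.random((3, 2, 2)))
        out = aff.random_walk_refine(cams, g, iterations=7)
        np.testing.assert_allclose(out.maps, cams.maps)

    def test_chain_converges_to_uniform(self):
        # one-hot activation diffused forever over a connected chain ends up
        # spatially uniform (right eigenvector of a row-stochastic matrix);
        # the level is the stationary-weighted mean: degrees with self-loops
        # are (2, 3, 2), so pi = (2, 3, 2)/7 and the limit is pi . (1,0,0) = 2/7
        cams = aff.CAMStack(maps=np.array([[[1.0, 0.0, 0.0]]]))
        out = aff.random_walk_refine(cams, self._chain_graph(), iterations=200)
        assert np.ptp(out.maps) < 1e-12
        np.testing.assert_allclose(out.maps, 2.0 / 7.0, atol=1e-10)

    def test_preserves_nonnegativity(self):
        rng = np.random.default_rng(5)
        cams = aff.CAMStack.from_raw(rng.random((2, 4, 4)))
        g = aff.predict_affinity(rng.random((4, 4, 2)), radius=2, beta=2)
        out = aff.random_walk_refine(cams, g, iterations=5)
        assert out.maps.min() >= 0.0

    def test_mass_conserved_on_degree_regular_graph(self):
        # complete uniform graph: every degree equal, so the row-stochastic
        # transition is doubly stochastic and diffusion conserves class mass
        n = 4 * 4
        i, j = np.triu_indices(n, k=1)
        g = aff.AffinityGraph(
            shape=(4, 4), edges_i=i, edges_j=j,
            weights=np.ones(i.size), radius=10.0,
        )
        rng = np.random.default_rng(6)
        raw = rng.random((3, 4, 4))
        t = aff.transition_matrix(g)
        m = raw.reshape(3, -1).T
        for _ in range(4):
            m = t @ m
        np.testing.assert_allclose(m.sum(axis=0), raw.reshape(3, -1).sum(axis=1))

    def test_shape_mismatch_rejected(self):
        cams = aff.CAMStack(maps=np.ones((1, 2, 2)))
        with pytest.raises(ValueError):
            aff.random_walk_refine(cams, self._chain_graph(), iterations=1)


class TestSynthesizeLabels:
    def test_single_full_activation_uniform_raster(self, scheme):
        maps = np.zeros((scheme.n_scored, 3, 3))
        maps[1] = 1.0  # bloom map everywhere
        out = aff.synthesize_labels(aff.CAMStack(maps=maps), scheme)
        np.testing.assert_array_equal(out.data, scheme.bloom_index)

    def test_all_below_threshold_all_ignore(self, scheme):
        maps = np.full((scheme.n_scored, 3, 3), 0.05)
        out = aff.synthesize_labels(
            aff.CAMStack(maps=maps), scheme, background_threshold=0.2
        )
        np.testing.assert_array_equal(out.data, scheme.ignore_index)

    def test_two_class_blob_partition_recovered(self, scheme):
        rng = np.random.default_rng(7)
        truth = np.zeros((8, 8), int)
        truth[2:6, 2:6] = scheme.bloom_index
        maps = np.zeros((scheme.n_scored, 8, 8))
        maps[0] = (truth == 0) * rng.uniform(0.5, 1.0, (8, 8))
        maps[1] = (truth == scheme.bloom_index) * rng.uniform(0.5, 1.0, (8, 8))
        out = aff.synthesize_labels(
            aff.CAMStack.from_raw(maps), scheme, background_threshold=0.2
        )
        np.testing.assert_array_equal(out.data, truth)


class TestRefinementImprovesLabels:
    @pytest.mark.parametrize("seed", range(20))
    def test_gt_affinity_never_hurts_bloom_iou(self, seed, scheme):
        """Diffusing noisy CAMs along ground-truth affinities can only help."""
        cfg = bs.SceneConfig(height=24, width=24, bank_fraction=0.0,
                             boat_count=0, salt_pepper_density=0.0,
                             gaussian_sigma=0.0, seed=seed)
        _, labels = bs.generate_scene(cfg)
        rng = np.random.default_rng(seed + 1000)
        scored = [i for i in range(scheme.n_classes) if i != scheme.ignore_index]
        onehot = np.stack([(labels.data == c).astype(float) for c in scored])
        noisy = np.clip(onehot + 0.45 * rng.standard_normal(onehot.shape), 0, None)
        cams = aff.CAMStack.from_raw(noisy)
        graph = aff.affinity_labels(labels, radius=2)

        def bloom_iou(lr):
            c = bs.confusion(lr, labels, scheme.bloom_index)
            return bs.iou(c)

        raw_labels = aff.synthesize_labels(cams, scheme, background_threshold=0.0)
        refined = aff.random_walk_refine(cams, graph, iterations=4)
        ref_labels = aff.synthesize_labels(refined, scheme, background_threshold=0.0)
        assert bloom_iou(ref_labels) >= bloom_iou(raw_labels)
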