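import numpy as np
import pytest

from graphdec._autodiff import Tensor
from graphdec.gnn_core import (GnnModelState, deconv_head, deconv_head_numpy,
                               domain_discriminator, fuse_layers, gnn_forward,
                               init_gnn, multi_channel_forward,
                               normalized_adjacency, sage_aggregate,
                               sage_update)
from graphdec.graphs import SimilarityGraph, build_knn_graph


@pytest.fixture
def path_graph():
    # 0 - 1 - 2 chain with unit weights
    return SimilarityGraph(["a", "b", "c"], ["reference"] * 3,
                           [(0, 1, 1.0), (1, 2, 1.0)], "reference", 1)


class TestSageAggregate:
    def test_single_neighbor_identity(self, path_graph):
        H = np.array([[0.0, 0.0], [2.0, 4.0], [0.0, 0.0]])
        np.testing.assert_allclose(sage_aggregate(0, path_graph, H), [2.0, 4.0])

    def test_two_neighbor_mean(self, path_graph):
        H = np.array([[0.0, 0.0], [9.0, 9.0], [2.0, 2.0]])
        np.testing.assert_allclose(sage_aggregate(1, path_graph, H), [1.0, 1.0])

    def test_weighted_mean_uses_edge_weights(self):
        g = SimilarityGraph(["a", "b", "c"], ["reference"] * 3,
                            [(0, 1, 3.0), (0, 2, 1.0), (1, 2, 1.0)],
                            "reference", 1)
        H = np.array([[0.0], [4.0], [8.0]])
        # node 0: (3*4 + 1*8) / 4 = 5
        np.testing.assert_allclose(sage_aggregate(0, g, H), [5.0])
        np.testing.assert_allclose(sage_aggregate(0, g, H, weighted=False),
                                   [6.0])

    def test_matches_explicit_neighbor_loop(self, rng):
        g = build_knn_graph(rng.normal(size=(12, 4)), k=3)
        H = rng.normal(size=(12, 5))
        for v in range(12):
            nbrs = [(j, w) for i, j, w in g.edges if i == v]
            nbrs += [(i, w) for i, j, w in g.edges if j == v]
            expected = sum(w * H[u] for u, w in nbrs) / sum(w for _, w in nbrs)
            np.testing.assert_allclose(sage_aggregate(v, g, H), expected,
                                       atol=1e-10)


class TestSageUpdate:
    def test_zero_weight_matrix(self):
        out = sage_update(np.ones(3), np.ones(3), np.zeros((4, 6)))
        np.testing.assert_array_equal(out, np.zeros(4))

    def test_self_block_identity(self):
        W = np.hstack([np.eye(3), np.zeros((3, 3))])
        h = np.array([1.0, 0.5, 2.0])
        np.testing.assert_allclose(sage_update(h, np.full(3, -9.0), W), h)

    def test_matches_concat_matmul_relu(self, rng):
        h_self, h_agg = rng.normal(size=(2, 4))
        W = rng.normal(size=(3, 8))
        expected = np.maximum(W @ np.concatenate([h_self, h_agg]), 0.0)
        np.testing.assert_allclose(sage_update(h_self, h_agg, W), expected)


class TestFuseLayers:
    def test_paper_figure_weights(self):
        out = fuse_layers([np.array([1.0, 0.0]), np.array([0.0, 1.0])],
                          np.array([0.7, 0.3]))
        np.testing.assert_allclose(out, [0.7, 0.3])

    def test_degenerate_weight_selects_layer(self, rng):
        h1, h2 = rng.normal(size=(2, 6))
        np.testing.assert_allclose(
            fuse_layers([h1, h2], np.array([1.0, 0.0])), h1)

    def test_convex_combination_bounds(self, rng):
        h1, h2 = rng.normal(size=(2, 8))
        s = rng.dirichlet([1, 1])
        out = fuse_layers([h1, h2], s)
        lo, hi = np.minimum(h1, h2), np.maximum(h1, h2)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_rejects_off_simplex_weights(self, rng):
        with pytest.raises(ValueError):
            fuse_layers([np.ones(2), np.ones(2)], np.array([0.9, 0.3]))


class TestMultiChannelForward:
    def test_single_channel_equals_fused(self, rng):
        g = build_knn_graph(rng.normal(size=(8, 3)), k=2)
        X = rng.uniform(size=(8, 3))
        state = init_gnn(3, 2, hidden_dim=5, n_channels=1, seed=0)
        emb = multi_channel_forward(X, g, state)
        np.testing.assert_array_equal(emb.Z_GNN, emb.fused[0])

    def test_zeroed_channel_gives_zero_block(self, rng):
        g = build_knn_graph(rng.normal(size=(8, 3)), k=2)
        X = rng.uniform(size=(8, 3))
        state = init_gnn(3, 2, hidden_dim=5, n_channels=2, seed=0)
        for W in state.channels[1].W:
            W.data = np.zeros_like(W.data)
        emb = multi_channel_forward(X, g, state)
        np.testing.assert_array_equal(emb.Z_GNN[:, 5:], 0.0)
        assert np.any(emb.Z_GNN[:, :5] != 0.0)

    def test_equals_per_node_oracle(self, rng):
        """Full multi-channel forward reproduced by per-node loops built
        from the reference operations (aggregate, update, fuse)."""
        g = build_knn_graph(rng.normal(size=(9, 4)), k=3)
        X = rng.uniform(size=(9, 4))
        state = init_gnn(4, 2, hidden_dim=6, n_channels=3, seed=1)
        emb = multi_channel_forward(X, g, state)
        for c, ch in enumerate(state.channels):
            H = X.copy()
            for layer, W in enumerate(ch.W):
                H_next = np.empty((9, 6))
                for v in range(9):
                    agg = sage_aggregate(v, g, H)
                    H_next[v] = sage_update(H[v], agg, W.data)
                H = H_next
                np.testing.assert_allclose(emb.per_layer[c][layer], H,
                                           atol=1e-8)

    def test_channel_concatenation_matches_singles(self, rng):
        """C=3 output equals three independent single-channel forwards."""
        g = build_knn_graph(rng.normal(size=(7, 3)), k=2)
        X = rng.uniform(size=(7, 3))
        state = init_gnn(3, 2, hidden_dim=4, n_channels=3, seed=5)
        emb = multi_channel_forward(X, g, state)
        for c in range(3):
            single = GnnModelState(
                channels=[state.channels[c]], head_W1=state.head_W1,
                head_b1=state.head_b1, head_W2=state.head_W2,
                head_b2=state.head_b2, disc_W1=state.disc_W1,
                disc_b1=state.disc_b1, disc_W2=state.disc_W2,
                disc_b2=state.disc_b2, input_dim=3, n_types=2, hidden_dim=4)
            part = multi_channel_forward(X, g, single)
            np.testing.assert_allclose(emb.Z_GNN[:, 4 * c:4 * (c + 1)],
                                       part.Z_GNN, atol=1e-12)

    def test_row_mismatch_raises(self, rng):
        g = build_knn_graph(rng.normal(size=(5, 3)), k=2)
        state = init_gnn(3, 2, hidden_dim=4, n_channels=1)
        with pytest.raises(ValueError):
            multi_channel_forward(rng.uniform(size=(6, 3)), g, state)

    def test_permutation_equivariance(self, rng):
        Z_lat = rng.normal(size=(10, 3))
        X = rng.uniform(size=(10, 3)).astype(np.float64)
        perm = rng.permutation(10)
        state = init_gnn(3, 2, hidden_dim=4, n_channels=2, seed=2)
        g = build_knn_graph(Z_lat, k=3)
        emb = multi_channel_forward(X, g, state)
        gp = build_knn_graph(Z_lat[perm], k=3)
        emb_p = multi_channel_forward(X[perm], gp, state)
        np.testing.assert_allclose(emb_p.Z_GNN, emb.Z_GNN[perm], atol=1e-8)


class TestHeads:
    def test_uniform_logits_give_uniform_proportions(self):
        state = init_gnn(3, 4, hidden_dim=4, n_channels=1, seed=0)
        # zero-initialized final layer -> all logits equal -> uniform
        out = deconv_head(state, np.ones((2, 4))).data
        np.testing.assert_allclose(out, 0.25)

    def test_dominant_logit_near_one_hot(self):
        state = init_gnn(3, 3, hidden_dim=4, n_channels=1, seed=0)
        state.head_W1.data = np.zeros_like(state.head_W1.data)
        state.head_b1.data = np.ones_like(state.head_b1.data)
        state.head_W2.data = np.zeros_like(state.head_W2.data)
        state.head_W2.data[0, :] = 10.0
        out = deconv_head(state, np.zeros((1, 4))).data
        assert out[0, 0] > 0.99

    def test_softmax_matches_exp_normalize_oracle(self, rng):
        state = init_gnn(3, 5, hidden_dim=4, n_channels=1, seed=3)
        state.head_W2.data = rng.normal(size=state.head_W2.data.shape)
        Z = rng.normal(size=(6, 4))
        out = deconv_head(state, Z).data
        h = np.maximum(Z @ state.head_W1.data.T + state.head_b1.data, 0)
        logits = h @ state.head_W2.data.T + state.head_b2.data
        expected = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out, expected, atol=1e-10)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(deconv_head_numpy(state, Z), out,
                                   atol=1e-12)

    def test_zeroed_discriminator_is_chance(self):
        state = init_gnn(3, 2, hidden_dim=4, n_channels=1, seed=0)
        d = domain_discriminator(state, np.random.default_rng(0).normal(size=(5, 4)))
        np.testing.assert_allclose(d.data, 0.5)

    def test_discriminator_monotone_in_logit(self, rng):
        state = init_gnn(3, 2, hidden_dim=4, n_channels=1, seed=4)
        state.disc_W2.data = 0.05 * np.abs(rng.normal(size=state.disc_W2.data.shape))
        z = 0.1 * np.ones((1, 4))
        d1 = domain_discriminator(state, z).data.item()
        state.disc_b2.data = state.disc_b2.data + 2.0
        d2 = domain_discriminator(state, z).data.item()
        assert d2 > d1

    def test_discriminator_matches_hand_forward(self, rng):
        state = init_gnn(3, 2, hidden_dim=4, n_channels=2, seed=6)
        state.disc_W2.data = rng.normal(size=state.disc_W2.data.shape)
        Z = rng.normal(size=(3, 8))
        d = domain_discriminator(state, Z).data
        h = np.maximum(Z @ state.disc_W1.data.T + state.disc_b1.data, 0)
        logit = h @ state.disc_W2.data.T + state.disc_b2.data
        np.testing.assert_allclose(d, 1 / (1 + np.exp(-logit)), atol=1e-10)


class TestAblationAdjacency:
    def test_identity_when_graph_disabled(self, rng):
        g = build_knn_graph(rng.normal(size=(6, 3)), k=2)
        a = normalized_adjacency(g, use_graph=False).toarray()
        np.testing.assert_array_equal(a, np.eye(6))

    def test_rows_sum_to_one(self, rng):
        g = build_knn_graph(rng.normal(size=(10, 3)), k=3)
        a = normalized_adjacency(g).toarray()
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)

    def test_no_gnn_state_ignores_graph_structure(self, rng):
        X = rng.uniform(size=(8, 3))
        state = init_gnn(3, 2, hidden_dim=4, n_channels=1, seed=0,
                         use_graph=False)
        g1 = build_knn_graph(rng.normal(size=(8, 3)), k=2)
        g2 = build_knn_graph(rng.normal(size=(8, 3)), k=3)
        z1 = gnn_forward(Tensor(X), g1, state).data
        z2 = gnn_forward(Tensor(X), g2, state).data
        np.testing.assert_array_equal(z1, z2)
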