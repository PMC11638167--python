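"""Graph attention, similarity update rule and prior anchoring."""

import numpy as np
import pytest

import mignet as mg
from mignet.graph import (AdjacencyState, GATConfig, classify, feature_similarity,
                          gat_layer, init_gat_params, update_adjacency)
from mignet.montage import PriorAdjacency


def loop_gat_layer(G, P, layer_params, slope=0.2):
    """Reference: per-node, per-head python-loop graph attention layer."""
    def elu(v):
        return np.where(v > 0, v, np.expm1(np.minimum(v, 0)))

    def leaky(v):
        return np.where(v > 0, v, slope * v)

    Q, _, D = layer_params["W"].shape
    C = G.shape[0]
    heads = []
    for q in range(Q):
        W, a_s, a_d = layer_params["W"][q], layer_params["a_src"][q], layer_params["a_dst"][q]
        h = G @ W
        out_q = np.zeros((C, D))
        for u in range(C):
            neigh = [v for v in range(C) if P[u, v] > 0 or v == u]
            logits = []
            for v in neigh:
                e = leaky(a_s @ h[u] + a_d @ h[v])
                bias = 0.0 if v == u else np.log(max(P[u, v], 1e-12))
                logits.append(e + bias)
            logits = np.array(logits)
            alpha = np.exp(logits - logits.max())
            alpha /= alpha.sum()
            out_q[u] = elu(sum(a * h[v] for a, v in zip(alpha, neigh)))
        heads.append(out_q)
    return np.concatenate(heads, axis=-1) @ layer_params["W_O"]


@pytest.fixture()
def four_node_setup():
    rng = np.random.default_rng(8)
    cfg = GATConfig(n_layers=1, heads=3, hidden_dims=(5,))
    params = init_gat_params(cfg, in_dim=6, n_classes=2, n_nodes=4, rng=rng)
    G = rng.standard_normal((4, 6))
    P = np.abs(rng.standard_normal((4, 4)))
    P = (P + P.T) / 2
    np.fill_diagonal(P, 0.0)
    P[0, 3] = P[3, 0] = 0.0  # one absent edge to exercise masking
    return cfg, params, G, P


class TestGATLayer:
    def test_matches_per_node_loop_reference(self, four_node_setup):
        cfg, params, G, P = four_node_setup
        fast = np.asarray(gat_layer(G, P, params["layers"][0], cfg))
        ref = loop_gat_layer(G, P, params["layers"][0], cfg.leaky_slope)
        np.testing.assert_allclose(fast, ref, atol=1e-6)

    def test_attention_rows_sum_to_one(self, four_node_setup):
        cfg, params, G, P = four_node_setup
        _, alpha = gat_layer(G, P, params["layers"][0], cfg, return_attention=True)
        sums = np.asarray(alpha).sum(-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_two_node_attention_ratio_equals_adjacency_weight(self):
        # equal logits (zero attention vectors): softmax bias log(P) makes
        # alpha_uv / alpha_uu = P_uv exactly
        cfg = GATConfig(n_layers=1, heads=1, hidden_dims=(2,))
        params = init_gat_params(cfg, in_dim=2, n_classes=2, n_nodes=2,
                                 rng=np.random.default_rng(0))
        layer = params["layers"][0]
        layer["a_src"][:] = 0.0
        layer["a_dst"][:] = 0.0
        P = np.array([[0.0, 0.4], [0.4, 0.0]])
        G = np.random.default_rng(1).standard_normal((2, 2))
        _, alpha = gat_layer(G, P, layer, cfg, return_attention=True)
        alpha = np.asarray(alpha)[0]
        assert alpha[0, 1] / alpha[0, 0] == pytest.approx(0.4, rel=1e-9)

    def test_node_permutation_equivariance(self, four_node_setup):
        cfg, params, G, P = four_node_setup
        perm = np.array([2, 0, 3, 1])
        out = np.asarray(gat_layer(G, P, params["layers"][0], cfg))
        out_perm = np.asarray(
            gat_layer(G[perm], P[np.ix_(perm, perm)], params["layers"][0], cfg)
        )
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-8)

    def test_absent_prior_edge_gets_zero_attention(self, four_node_setup):
        cfg, params, G, P = four_node_setup
        _, alpha = gat_layer(G, P, params["layers"][0], cfg, return_attention=True)
        assert np.all(np.asarray(alpha)[:, 0, 3] == 0.0)


class TestFeatureSimilarity:
    def test_identical_rows_give_similarity_one(self):
        G3 = np.ones((3, 4))
        K = feature_similarity(G3, delta=2.0, xi=0.5)
        np.testing.assert_allclose(K, 1.0)

    def test_hand_computed_value(self):
        # distance 1, delta=2, xi=0.5 -> 0.5 / (1 + 0.5) = 1/3
        G3 = np.array([[0.0, 0.0], [1.0, 0.0]])
        K = feature_similarity(G3, delta=2.0, xi=0.5)
        assert K[0, 1] == pytest.approx(1.0 / 3.0)
        assert K[0, 0] == pytest.approx(1.0)

    def test_bounded_symmetric_decreasing(self):
        rng = np.random.default_rng(2)
        G3 = rng.standard_normal((6, 5))
        K = feature_similarity(G3, delta=2.0, xi=0.5)
        assert np.all((K > 0) & (K <= 1.0))
        np.testing.assert_allclose(K, K.T)
        # farther pair has smaller similarity
        d = np.linalg.norm(G3[:, None] - G3[None, :], axis=-1)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        assert K[i, j] == K.min()

    def test_large_distance_limit_is_zero(self):
        G3 = np.array([[0.0], [1e8]])
        assert feature_similarity(G3, 2.0, 0.5)[0, 1] < 1e-12

    def test_invalid_hyperparameters_raise(self):
        with pytest.raises(ValueError):
            feature_similarity(np.zeros((2, 2)), delta=0.0, xi=0.5)
        with pytest.raises(ValueError, match="non-finite"):
            feature_similarity(np.array([[np.inf]]), 2.0, 0.5)


class TestAdjacencyUpdate:
    @pytest.fixture()
    def state(self):
        E = np.array([[0.0, 0.8, 0.2], [0.8, 0.0, 1.0], [0.2, 1.0, 0.0]])
        return AdjacencyState(prior=PriorAdjacency(E=E))

    def test_gamma_zero_returns_prior(self, state):
        cfg = GATConfig(gamma=0.0)
        G3 = np.random.default_rng(0).standard_normal((3, 4))
        update_adjacency(state, G3, cfg)
        np.testing.assert_allclose(state.P, state.E)

    def test_identical_features_return_prior(self, state):
        cfg = GATConfig(gamma=1.0)
        update_adjacency(state, np.ones((3, 4)), cfg)
        np.testing.assert_allclose(state.P, state.E)

    def test_elementwise_product_value(self, state):
        # E entry 0.8 with K = 1/3 at gamma 1 -> 0.8/3
        cfg = GATConfig(gamma=1.0, delta=2.0, xi=0.5)
        G3 = np.array([[0.0, 0.0], [1.0, 0.0], [50.0, 50.0]])
        update_adjacency(state, G3, cfg)
        assert state.P[0, 1] == pytest.approx(0.8 / 3.0)

    def test_update_counting_and_history(self, state):
        cfg = GATConfig()
        for n in range(1, 4):
            update_adjacency(state, np.random.default_rng(n).standard_normal((3, 2)), cfg)
            assert state.update_count == n
            assert len(state.history) == n

    def test_missing_statistics_raise(self, state):
        with pytest.raises(ValueError, match="forward pass"):
            update_adjacency(state, None, GATConfig())

    def test_anchoring_bound_and_support(self, state):
        cfg = GATConfig(gamma=1.5)
        rng = np.random.default_rng(5)
        for _ in range(10):
            update_adjacency(state, rng.standard_normal((3, 4)), cfg)
            assert np.all(state.P >= 0) and np.all(state.P <= state.E + 1e-12)
            assert np.all(state.P[state.E == 0] == 0)
            np.testing.assert_allclose(state.P, state.P.T)
            assert np.all(np.diag(state.P) == 0)


class TestClassifierHead:
    def test_zero_weights_give_uniform_probabilities(self):
        head = {"W": np.zeros((12, 4)), "b": np.zeros(4)}
        G = np.random.default_rng(0).standard_normal((3, 4, 3))
        probs = np.asarray(classify(G, head))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        head = {"W": rng.standard_normal((12, 4)), "b": rng.standard_normal(4)}
        probs = np.asarray(classify(rng.standard_normal((5, 4, 3)), head))
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-6)
        assert probs.shape == (5, 4)
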