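"""Encoder components against independent dense/brute-force oracles."""

import numpy as np
import pytest

from stratgraph.autodiff import Tensor
from stratgraph.encoder import (Encoder, EncoderConfig, FusionWeights,
                                CrossModalAttention, ModalityEncoder,
                                MultiHeadAttention, fuse_modalities,
                                gated_graph_layer, gcn_layer,
                                hierarchical_merge, relative_position_index,
                                temporal_attention)
from stratgraph.graph import GraphParams, PatientGraph
from stratgraph.nn import Linear


def _graph(weights):
    w = np.asarray(weights, dtype=float)
    return PatientGraph(weights=w, params=GraphParams(tau=0.0))


def _dense_gcn_oracle(h, weights, w_mat):
    """Independent dense-matrix oracle for the propagation rule."""
    a = weights + np.eye(len(weights))
    d = a.sum(axis=1)
    p = a / np.sqrt(np.outer(d, d))
    return np.maximum(p @ h @ w_mat, 0.0)


def _softmax_oracle(scores):
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class TestModalityEncoderAndFusion:
    def test_zero_input_zero_bias_maps_to_zero(self, rng):
        enc = ModalityEncoder(3, 4, rng)
        enc.mlp.fc1.b.data[:] = 0
        enc.mlp.fc2.b.data[:] = 0
        out = enc(np.zeros((2, 5, 3)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_tiny_weights_match_hand_computation(self, rng):
        enc = ModalityEncoder(2, 2, rng)
        w1, b1 = enc.mlp.fc1.W.data, enc.mlp.fc1.b.data
        w2, b2 = enc.mlp.fc2.W.data, enc.mlp.fc2.b.data
        x = np.array([[0.5, -1.0]])
        hidden = np.maximum(x @ w1 + b1, 0.0)
        np.testing.assert_allclose(enc(x).data, hidden @ w2 + b2, atol=1e-12)

    def test_masked_step_receives_reserved_missing_vector(self, rng):
        enc = ModalityEncoder(3, 4, rng)
        x = rng.normal(size=(1, 2, 3))
        mask = np.array([[True, False]])
        out = enc(x, mask).data
        np.testing.assert_allclose(out[0, 1], enc.missing.data)

    def test_input_dim_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ModalityEncoder(3, 4, rng)(np.zeros((2, 5)))

    def test_single_modality_fusion_is_identity(self, rng):
        e = Tensor(rng.normal(size=(3, 4)))
        out = fuse_modalities([e], FusionWeights(1))
        np.testing.assert_allclose(out.data, e.data)

    def test_equal_weights_cancel_opposite_encodings(self, rng):
        e = Tensor(rng.normal(size=(3, 4)))
        out = fuse_modalities([e, e * -1.0], FusionWeights(2))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_explicit_weights_weight_the_sum(self):
        fw = FusionWeights(2)
        fw.logits.data = np.log(np.array([0.7, 0.3]))
        out = fuse_modalities([Tensor([[1.0, 0.0]]), Tensor([[0.0, 1.0]])], fw)
        np.testing.assert_allclose(out.data, [[0.7, 0.3]], atol=1e-12)

    def test_empty_fusion_rejected(self):
        with pytest.raises(ValueError):
            fuse_modalities([], FusionWeights(1))


class TestGraphLayers:
    def test_single_node_reduces_to_self_loop(self, rng):
        h = rng.normal(size=(1, 3))
        w = rng.normal(size=(3, 3))
        out = gcn_layer(h, _graph(np.zeros((1, 1))), w)
        np.testing.assert_allclose(out.data, np.maximum(h @ w, 0), atol=1e-12)

    def test_two_node_unit_edge_linear_matches_hand_calc(self):
        h = np.array([[1.0], [3.0]])
        g = _graph([[0, 1], [1, 0]])
        out = gcn_layer(h, g, np.eye(1), activation="linear").data
        # P = (A+I)/2 for two nodes with unit edge and self-loops
        np.testing.assert_allclose(out, [[2.0], [2.0]])

    @pytest.mark.parametrize("n", [5, 12, 20])
    def test_matches_dense_oracle_on_random_graphs(self, n, rng):
        w_adj = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
        w_adj = np.triu(w_adj, 1)
        w_adj = w_adj + w_adj.T
        h = rng.normal(size=(n, 6))
        w_mat = rng.normal(size=(6, 4))
        out = gcn_layer(h, _graph(w_adj), w_mat).data
        np.testing.assert_allclose(out, _dense_gcn_oracle(h, w_adj, w_mat),
                                   atol=1e-6)

    def test_gated_layer_zero_states_and_bias_give_zero(self, rng):
        g = _graph(rng.random((4, 4)) * 0)
        out = gated_graph_layer(np.zeros((4, 3)), g, rng.normal(size=(3, 3)),
                                rng.normal(size=(3, 3)), np.zeros(3))
        np.testing.assert_allclose(out.data, 0.0)

    def test_gated_layer_outputs_strictly_inside_unit_interval(self, rng):
        w_adj = rng.random((6, 6))
        w_adj = np.triu(w_adj, 1)
        w_adj = w_adj + w_adj.T
        out = gated_graph_layer(rng.normal(size=(6, 5)) * 10, _graph(w_adj),
                                rng.normal(size=(5, 5)),
                                rng.normal(size=(5, 5)), rng.normal(size=5))
        assert np.abs(out.data).max() < 1.0

    def test_gated_layer_two_node_scalar_hand_computation(self):
        h = np.array([[2.0], [-1.0]])
        adj = np.array([[0.0, 0.5], [0.5, 0.0]])
        w, u, b = np.array([[1.5]]), np.array([[-0.7]]), np.array([0.3])
        a = adj + np.eye(2)
        deg = a.sum(axis=1)
        p = a / np.sqrt(np.outer(deg, deg))
        gate = 1 / (1 + np.exp(-(p @ h @ w + b)))
        expected = gate * np.tanh(p @ h @ u)
        out = gated_graph_layer(h, _graph(adj), w, u, b).data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_node_permutation_equivariance(self, rng):
        n = 9
        w_adj = rng.random((n, n))
        w_adj = np.triu(w_adj, 1)
        w_adj = w_adj + w_adj.T
        h = rng.normal(size=(n, 4))
        w, u, b = (rng.normal(size=(4, 4)), rng.normal(size=(4, 4)),
                   rng.normal(size=4))
        perm = rng.permutation(n)
        base = gated_graph_layer(h, _graph(w_adj), w, u, b).data
        permuted = gated_graph_layer(h[perm],
                                     _graph(w_adj[np.ix_(perm, perm)]),
                                     w, u, b).data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)


class TestTemporalAttention:
    def _params(self, rng, d):
        return (rng.normal(size=(d, d)), rng.normal(size=(d, d)),
                rng.normal(size=(d, d)))

    def test_single_step_attends_to_itself(self, rng):
        d = 3
        wq, wk, wv = self._params(rng, d)
        h = rng.normal(size=(1, d))
        beta, out = temporal_attention(h, wq, wk, wv, np.zeros(1))
        np.testing.assert_allclose(beta.data, [[1.0]])
        np.testing.assert_allclose(out.data, h @ wv, atol=1e-12)

    def test_constant_states_and_zero_bias_give_uniform_rows(self, rng):
        d, t = 4, 6
        wq, wk, wv = self._params(rng, d)
        h = np.tile(rng.normal(size=(1, d)), (t, 1))
        beta, _ = temporal_attention(h, wq, wk, wv, np.zeros(2 * t - 1))
        np.testing.assert_allclose(beta.data, np.full((t, t), 1 / t))

    def test_matches_brute_force_softmax_with_linear_lag_bias(self, rng):
        d, t = 3, 3
        wq, wk, wv = self._params(rng, d)
        h = rng.normal(size=(t, d))
        lags = np.arange(-(t - 1), t)
        bias = -0.1 * np.abs(lags)  # phi(dt) = -0.1|dt|
        beta, out = temporal_attention(h, wq, wk, wv, bias)
        scores = (h @ wq) @ (h @ wk).T / np.sqrt(d)
        scores = scores + bias[relative_position_index(t)]
        expected_beta = _softmax_oracle(scores)
        np.testing.assert_allclose(beta.data, expected_beta, atol=1e-10)
        np.testing.assert_allclose(out.data, expected_beta @ (h @ wv),
                                   atol=1e-10)

    def test_masked_steps_are_exactly_zero_and_rows_renormalize(self, rng):
        d, t = 3, 5
        wq, wk, wv = self._params(rng, d)
        h = rng.normal(size=(2, t, d))
        mask = np.ones((2, t), dtype=bool)
        mask[0, 3:] = False
        beta, _ = temporal_attention(h, wq, wk, wv, np.zeros(2 * t - 1), mask)
        assert np.all(beta.data[0, :, 3:] == 0)
        np.testing.assert_allclose(beta.data.sum(axis=-1), 1.0)

    def test_fully_masked_patient_rejected(self, rng):
        d, t = 2, 3
        wq, wk, wv = self._params(rng, d)
        with pytest.raises(ValueError):
            temporal_attention(rng.normal(size=(1, t, d)), wq, wk, wv,
                               np.zeros(2 * t - 1),
                               np.zeros((1, t), dtype=bool))


class TestMultiHeadAttention:
    def test_single_head_reduces_to_scaled_dot_product(self, rng):
        d = 4
        mha = MultiHeadAttention(d, 1, rng)
        for w in (mha.w_q, mha.w_k, mha.w_v, mha.w_o):
            w.data = np.eye(d)
        x = rng.normal(size=(1, 5, d))
        out = mha(x, x, x).data
        scores = x[0] @ x[0].T / np.sqrt(d)
        expected = _softmax_oracle(scores) @ x[0]
        np.testing.assert_allclose(out[0], expected, atol=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        mha = MultiHeadAttention(8, 2, rng)
        x = rng.normal(size=(3, 6, 8))
        _, attn = mha(x, x, x, return_weights=True)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0)

    def test_key_value_permutation_leaves_output_invariant(self, rng):
        mha = MultiHeadAttention(8, 2, rng)
        q = rng.normal(size=(1, 4, 8))
        kv = rng.normal(size=(1, 6, 8))
        perm = rng.permutation(6)
        base = mha(q, kv, kv).data
        permuted = mha(q, kv[:, perm], kv[:, perm]).data
        np.testing.assert_allclose(permuted, base, atol=1e-10)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError):
            MultiHeadAttention(6, 4, rng)


class TestCrossModalAttention:
    def test_self_pair_equals_self_attention(self, rng):
        cm = CrossModalAttention(8, 2, rng)
        x = rng.normal(size=(2, 5, 8))
        out = cm(x, x).data
        expected = x + cm.mha(x, x, x).data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_zero_values_return_pure_residual(self, rng):
        cm = CrossModalAttention(8, 2, rng)
        cm.mha.w_v.data[:] = 0.0
        x_m = rng.normal(size=(2, 5, 8))
        x_n = rng.normal(size=(2, 5, 8))
        np.testing.assert_allclose(cm(x_m, x_n).data, x_m, atol=1e-12)

    def test_two_token_toy_matches_hand_softmax(self, rng):
        d = 2
        cm = CrossModalAttention(d, 1, rng)
        for w in (cm.mha.w_q, cm.mha.w_k, cm.mha.w_v, cm.mha.w_o):
            w.data = np.eye(d)
        x_m = np.array([[[1.0, 0.0]]])
        x_n = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        scores = x_m[0] @ x_n[0].T / np.sqrt(d)
        expected = x_m[0] + _softmax_oracle(scores) @ x_n[0]
        np.testing.assert_allclose(cm(x_m, x_n).data[0], expected, atol=1e-12)


class TestHierarchicalMerge:
    def test_identity_transform_doubles_constant_input(self, rng):
        d = 3
        tf = Linear(d, d, rng)
        tf.W.data = np.eye(d)
        tf.b.data[:] = 0
        c = np.ones((2, 4, d))
        out = hierarchical_merge(c, c.mean(axis=1), tf)
        np.testing.assert_allclose(out.data, 2 * np.ones((2, d)))

    def test_zero_final_layer_leaves_temporal_mean(self, rng):
        d = 3
        tf = Linear(d, d, rng)
        tf.b.data[:] = 0
        h_local = rng.normal(size=(2, 4, d))
        out = hierarchical_merge(h_local, np.zeros((2, d)), tf)
        np.testing.assert_allclose(out.data, h_local.mean(axis=1), atol=1e-12)

    def test_random_inputs_equal_mean_plus_affine(self, rng):
        d = 4
        tf = Linear(d, d, rng)
        h_local = rng.normal(size=(3, 5, d))
        h_final = rng.normal(size=(3, d))
        out = hierarchical_merge(h_local, h_final, tf)
        expected = h_local.mean(axis=1) + h_final @ tf.W.data + tf.b.data
        np.testing.assert_allclose(out.data, expected, atol=1e-12)


class TestFullEncoder:
    def _setup(self, rng, use_graph=True, use_temporal=True,
               use_cross_modal=True):
        cfg = EncoderConfig(hidden_dim=8, attention_heads=2,
                            temporal_window=4, dropout=0.3)
        enc = Encoder({"a": 3, "b": 5}, cfg, rng, use_graph=use_graph,
                      use_temporal=use_temporal,
                      use_cross_modal=use_cross_modal)
        n, t = 6, 4
        feats = {"a": rng.normal(size=(n, t, 3)),
                 "b": rng.normal(size=(n, t, 5))}
        masks = {"a": np.ones((n, t), bool), "b": np.ones((n, t), bool)}
        w = rng.random((n, n))
        w = np.triu(w, 1)
        graph = _graph(w + w.T)
        return enc, feats, masks, graph

    def test_forward_without_dropout_is_reproducible(self, rng):
        enc, feats, masks, graph = self._setup(rng)
        out1 = enc.forward(feats, masks, graph, training=False)
        out2 = enc.forward(feats, masks, graph, training=False)
        np.testing.assert_array_equal(out1.h_global.data, out2.h_global.data)

    def test_attention_maps_are_valid_distributions(self, rng):
        enc, feats, masks, graph = self._setup(rng)
        masks["b"][:, 2] = False
        out = enc.forward(feats, masks, graph, collect_attention=True)
        np.testing.assert_allclose(out.temporal_beta.sum(axis=-1), 1.0)
        for (m, n), attn in out.cross_attention.items():
            np.testing.assert_allclose(attn.sum(axis=-1), 1.0)
            if n == "b":
                assert np.all(attn[:, :, 2] == 0)

    def test_fusion_alphas_form_distribution(self, rng):
        enc, feats, masks, graph = self._setup(rng)
        out = enc.forward(feats, masks, graph)
        assert out.fusion_alphas.min() >= 0
        assert out.fusion_alphas.sum() == pytest.approx(1.0, abs=1e-7)

    def test_all_pathways_disabled_rejected(self, rng):
        with pytest.raises(ValueError):
            self._setup(rng, use_graph=False, use_temporal=False,
                        use_cross_modal=False)

    def test_graph_pathway_permutation_equivariance(self, rng):
        enc, feats, masks, graph = self._setup(rng, use_temporal=False,
                                               use_cross_modal=False)
        base = enc.forward(feats, masks, graph).h_global.data
        perm = rng.permutation(6)
        feats_p = {k: v[perm] for k, v in feats.items()}
        masks_p = {k: v[perm] for k, v in masks.items()}
        graph_p = _graph(graph.weights[np.ix_(perm, perm)])
        permuted = enc.forward(feats_p, masks_p, graph_p).h_global.data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)
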