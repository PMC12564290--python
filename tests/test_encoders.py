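"""Encoder contracts: MSA/NCAA oracles, DropEdge calibration, GCN oracle."""

import numpy as np
import pytest

from popconn.autodiff import Tensor
from popconn.encoders import (GCNLayer, MultiHeadSelfAttention, NCAALayer,
                              PopulationGCN, TargetAwareAggregator, drop_edge,
                              ncaa_update, normalized_adjacency)
from popconn.nn import rng_for

RNG = np.random.default_rng(0)


def _identity_linear(lin):
    lin.weight.data = np.eye(*lin.weight.shape)
    if lin.bias is not None:
        lin.bias.data[:] = 0.0


class TestMSA:
    def test_shape_preserved(self):
        msa = MultiHeadSelfAttention(8, 2, np.random.default_rng(1))
        x = Tensor(RNG.standard_normal((3, 5, 8)))
        assert msa(x).shape == (3, 5, 8)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadSelfAttention(6, 4, np.random.default_rng(0))

    def test_single_head_identity_projections_match_loop_oracle(self):
        d = 4
        msa = MultiHeadSelfAttention(d, 1, np.random.default_rng(2))
        for lin in (msa.wq, msa.wk, msa.wv, msa.wo):
            _identity_linear(lin)
        x = RNG.standard_normal((2, 5, d))
        out = msa(Tensor(x)).data
        for b in range(2):
            scores = x[b] @ x[b].T / np.sqrt(d)
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            attn = e / e.sum(axis=1, keepdims=True)
            assert np.allclose(out[b], attn @ x[b], atol=1e-10)

    def test_permutation_equivariance(self):
        msa = MultiHeadSelfAttention(6, 2, np.random.default_rng(3))
        x = RNG.standard_normal((2, 7, 6))
        perm = RNG.permutation(7)
        out = msa(Tensor(x)).data
        out_perm = msa(Tensor(x[:, perm, :])).data
        assert np.allclose(out_perm, out[:, perm, :], atol=1e-10)


class TestNCAA:
    def test_rows_are_simplex_points(self):
        layer = NCAALayer(5, 8, np.random.default_rng(4))
        alpha = layer.attention(Tensor(RNG.standard_normal((3, 6, 5)))).data
        assert np.all(alpha >= 0)
        assert np.allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(np.diagonal(alpha, axis1=1, axis2=2) == 0.0)

    def test_two_rois_single_neighbor(self):
        layer = NCAALayer(3, 4, np.random.default_rng(5))
        alpha = layer.attention(Tensor(RNG.standard_normal((2, 2, 3)))).data
        assert np.allclose(alpha[:, 0, 1], 1.0)
        assert np.allclose(alpha[:, 1, 0], 1.0)

    def test_matches_concat_scorer_oracle(self):
        """The pairwise-sum scorer must equal an explicit loop that
        concatenates [h_i || h_j] and runs the two-layer perceptron."""
        d, hidden, seq = 3, 4, 3
        layer = NCAALayer(d, hidden, np.random.default_rng(6))
        x = RNG.standard_normal((2, seq, d))
        alpha = layer.attention(Tensor(x)).data
        w1 = np.vstack([layer.center.weight.data, layer.neighbor.weight.data])
        b1 = layer.center.bias.data
        w2, b2 = layer.score.weight.data, layer.score.bias.data
        for b in range(2):
            for i in range(seq):
                scores = {}
                for j in range(seq):
                    if j == i:
                        continue
                    cat = np.concatenate([x[b, i], x[b, j]])
                    scores[j] = (np.tanh(cat @ w1 + b1) @ w2 + b2).item()
                mx = max(scores.values())
                exp = {j: np.exp(s - mx) for j, s in scores.items()}
                z = sum(exp.values())
                for j, e in exp.items():
                    assert abs(alpha[b, i, j] - e / z) <= 1e-10

    def test_update_closed_forms(self):
        x = RNG.standard_normal((1, 4, 3))
        # one-hot on neighbor 2 for every center
        alpha = np.zeros((1, 4, 4))
        alpha[0, :, 2] = 1.0
        alpha[0, 2, 2] = 0.0
        alpha[0, 2, 0] = 1.0
        out = ncaa_update(Tensor(x), Tensor(alpha)).data
        assert np.allclose(out[0, 1], x[0, 1] + x[0, 2], atol=1e-12)
        assert np.allclose(out[0, 2], x[0, 2] + x[0, 0], atol=1e-12)
        # uniform weights: center plus mean of the others
        uni = (np.ones((4, 4)) - np.eye(4)) / 3.0
        out = ncaa_update(Tensor(x), Tensor(uni[None])).data
        others = (x[0].sum(axis=0) - x[0, 1]) / 3.0
        assert np.allclose(out[0, 1], x[0, 1] + others, atol=1e-12)

    def test_seq_below_two_rejected(self):
        layer = NCAALayer(3, 4, np.random.default_rng(7))
        with pytest.raises(ValueError, match="2 ROIs"):
            layer.attention(Tensor(RNG.standard_normal((1, 1, 3))))


class TestTAA:
    def test_composition_matches_manual_single_layer(self):
        taa = TargetAwareAggregator(5, embed_dim=4, n_layers=1, n_heads=1,
                                    hidden=6, seed=3)
        s = RNG.standard_normal((3, 5, 5))
        s = (s + s.swapaxes(1, 2)) / 2
        out = taa(s).data
        x = taa.msa(Tensor(s))
        x = ncaa_update(x, taa.ncaa_layers[0].attention(x))
        manual = taa.readout(x.mean(axis=1)).data
        assert np.allclose(out, manual, atol=1e-12)

    def test_roi_permutation_invariant_after_pooling(self):
        taa = TargetAwareAggregator(8, embed_dim=4, n_layers=2, seed=1)
        x = RNG.standard_normal((2, 8, 8))
        perm = RNG.permutation(8)
        assert np.allclose(taa(x).data, taa(x[:, perm, :]).data, atol=1e-8)

    def test_eval_determinism(self):
        taa = TargetAwareAggregator(6, embed_dim=4, seed=2)
        x = RNG.standard_normal((4, 6, 6))
        assert np.array_equal(taa(x).data, taa(x).data)

    def test_rejects_zero_layers(self):
        with pytest.raises(ValueError, match="n_layers"):
            TargetAwareAggregator(6, n_layers=0)


class TestDropEdge:
    def _graph(self, n=25, n_edges=100, seed=0):
        rng = np.random.default_rng(seed)
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        pick = rng.choice(iu.size, size=n_edges, replace=False)
        w[iu[pick], ju[pick]] = rng.random(n_edges) + 0.1
        return w + w.T

    def test_noop_cases(self):
        w = self._graph()
        assert drop_edge(w, 0.0, training=True,
                         rng=np.random.default_rng(0)) is w
        assert drop_edge(w, 0.3, training=False) is w  # eval: bit-exact no-op

    def test_rate_validation(self):
        with pytest.raises(ValueError, match="rate"):
            drop_edge(self._graph(), 1.0, training=True,
                      rng=np.random.default_rng(0))

    def test_binomial_calibration(self):
        # 1000 draws at rate 0.3 on a 100-edge graph: the mean kept-edge
        # count must fall in the 99.9% binomial interval around 70
        w = self._graph()
        kept = []
        for s in range(1000):
            out = drop_edge(w, 0.3, training=True,
                            rng=np.random.default_rng(s))
            kept.append((out[np.triu_indices_from(out, k=1)] > 0).sum())
        assert 67.3 <= np.mean(kept) <= 72.7

    def test_symmetry_preserved_every_draw(self):
        w = self._graph(seed=3)
        for s in range(20):
            out = drop_edge(w, 0.5, training=True,
                            rng=np.random.default_rng(s))
            assert np.array_equal(out, out.T)


class TestGCNLayer:
    def test_path_graph_hand_oracle(self):
        # 3-node path, H = I, Theta = I, residual off
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        layer = GCNLayer(3, 3, np.random.default_rng(0), residual=False)
        _identity_linear(layer.theta)
        out = layer(Tensor(np.eye(3)), normalized_adjacency(w)).data
        a_tilde = w + np.eye(3)
        d = np.diag(1 / np.sqrt(a_tilde.sum(axis=1)))
        expected = np.maximum(d @ a_tilde @ d, 0.0)
        assert np.allclose(out, expected, atol=1e-6)

    def test_isolated_node_reduces_to_self_loop(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0  # node 3 isolated
        rng = np.random.default_rng(1)
        layer = GCNLayer(5, 5, rng, residual=False)
        h = RNG.standard_normal((4, 5))
        out = layer(Tensor(h), normalized_adjacency(w)).data
        expected = np.maximum(h[3] @ layer.theta.weight.data, 0.0)
        assert np.allclose(out[3], expected, atol=1e-10)

    def test_zero_theta_identity_residual_passes_through(self):
        layer = GCNLayer(4, 4, np.random.default_rng(2))
        layer.theta.weight.data[:] = 0.0
        h = RNG.standard_normal((5, 4))
        w = self_w = np.ones((5, 5)) - np.eye(5)
        out = layer(Tensor(h), normalized_adjacency(self_w)).data
        assert np.allclose(out, h, atol=1e-12)

    def test_dense_bruteforce_oracle_random_graphs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = rng.integers(2, 7)
            w = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
            w = np.triu(w, 1)
            w = w + w.T
            h = rng.standard_normal((n, 3))
            layer = GCNLayer(3, 4, rng)
            out = layer(Tensor(h), normalized_adjacency(w)).data
            a_tilde = w + np.eye(n)
            dmh = np.diag(1 / np.sqrt(a_tilde.sum(axis=1)))
            expected = np.maximum(
                dmh @ a_tilde @ dmh @ h @ layer.theta.weight.data, 0.0
            ) + h @ layer.residual.weight.data
            assert np.allclose(out, expected, atol=1e-6)


class TestPopulationGCN:
    def test_eval_determinism(self):
        gcn = PopulationGCN(10, hidden=6, out_dim=4, seed=0)
        x = RNG.standard_normal((8, 10))
        w = np.abs(self_w := RNG.standard_normal((8, 8)))
        w = np.triu(w, 1)
        w = w + w.T
        a = gcn(x, w, training=False).data
        b = gcn(x, w, training=False).data
        assert np.array_equal(a, b)

    def test_zero_adjacency_is_per_node_map(self):
        gcn = PopulationGCN(6, hidden=5, out_dim=3, n_layers=2, seed=1)
        x = RNG.standard_normal((4, 6))
        out = gcn(x, np.zeros((4, 4)), training=False).data
        # self-loops only: two subjects with equal features map identically
        x2 = x.copy()
        x2[2] = x2[0]
        out2 = gcn(x2, np.zeros((4, 4)), training=False).data
        assert np.allclose(out2[2], out2[0], atol=1e-12)
        assert np.allclose(out[0], out2[0], atol=1e-12)

    def test_training_edge_dropout_is_stochastic_across_seeds(self):
        gcn = PopulationGCN(6, hidden=5, out_dim=3, edge_dropout=0.5,
                            p_dropout=0.0, seed=2)
        x = RNG.standard_normal((10, 6))
        w = np.ones((10, 10)) - np.eye(10)
        a = gcn(x, w, training=True, rng=np.random.default_rng(1)).data
        b = gcn(x, w, training=True, rng=np.random.default_rng(2)).data
        assert not np.allclose(a, b)

    def test_chebyshev_variant_runs(self):
        gcn = PopulationGCN(6, hidden=5, out_dim=3, variant="chebyshev",
                            cheb_k=2, seed=3)
        x = RNG.standard_normal((5, 6))
        w = np.ones((5, 5)) - np.eye(5)
        assert gcn(x, w, training=False).shape == (5, 3)
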