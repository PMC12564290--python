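"""Loss closed forms, hand-expanded oracles, and gradient sanity."""

import numpy as np
import pytest

from popconn.autodiff import Tensor
from popconn.losses import (ProjectionHead, consistency_loss, contrastive_loss,
                            cross_entropy, pairwise_similarity, positive_mask,
                            total_loss)

from conftest import numeric_gradient

RNG = np.random.default_rng(0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _norm_rows(x):
    return x / np.sqrt((x**2).sum(axis=1, keepdims=True) + 1e-12)


class TestConsistencyLoss:
    def test_single_view_is_zero(self):
        g = RNG.standard_normal((4, 3))
        assert consistency_loss([g], [g]).data == 0.0

    def test_identical_views_hand_formula(self):
        # after row-normalisation every inner product is 1, so each pair
        # contributes -log(sigmoid(2))
        g = RNG.standard_normal((5, 3))
        t = RNG.standard_normal((5, 3))
        val = consistency_loss([g, g, g], [t, t, t]).data
        expected = 3 * -np.log(_sigmoid(2.0))  # 3 unordered pairs
        assert abs(val - expected) <= 1e-9

    def test_two_view_hand_expansion(self):
        g1 = np.array([[1.0, 0.0], [0.6, 0.8]])
        g2 = np.array([[0.0, 1.0], [1.0, 0.0]])
        t1 = np.array([[0.5, 0.5], [1.0, 2.0]])
        t2 = np.array([[2.0, -1.0], [0.0, 1.0]])
        val = consistency_loss([g1, g2], [t1, t2]).data
        gn1, gn2, tn1, tn2 = map(_norm_rows, (g1, g2, t1, t2))
        inner = (gn1 * gn2).sum(axis=1) + (tn1 * tn2).sum(axis=1)
        expected = -np.log(_sigmoid(inner)).mean()
        assert abs(val - expected) <= 1e-10

    def test_symmetric_under_view_swap(self):
        g1, g2 = RNG.standard_normal((4, 3)), RNG.standard_normal((4, 3))
        t1, t2 = RNG.standard_normal((4, 3)), RNG.standard_normal((4, 3))
        a = consistency_loss([g1, g2], [t1, t2]).data
        b = consistency_loss([g2, g1], [t2, t1]).data
        assert abs(a - b) <= 1e-12

    def test_aligned_views_beat_opposed_views(self):
        g = RNG.standard_normal((6, 4))
        t = RNG.standard_normal((6, 4))
        low = consistency_loss([g, g], [t, t]).data
        high = consistency_loss([g, -g], [t, -t]).data
        assert low < high


class TestProjectionHead:
    def test_output_dim(self):
        head = ProjectionHead(6, out_dim=3, seed=0)
        assert head(RNG.standard_normal((5, 6))).shape == (5, 3)

    def test_shared_parameters_across_branches(self):
        head = ProjectionHead(4, seed=1)
        params_a = head.parameters()
        # both calls go through the very same parameter tensors
        head(RNG.standard_normal((2, 4)))
        head(RNG.standard_normal((7, 4)))
        assert all(pa is pb for pa, pb in zip(params_a, head.parameters()))

    def test_identity_weights_give_elementwise_elu(self):
        head = ProjectionHead(3, out_dim=3, hidden=3, seed=2)
        for lin in (head.lin1, head.lin2):
            lin.weight.data = np.eye(3)
            lin.bias.data[:] = 0.0
        z = RNG.standard_normal((4, 3))
        expected = np.where(z > 0, z, np.expm1(z))
        assert np.allclose(head(z).data, expected, atol=1e-12)


class TestPairwiseSimilarity:
    def test_closed_forms(self):
        phi = np.array([[1.0, 0.0], [0.0, 1.0]])
        sim = pairwise_similarity(phi, phi, tau=0.5).data
        assert sim[0, 0] == pytest.approx(np.exp(2.0), rel=1e-12)
        assert sim[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_pair_loop(self):
        a, b = RNG.standard_normal((3, 2)), RNG.standard_normal((3, 2))
        sim = pairwise_similarity(a, b, tau=0.7).data
        for i in range(3):
            for j in range(3):
                c = a[i] @ b[j] / (np.linalg.norm(a[i]) * np.linalg.norm(b[j]))
                assert abs(sim[i, j] - np.exp(c / 0.7)) <= 1e-12

    def test_errors(self):
        with pytest.raises(ValueError, match="tau"):
            pairwise_similarity(np.ones((2, 2)), np.ones((2, 2)), tau=0.0)
        with pytest.raises(ValueError, match="zero-norm"):
            pairwise_similarity(np.zeros((2, 2)), np.ones((2, 2)), tau=0.5)


class TestContrastiveLoss:
    def test_gamma_endpoints(self):
        a, b = RNG.standard_normal((4, 3)), RNG.standard_normal((4, 3))
        mp = np.eye(4)
        full = contrastive_loss(a, b, mp, tau=0.5, gamma=0.4).data
        l_lv = contrastive_loss(a, b, mp, tau=0.5, gamma=1.0).data
        l_gv = contrastive_loss(a, b, mp, tau=0.5, gamma=0.0).data
        assert abs(full - (0.4 * l_lv + 0.6 * l_gv)) <= 1e-12

    def test_hand_expansion_n2(self):
        phi_l = np.array([[1.0, 0.0], [0.0, 1.0]])
        phi_g = np.array([[0.8, 0.6], [-0.6, 0.8]])
        tau, gamma = 0.5, 0.4
        val = contrastive_loss(phi_l, phi_g, np.eye(2), tau, gamma).data

        def direction(a, b):
            total = 0.0
            for i in range(2):
                sims = [np.exp(a[i] @ b[j] / (np.linalg.norm(a[i])
                        * np.linalg.norm(b[j])) / tau) for j in range(2)]
                total += -np.log(sims[i] / sum(sims))
            return total / 2

        expected = gamma * direction(phi_l, phi_g) + \
            (1 - gamma) * direction(phi_g, phi_l)
        assert abs(val - expected) <= 1e-10

    def test_alignment_is_rewarded(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            phi = rng.standard_normal((8, 4)) + 3 * np.eye(8, 4)
            perm = rng.permutation(8)
            aligned = contrastive_loss(phi, phi, np.eye(8)).data
            shuffled = contrastive_loss(phi, phi[perm], np.eye(8)).data
            wins += aligned < shuffled
        assert wins == 20

    def test_interpolating_toward_alignment_decreases_loss(self):
        losses = {t: [] for t in (0.0, 0.5, 1.0)}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            phi_l = rng.standard_normal((6, 4))
            phi_g = rng.standard_normal((6, 4))
            for t in losses:
                mix = (1 - t) * phi_g + t * phi_l
                losses[t].append(
                    contrastive_loss(phi_l, mix, np.eye(6)).data)
        means = [np.mean(losses[t]) for t in (0.0, 0.5, 1.0)]
        assert means[0] > means[1] > means[2]

    def test_empty_mask_row_names_row(self):
        mp = np.eye(3)
        mp[1, 1] = 0
        with pytest.raises(ValueError, match="row 1"):
            contrastive_loss(RNG.standard_normal((3, 2)),
                             RNG.standard_normal((3, 2)), mp)

    def test_same_label_mask(self):
        mp = positive_mask(4, "same_label", labels=np.array([0, 1, 0, 1]))
        assert np.array_equal(mp, np.array([[1, 0, 1, 0], [0, 1, 0, 1],
                                            [1, 0, 1, 0], [0, 1, 0, 1]]))


class TestCrossEntropy:
    def test_closed_form_half(self):
        assert cross_entropy(np.array([0.5]), np.array([1.0])).data == \
            pytest.approx(np.log(2), rel=1e-12)

    def test_perfect_predictions_near_zero(self):
        val = cross_entropy(np.array([1.0, 0.0]), np.array([1.0, 0.0])).data
        assert 0 <= val <= 1e-6

    def test_batch_matches_direct_formula(self):
        p = np.array([0.9, 0.2, 0.7])
        y = np.array([1.0, 0.0, 1.0])
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert abs(cross_entropy(p, y).data - expected) <= 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy(np.array([0.5]), np.array([1.0, 0.0]))


class TestTotalLoss:
    def test_arithmetic(self):
        assert total_loss(1.0, 2.0, 3.0, alpha=0.5, beta=0.1).data == \
            pytest.approx(2.3, abs=1e-12)

    def test_zero_weights_reduce_to_ce(self):
        assert total_loss(1.7, 9.0, 9.0, alpha=0.0, beta=0.0).data == \
            pytest.approx(1.7, abs=1e-12)

    def test_defaults(self):
        from popconn.config import LossConfig

        cfg = LossConfig()
        assert (cfg.alpha, cfg.beta, cfg.gamma) == (0.1, 0.01, 0.4)


class TestGradientSanity:
    """Finite-difference gradients of every loss on 3x2 toys."""

    def _check(self, build, x0):
        t = Tensor(x0.copy(), requires_grad=True)
        build(t).backward()
        num = numeric_gradient(lambda arr: float(build(Tensor(arr)).data),
                               x0.copy())
        denom = np.maximum(np.abs(num), 1e-3)
        assert np.max(np.abs(t.grad - num) / denom) <= 1e-4

    def test_consistency_gradient(self):
        other = RNG.standard_normal((3, 2))
        t_fix = RNG.standard_normal((3, 2))
        self._check(
            lambda g: consistency_loss([g, other], [t_fix, t_fix]),
            RNG.standard_normal((3, 2)),
        )

    def test_contrastive_gradient(self):
        other = RNG.standard_normal((3, 2))
        self._check(
            lambda p: contrastive_loss(p, Tensor(other), np.eye(3)),
            RNG.standard_normal((3, 2)),
        )

    def test_cross_entropy_gradient(self):
        y = np.array([1.0, 0.0, 1.0])
        self._check(
            lambda p: cross_entropy(p.sigmoid(), y),
            RNG.standard_normal(3),
        )
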