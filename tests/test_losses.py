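import numpy as np
import pytest

import msffnet as mf
from msffnet.losses import (
    HL1_WEIGHTS,
    HL2_WEIGHTS,
    LossWeights,
    combined_dice_loss,
    cross_entropy,
    dice_loss_class,
    dice_loss_region,
    hybrid_hl1,
    hybrid_hl2,
    recall_loss,
    sliced_dice_loss,
)

from .oracles import (
    naive_combined_dice,
    naive_cross_entropy,
    naive_dice_class,
    naive_dice_region,
    naive_hl1,
    naive_hl2,
    naive_recall,
    naive_sliced_dice,
)


def _one_channel_pair(p_vals, g_vals, k=1):
    """Build (N,1,5) maps whose channel-k values are given; rest on channel 0."""
    n = len(p_vals)
    P = np.zeros((n, 1, 5))
    G = np.zeros((n, 1, 5))
    P[:, 0, k] = p_vals
    P[:, 0, 0] = 1.0 - np.asarray(p_vals)
    G[:, 0, k] = g_vals
    G[:, 0, 0] = 1.0 - np.asarray(g_vals)
    return P, G


class TestCrossEntropy:
    def test_zero_at_truth(self, rng):
        G = mf.one_hot(rng.integers(0, 5, (6, 6)))
        assert cross_entropy(G, G) <= 1e-6

    def test_uniform_prediction_closed_form(self):
        G = mf.one_hot(np.zeros((4, 4), int))
        P = np.full((4, 4, 5), 0.2)
        assert cross_entropy(P, G) == pytest.approx(np.log(5), abs=1e-9)

    def test_half_probability_single_pixel(self):
        P = np.array([[[0.5, 0.5, 0, 0, 0]]], float)
        G = np.array([[[1.0, 0, 0, 0, 0]]], float)
        assert cross_entropy(P, G) == pytest.approx(np.log(2), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy(np.ones((2, 2, 5)), np.ones((3, 2, 5)))


class TestDice:
    def test_hand_example(self):
        P, G = _one_channel_pair([1.0, 0.5, 0.0, 0.0], [1.0, 1.0, 0.0, 0.0])
        assert dice_loss_class(P, G, 1) == pytest.approx(1 - 3 / 3.5, abs=1e-4)

    def test_zero_at_truth_and_absent_class(self, rng):
        G = mf.one_hot(rng.integers(0, 2, (5, 5)))  # classes 0 and 1 only
        assert dice_loss_class(G, G, 1) == pytest.approx(0.0, abs=1e-4)
        assert dice_loss_class(G, G, 4) == pytest.approx(0.0, abs=1e-9)  # absent: smoothed

    def test_region_hand_example(self):
        # 2 pixels: truth (edema, background); complete region matches exactly,
        # core region predicted 0.5 mass against an empty truth.
        G = mf.one_hot(np.array([[2, 0]]))
        P = np.array([[[0, 0.5, 0.5, 0, 0], [1, 0, 0, 0, 0]]], float)
        assert dice_loss_region(P, G, "complete") == pytest.approx(0.0, abs=1e-4)
        s = 1e-5
        expected = 1 - s / (0.5 + s)
        assert dice_loss_region(P, G, "core") == pytest.approx(expected, abs=1e-6)

    def test_combined_is_sum_of_components(self, random_probs):
        P, G = random_probs
        parts = sum(
            dice_loss_region(P, G, r) for r in ("background", "complete", "core", "enhancing")
        )
        assert combined_dice_loss(P, G) == pytest.approx(parts, abs=1e-12)
        assert 0 <= combined_dice_loss(P, G) <= 4

    def test_sliced_uniform_closed_form(self):
        # Uniform P on a single-class truth: DL_c = 1 - (2N/5)/(N/5 + N) = 2/3,
        # and each of the four absent classes contributes ~1.
        G = mf.one_hot(np.full((6, 6), 2))
        P = np.full((6, 6, 5), 0.2)
        assert sliced_dice_loss(P, G) == pytest.approx(2 / 3 + 4.0, abs=1e-3)

    def test_permutation_invariance(self, rng, random_probs):
        P, G = random_probs
        perm = rng.permutation(64)
        Pp = P.reshape(64, 5)[perm].reshape(8, 8, 5)
        Gp = G.reshape(64, 5)[perm].reshape(8, 8, 5)
        assert sliced_dice_loss(Pp, Gp) == pytest.approx(sliced_dice_loss(P, G), abs=1e-12)


class TestRecall:
    def test_hand_example(self):
        P, G = _one_channel_pair([1.0, 0.5, 0.0, 0.0], [1.0, 1.0, 0.0, 0.0])
        assert recall_loss(P, G, 1) == pytest.approx(0.25, abs=1e-4)

    def test_total_miss(self):
        G = mf.one_hot(np.full((3, 3), 4))
        P = mf.one_hot(np.zeros((3, 3), int))
        assert recall_loss(P, G, "enhancing") == pytest.approx(1.0, abs=1e-4)

    def test_zero_at_truth(self, rng):
        G = mf.one_hot(rng.integers(0, 5, (5, 5)))
        for target in (0, 2, "complete", "core", "enhancing"):
            assert recall_loss(G, G, target) == pytest.approx(0.0, abs=1e-4)

    def test_false_positives_ignored(self):
        # Recall only cares about the truth's pixels: over-segmentation is free.
        G = mf.one_hot(np.array([[4, 0, 0]]))
        exact = mf.one_hot(np.array([[4, 0, 0]]))
        over = mf.one_hot(np.array([[4, 4, 4]]))
        assert recall_loss(over, G, "enhancing") == pytest.approx(
            recall_loss(exact, G, "enhancing"), abs=1e-9
        )


class TestHybrid:
    def test_hl1_weighted_sum_of_components(self, random_probs):
        P, G = random_probs
        expected = (
            20.0 * cross_entropy(P, G)
            + 0.5 * recall_loss(P, G, "complete")
            + 1.0 * recall_loss(P, G, "core")
            + 0.5 * recall_loss(P, G, "enhancing")
        )
        assert hybrid_hl1(P, G) == pytest.approx(expected, abs=1e-10)

    def test_hl2_weighted_sum_of_components(self, random_probs):
        P, G = random_probs
        expected = (
            1.0 * combined_dice_loss(P, G)
            + 0.1 * recall_loss(P, G, "complete")
            + 1.3 * recall_loss(P, G, "core")
            + 0.5 * recall_loss(P, G, "enhancing")
        )
        assert hybrid_hl2(P, G) == pytest.approx(expected, abs=1e-10)

    def test_published_default_weights(self):
        assert (HL1_WEIGHTS.alpha, HL1_WEIGHTS.beta, HL1_WEIGHTS.gamma, HL1_WEIGHTS.delta) == (
            20.0, 0.5, 1.0, 0.5,
        )
        assert (HL2_WEIGHTS.alpha, HL2_WEIGHTS.beta, HL2_WEIGHTS.gamma, HL2_WEIGHTS.delta) == (
            1.0, 0.1, 1.3, 0.5,
        )

    def test_linearity_in_weights(self, random_probs):
        P, G = random_probs
        w = LossWeights(2.0, 0.4, 0.6, 0.8)
        w2 = LossWeights(4.0, 0.8, 1.2, 1.6)
        assert hybrid_hl1(P, G, w2) == pytest.approx(2 * hybrid_hl1(P, G, w), abs=1e-10)

    def test_hl2_reduces_to_combined_dice(self, random_probs):
        P, G = random_probs
        w = LossWeights(1.0, 0.0, 0.0, 0.0)
        assert hybrid_hl2(P, G, w) == pytest.approx(combined_dice_loss(P, G), abs=1e-12)

    def test_perfect_prediction_near_zero(self, rng):
        G = mf.one_hot(rng.integers(0, 5, (6, 6)))
        assert hybrid_hl1(G, G) <= 20 * 1e-6 + 1e-6
        assert hybrid_hl2(G, G) <= 1e-4


def _edge_case_pairs(rng):
    """One-hot, uniform and empty-region pairs plus random soft maps."""
    pairs = []
    G = mf.one_hot(rng.integers(0, 5, (8, 8)))
    pairs.append((G.copy(), G))                       # exact one-hot
    pairs.append((np.full((8, 8, 5), 0.2), G))        # uniform prediction
    bg = mf.one_hot(np.zeros((8, 8), int))
    pairs.append((np.full((8, 8, 5), 0.2), bg))       # empty tumor regions
    pairs.append((bg.copy(), bg))                     # both empty
    return pairs


class TestOracleEquivalence:
    """Vectorized losses must match naive per-pixel double loops to 1e-6."""

    def test_fifty_random_pairs_plus_edge_cases(self, rng):
        pairs = _edge_case_pairs(rng)
        while len(pairs) < 50:
            raw = rng.random((8, 8, 5)) + 1e-4
            P = raw / raw.sum(-1, keepdims=True)
            G = mf.one_hot(rng.integers(0, 5, (8, 8)))
            pairs.append((P, G))
        for P, G in pairs:
            assert cross_entropy(P, G) == pytest.approx(naive_cross_entropy(P, G), abs=1e-6)
            for k in range(5):
                assert dice_loss_class(P, G, k) == pytest.approx(
                    naive_dice_class(P, G, k), abs=1e-6
                )
            for r in ("background", "complete", "core", "enhancing"):
                assert dice_loss_region(P, G, r) == pytest.approx(
                    naive_dice_region(P, G, r), abs=1e-6
                )
                assert recall_loss(P, G, r) == pytest.approx(naive_recall(P, G, r), abs=1e-6)
            assert combined_dice_loss(P, G) == pytest.approx(naive_combined_dice(P, G), abs=1e-6)
            assert sliced_dice_loss(P, G) == pytest.approx(naive_sliced_dice(P, G), abs=1e-6)
            assert hybrid_hl1(P, G) == pytest.approx(naive_hl1(P, G), abs=1e-6)
            assert hybrid_hl2(P, G) == pytest.approx(naive_hl2(P, G), abs=1e-6)


class TestGradients:
    """Analytic dL/dP matches central finite differences to 1e-4 on 4x4 maps."""

    @pytest.mark.parametrize(
        "fn",
        [
            lambda P, G, g: cross_entropy(P, G, return_grad=g),
            lambda P, G, g: dice_loss_class(P, G, 2, return_grad=g),
            lambda P, G, g: dice_loss_region(P, G, "core", return_grad=g),
            lambda P, G, g: combined_dice_loss(P, G, return_grad=g),
            lambda P, G, g: sliced_dice_loss(P, G, return_grad=g),
            lambda P, G, g: recall_loss(P, G, "complete", return_grad=g),
            lambda P, G, g: hybrid_hl1(P, G, return_grad=g),
            lambda P, G, g: hybrid_hl2(P, G, return_grad=g),
        ],
        ids=["ce", "dice_class", "dice_region", "combined", "sliced", "recall", "hl1", "hl2"],
    )
    def test_finite_difference_agreement(self, fn, rng):
        raw = rng.random((4, 4, 5)) + 0.05
        P = raw / raw.sum(-1, keepdims=True)
        G = mf.one_hot(rng.integers(0, 5, (4, 4)))
        _, grad = fn(P, G, True)
        h = 1e-6
        for _ in range(12):
            idx = tuple(rng.integers(0, s) for s in P.shape)
            old = P[idx]
            P[idx] = old + h
            v1 = fn(P, G, False)
            P[idx] = old - h
            v2 = fn(P, G, False)
            P[idx] = old
            assert (v1 - v2) / (2 * h) == pytest.approx(grad[idx], abs=1e-4)


class TestPoolingAndBounds:
    def test_batch_pooling_equals_flattened(self, rng):
        """A batch behaves exactly like one big image (sums pooled over N*H*W)."""
        raw = rng.random((3, 4, 4, 5)) + 1e-3
        P = raw / raw.sum(-1, keepdims=True)
        G = mf.one_hot(rng.integers(0, 5, (3, 4, 4)))
        Pf, Gf = P.reshape(1, 48, 1, 5), G.reshape(1, 48, 1, 5)
        for fn in (cross_entropy, combined_dice_loss, sliced_dice_loss, hybrid_hl1, hybrid_hl2):
            assert fn(P, G) == pytest.approx(fn(Pf, Gf), abs=1e-10)

    def test_ratio_losses_bounded_unit_interval(self, rng):
        for _ in range(20):
            raw = rng.random((6, 6, 5)) + 1e-4
            P = raw / raw.sum(-1, keepdims=True)
            G = mf.one_hot(rng.integers(0, 5, (6, 6)))
            for k in range(5):
                assert 0.0 <= dice_loss_class(P, G, k) <= 1.0
            for r in ("background", "complete", "core", "enhancing"):
                assert 0.0 <= dice_loss_region(P, G, r) <= 1.0
                assert 0.0 <= recall_loss(P, G, r) <= 1.0
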