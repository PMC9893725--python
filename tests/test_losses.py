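"""Closed forms and properties of the four training objectives."""

import math

import numpy as np
import pytest

from ustrack.boxes import Anchor, Box
from ustrack.losses import (
    AttentionPair,
    LMSoftmaxParams,
    LossWeights,
    MarginClsParams,
    attention_loss,
    box_head_loss,
    combined_loss,
    lm_softmax_mask_loss,
    margin_cls_loss,
    phi,
)


def make_pair(rng, offset=0.0, intensity_shift=0.0):
    box = Box(20, 20, 16, 16)
    out_box = Box(20 + offset, 20, 16, 16)
    u = rng.uniform(0, 255, size=(16, 16))
    v = u + intensity_shift
    # patches aligned to each box's top-left corner
    return AttentionPair(input_patch=u, target_patch=v, target_box=box,
                         output_box=out_box, anchor=Anchor(Box(20, 20, 100, 100)))


class TestAttentionLoss:
    def test_perfect_prediction_is_zero(self, rng):
        r = attention_loss(make_pair(rng))
        assert float(r) == pytest.approx(0.0)

    def test_unit_intensity_offset_gives_unit_image_term(self, rng):
        r = attention_loss(make_pair(rng, intensity_shift=1.0))
        assert r.box_term == pytest.approx(0.0)
        assert r.image_term == pytest.approx(1.0)
        assert r.total == pytest.approx(1.0)

    def test_zero_intersection_flagged(self, rng):
        pair = make_pair(rng)
        far = AttentionPair(pair.input_patch, pair.target_patch,
                            target_box=Box(200, 200, 16, 16),
                            output_box=pair.output_box, anchor=pair.anchor)
        r = attention_loss(far)
        assert r.empty_intersection
        assert r.image_term == 0.0
        assert r.total == pytest.approx(r.box_term)

    def test_loss_at_least_box_term(self, rng):
        for _ in range(200):
            pair = make_pair(rng, offset=rng.uniform(-8, 8),
                             intensity_shift=rng.uniform(-20, 20))
            r = attention_loss(pair)
            assert r.total >= r.box_term - 1e-12
            assert r.total >= 0


class TestMarginClsLoss:
    def test_hinge_inactive_when_margin_satisfied(self, rng):
        g_o, g_t = rng.normal(size=8), rng.normal(size=8)
        denom = 1e-6 + np.linalg.norm(g_o - g_t)
        f_t = 10.0
        f_o = f_t - 2.0 * denom  # f_t - f_o = 2*denom > gamma*denom
        assert margin_cls_loss([[(f_o, f_t, g_o, g_t)]],
                               MarginClsParams(gamma_margin=1.0)) == 0.0

    def test_equal_scores_give_gamma_per_term(self, rng):
        layers = [(0.5, 0.5, rng.normal(size=4), rng.normal(size=4)) for _ in range(3)]
        loss = margin_cls_loss([layers, layers], MarginClsParams(gamma_margin=0.7))
        assert loss == pytest.approx(0.7 * 6)

    def test_identical_gradients_epsilon_denominator(self):
        g = np.ones(5)
        loss = margin_cls_loss([[(1e-6, 0.0, g, g)]],
                               MarginClsParams(gamma_margin=1.0, epsilon=1e-6))
        assert loss == pytest.approx(2.0)

    def test_zero_gradients_unit_epsilon_reduces_to_plain_hinge(self):
        z = np.zeros(3)
        params = MarginClsParams(gamma_margin=1.0, epsilon=1.0)
        for f_o, f_t in [(0.3, 0.1), (-1.0, 2.0), (5.0, 1.0)]:
            expected = max(0.0, 1.0 + (f_o - f_t))
            assert margin_cls_loss([[(f_o, f_t, z, z)]], params) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            margin_cls_loss([[(0.0, 0.0, np.zeros(3), np.zeros(4))]])


class TestPhi:
    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_value_at_zero(self, m):
        assert phi(0.0, m) == pytest.approx(1.0)

    def test_known_value(self):
        # m=2, theta=pi -> k=1: -cos(2 pi) - 2 = -3
        assert phi(math.pi, 2) == pytest.approx(-3.0)

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_branch_continuity(self, m):
        for k in range(1, m):
            theta = k * math.pi / m
            left = (-1.0) ** (k - 1) * math.cos(m * theta) - 2 * (k - 1)
            right = (-1.0) ** k * math.cos(m * theta) - 2 * k
            assert abs(left - right) < 1e-12
            assert phi(theta, m) == pytest.approx(right, abs=1e-12)

    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_monotone_decreasing(self, m):
        grid = np.linspace(0, math.pi, 10_000)
        vals = [phi(t, m) for t in grid]
        assert all(a >= b - 1e-12 for a, b in zip(vals[:-1], vals[1:]))

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            phi(-0.1, 2)
        with pytest.raises(ValueError):
            phi(3.5, 2)


class TestLMSoftmax:
    def test_m1_equals_softmax_cross_entropy(self, rng):
        w = rng.normal(size=(6, 2))
        feats = [(rng.normal(size=6), int(rng.integers(2))) for _ in range(20)]
        loss = lm_softmax_mask_loss(feats, w, LMSoftmaxParams(m=1, lambda_reg=0.0))
        # oracle: plain CE on logits ||W_j|| ||x|| cos(theta_j) = W_j . x
        expected = 0.0
        for x, y in feats:
            logits = w.T @ x
            expected += -(logits[y] - np.logaddexp(logits[0], logits[1]))
        assert loss == pytest.approx(expected, abs=1e-6)

    def test_aligned_orthonormal_case(self):
        w = np.eye(2)
        x = np.array([3.0, 0.0])  # aligned with class-0 column, orthogonal to class 1
        loss = lm_softmax_mask_loss([(x, 0)], w, LMSoftmaxParams(m=2, lambda_reg=0.0))
        expected = -math.log(math.exp(3.0) / (math.exp(3.0) + 1.0))
        assert loss == pytest.approx(expected, abs=1e-9)

    def test_margin_monotonicity(self, rng):
        w = np.eye(3)[:, :2]
        for _ in range(20):
            # correctly classified feature near class 0's column
            x = np.array([1.0, 0.2, 0.0]) + rng.normal(scale=0.05, size=3)
            l2 = lm_softmax_mask_loss([(x, 0)], w, LMSoftmaxParams(m=2, lambda_reg=0.0))
            l4 = lm_softmax_mask_loss([(x, 0)], w, LMSoftmaxParams(m=4, lambda_reg=0.0))
            assert l4 >= l2 - 1e-9

    def test_zero_feature_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            lm_softmax_mask_loss([(np.zeros(4), 1)], np.eye(4)[:, :2])

    def test_weight_penalty(self):
        w = np.array([[2.0, 0.0], [0.0, 1.0]])
        base = lm_softmax_mask_loss([(np.array([1.0, 0]), 0)], w,
                                    LMSoftmaxParams(m=1, lambda_reg=0.0))
        reg = lm_softmax_mask_loss([(np.array([1.0, 0]), 0)], w,
                                   LMSoftmaxParams(m=1, lambda_reg=0.1))
        assert reg == pytest.approx(base + 0.1 * 5.0)


class TestLMSoftmaxGradients:
    def test_finite_difference_gradcheck(self, rng):
        """The differentiable training graph matches finite differences."""
        from ustrack.autodiff import Tensor
        from ustrack.nets import _lm_softmax_t

        params = LMSoftmaxParams(m=2, lambda_reg=1e-3)
        feats = rng.normal(size=(6, 4)) + 0.5
        labels = rng.integers(0, 2, size=6)
        w0 = rng.normal(size=(4, 2))

        def numpy_loss(wdata, fdata):
            return lm_softmax_mask_loss(
                [(fdata[i], int(labels[i])) for i in range(len(labels))], wdata, params)

        wt = Tensor(w0, requires_grad=True)
        ft = Tensor(feats, requires_grad=True)
        loss = _lm_softmax_t(ft, labels, wt, params)
        assert loss.item() == pytest.approx(numpy_loss(w0, feats), abs=1e-8)
        loss.backward()
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (3, 0)]:
            w1 = w0.copy(); w1[idx] += eps
            w2 = w0.copy(); w2[idx] -= eps
            fd = (numpy_loss(w1, feats) - numpy_loss(w2, feats)) / (2 * eps)
            assert wt.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)
        for idx in [(0, 1), (4, 2)]:
            f1 = feats.copy(); f1[idx] += eps
            f2 = feats.copy(); f2[idx] -= eps
            fd = (numpy_loss(w0, f1) - numpy_loss(w0, f2)) / (2 * eps)
            assert ft.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestBoxHeadAndCombination:
    def test_perfect_prediction(self):
        assert box_head_loss([[0.3, -0.2]], [[0.3, -0.2]]) == 0.0

    def test_unit_center_error(self):
        assert box_head_loss([[1.0, 0.0]], [[0.0, 0.0]]) == pytest.approx(0.5)

    def test_large_error_uses_linear_branch(self):
        assert box_head_loss([[3.0, 4.0]], [[0.0, 0.0]]) == pytest.approx(6.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            box_head_loss([[0, 0]], [[0, 0], [1, 1]])

    @pytest.mark.parametrize("triplet,expected", [((1, 1, 1), 1.0), ((0, 0, 2), 1.2),
                                                  ((5, 0, 0), 1.0)])
    def test_combined_defaults(self, triplet, expected):
        assert combined_loss(*triplet) == pytest.approx(expected)

    def test_combined_is_linear(self, rng):
        w = LossWeights()
        a, b, c = rng.uniform(0, 5, 3)
        assert combined_loss(2 * a, 2 * b, 2 * c, w) == pytest.approx(
            2 * combined_loss(a, b, c, w))

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            LossWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            LossWeights(-0.2, 0.6, 0.6)
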