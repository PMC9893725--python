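"""Training objectives for the cascade tracker.

Four losses drive learning:

* :func:`attention_loss` — search-region regression: squared error of the
  box-delta encodings plus a mean squared intensity difference over the
  intersection pixels of the predicted and ground-truth boxes.
* :func:`margin_cls_loss` — a large-margin hinge on classification scores,
  normalized by the norm of the score-gradient difference at each supervised
  layer (deep supervision: the per-layer margins are summed).
* :func:`lm_softmax_mask_loss` — large-margin softmax for binary pixel
  (mask) classification, with the angular margin ``phi`` applied to the
  true-class angle and a Frobenius weight penalty.
* :func:`box_head_loss` — robust (smooth-L1) regression of the box center;
  the box size is fixed at 20 x 20 px so only centers are regressed.

The total detector objective is ``w1*L_cls + w2*L_mask + w3*L_box`` with
weights defaulting to (0.2, 0.2, 0.6) to emphasize box regression.

These are pure numpy reference implementations; the differentiable graphs
used during training (:mod:`ustrack.nets`) mirror them and are tested for
agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boxes import Anchor, Box, encode_delta, smooth_l1

__all__ = [
    "LossWeights",
    "MarginClsParams",
    "LMSoftmaxParams",
    "AttentionPair",
    "AttentionLossResult",
    "attention_loss",
    "margin_cls_loss",
    "lm_softmax_mask_loss",
    "phi",
    "box_head_loss",
    "combined_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights (w1, w2, w3) for (classification, mask, box); must sum to 1."""

    w1: float = 0.2
    w2: float = 0.2
    w3: float = 0.6

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("loss weights must be nonnegative")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")


@dataclass(frozen=True)
class MarginClsParams:
    """Parameters of the large-margin classification hinge.

    gamma_margin is the decision boundary; epsilon guards the gradient-norm
    denominator against numerical instability; ``layers`` names the
    activations used for deep supervision.
    """

    gamma_margin: float = 1.0
    epsilon: float = 1e-6
    layers: tuple[str, ...] = ("trunk", "cls_fc1")

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.gamma_margin <= 0:
            raise ValueError("gamma_margin must be positive")


@dataclass(frozen=True)
class LMSoftmaxParams:
    """Angular-margin softmax parameters: integer margin m and weight penalty."""

    m: int = 2
    lambda_reg: float = 1e-4

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("margin m must be a positive integer")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")


@dataclass(frozen=True)
class AttentionPair:
    """One training pair for the attention network.

    ``input_patch`` holds the image content of ``output_box`` and
    ``target_patch`` the content of ``target_box``; the patches' pixel grids
    are aligned to their boxes' top-left corners.
    """

    input_patch: np.ndarray
    target_patch: np.ndarray
    target_box: Box
    output_box: Box
    anchor: Anchor


@dataclass(frozen=True)
class AttentionLossResult:
    """Attention loss with its two terms; ``empty_intersection`` flags N = 0."""

    total: float
    box_term: float
    image_term: float
    empty_intersection: bool = False

    def __float__(self) -> float:
        return self.total


def _intersection_crops(pair: AttentionPair) -> tuple[np.ndarray, np.ndarray, int]:
    """Aligned crops of the two patches over the boxes' intersection, and N."""
    a, b = pair.output_box, pair.target_box
    ix0, ix1 = max(a.x0, b.x0), min(a.x1, b.x1)
    iy0, iy1 = max(a.y0, b.y0), min(a.y1, b.y1)
    nw = int(round(ix1 - ix0))
    nh = int(round(iy1 - iy0))
    if nw <= 0 or nh <= 0:
        return np.empty((0, 0)), np.empty((0, 0)), 0
    ua = int(round(ix0 - a.x0))
    va = int(round(iy0 - a.y0))
    ub = int(round(ix0 - b.x0))
    vb = int(round(iy0 - b.y0))
    u = np.asarray(pair.input_patch, dtype=float)[va : va + nh, ua : ua + nw]
    v = np.asarray(pair.target_patch, dtype=float)[vb : vb + nh, ub : ub + nw]
    nh = min(u.shape[0], v.shape[0])
    nw = min(u.shape[1], v.shape[1])
    return u[:nh, :nw], v[:nh, :nw], nh * nw


def attention_loss(pair: AttentionPair) -> AttentionLossResult:
    """Squared delta-encoding error plus mean squared intensity difference.

    Both the target and output boxes are encoded against the pair's anchor
    (the input search patch); the image term averages the squared intensity
    difference over the N intersection pixels of the two boxes.  When the
    boxes do not intersect the image term is 0 and the result is flagged.
    """
    t = encode_delta(pair.target_box, pair.anchor).as_array()
    o = encode_delta(pair.output_box, pair.anchor).as_array()
    box_term = float(np.sum((t - o) ** 2))
    u, v, n = _intersection_crops(pair)
    if n == 0:
        return AttentionLossResult(box_term, box_term, 0.0, empty_intersection=True)
    image_term = float(np.sum((u - v) ** 2) / n)
    return AttentionLossResult(box_term + image_term, box_term, image_term)


def margin_cls_loss(
    per_layer_scores: list[list[tuple[float, float, np.ndarray, np.ndarray]]],
    params: MarginClsParams = MarginClsParams(),
) -> float:
    """Deep-supervised large-margin hinge over samples and layers.

    ``per_layer_scores[i][l]`` is ``(f_o, f_t, grad_o, grad_t)`` for sample i
    at supervised layer l: the scores for the predicted-wrong class o and the
    true class t, and the gradients of those scores with respect to the
    layer-l activations.  Each term is

        max{0, gamma + (f_o - f_t) / (epsilon + ||grad_o - grad_t||_2)}.
    """
    total = 0.0
    for sample in per_layer_scores:
        for f_o, f_t, grad_o, grad_t in sample:
            go = np.asarray(grad_o, dtype=float)
            gt = np.asarray(grad_t, dtype=float)
            if go.shape != gt.shape:
                raise ValueError(
                    f"gradient shapes differ: {go.shape} vs {gt.shape}"
                )
            denom = params.epsilon + float(np.linalg.norm((go - gt).ravel()))
            total += max(0.0, params.gamma_margin + (float(f_o) - float(f_t)) / denom)
    return total


def phi(theta: float, m: int) -> float:
    """Piecewise angular margin: (-1)^k cos(m*theta) - 2k on [k*pi/m, (k+1)*pi/m].

    Continuous and strictly decreasing on [0, pi]; phi(0) = 1, phi(pi) = 1 - 2m.
    """
    if not 0.0 <= theta <= math.pi + 1e-12:
        raise ValueError(f"theta must lie in [0, pi], got {theta}")
    if m < 1:
        raise ValueError("m must be a positive integer")
    theta = min(theta, math.pi)
    k = min(int(theta * m / math.pi), m - 1)
    return (-1.0) ** k * math.cos(m * theta) - 2.0 * k


def lm_softmax_mask_loss(
    pixel_features: list[tuple[np.ndarray, int]],
    last_layer_weights: np.ndarray,
    params: LMSoftmaxParams = LMSoftmaxParams(),
) -> float:
    """Binary large-margin softmax over pixel feature vectors.

    ``last_layer_weights`` has one column per class (shape (d, 2)).  For each
    pixel with feature x and label y, the true-class logit is
    ``||W_y|| * ||x|| * phi(theta_y)`` with the angular margin applied, while
    the other class keeps its plain ``||W_j|| * ||x|| * cos(theta_j)`` logit;
    the loss is the negative log of the resulting two-way softmax plus
    ``lambda * ||W||_F^2``.
    """
    w = np.asarray(last_layer_weights, dtype=float)
    if w.ndim != 2 or w.shape[1] != 2:
        raise ValueError("last_layer_weights must have shape (d, 2)")
    wnorm = np.linalg.norm(w, axis=0)
    total = 0.0
    for x, y in pixel_features:
        x = np.asarray(x, dtype=float).ravel()
        xn = np.linalg.norm(x)
        if xn == 0:
            raise ValueError("zero-norm pixel feature: angle to weight columns undefined")
        y = int(y)
        cos = (w.T @ x) / (np.maximum(wnorm, 1e-300) * xn)
        cos = np.clip(cos, -1.0, 1.0)
        theta_y = float(np.arccos(cos[y]))
        s_true = wnorm[y] * xn * phi(theta_y, params.m)
        s_other = wnorm[1 - y] * xn * cos[1 - y]
        # -log(e^{s_true} / (e^{s_true} + e^{s_other})), computed stably
        total += float(np.logaddexp(0.0, s_other - s_true))
    return total + params.lambda_reg * float(np.sum(w * w))


def box_head_loss(pred_deltas: np.ndarray, target_deltas: np.ndarray) -> float:
    """Smooth-L1 loss on paired center deltas (t_x, t_y) vs (o_x, o_y).

    Box size is fixed (20 x 20 px) so only centers enter the objective.
    """
    p = np.atleast_2d(np.asarray(pred_deltas, dtype=float))
    t = np.atleast_2d(np.asarray(target_deltas, dtype=float))
    if p.shape != t.shape:
        raise ValueError(f"pred/target shapes differ: {p.shape} vs {t.shape}")
    if p.shape[1] != 2:
        raise ValueError("deltas must be (n, 2) center offsets")
    d = p - t
    return float(np.sum(smooth_l1(d[:, 0])) + np.sum(smooth_l1(d[:, 1])))


def combined_loss(l_cls: float, l_mask: float, l_box: float,
                  weights: LossWeights = LossWeights()) -> float:
    """Weighted sum ``w1*l_cls + w2*l_mask + w3*l_box``."""
    return weights.w1 * l_cls + weights.w2 * l_mask + weights.w3 * l_box
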