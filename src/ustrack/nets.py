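"""Trainable components of the cascade tracker and their training loop.

Three networks cooperate at inference time:

* an **attention network** that maps a 100 x 100 px patch centered on the
  previous landmark position to a reduced search-region box (a box delta
  decoded against the patch);
* a **detector** in the mask R-CNN mould: a small convolutional backbone, a
  two-level feature pyramid, a region-proposal stage over sliding-window
  anchors, and three heads per pooled proposal — binary classification
  (large-margin hinge with deep supervision), center regression for a fixed
  20 x 20 box (smooth-L1), and a binary mask (large-margin softmax);
* **LSTM temporal heads** that re-score and re-center proposals from the
  features of up to five consecutive frames; the mask head deliberately
  bypasses the LSTM so abrupt motion cannot corrupt pixel classification.

All computation runs on the package's numpy autodiff engine and is a
deterministic function of (input, weights); training is reproducible under
a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize


from .autodiff import Adam, Tensor, conv2d
from .boxes import Anchor, Box, BoxDelta, decode_delta, encode_delta, generate_anchors, iou
from .io import LandmarkTrack, USSequence
from .losses import LMSoftmaxParams, LossWeights, MarginClsParams

__all__ = [
    "LSTMParams",
    "LSTMState",
    "ProposalRecord",
    "DetectorConfig",
    "TrainConfig",
    "ModelWeights",
    "lstm_step",
    "AttentionNet",
    "Detector",
    "TemporalHead",
    "attention_forward",
    "detector_forward",
    "temporal_head",
    "train_model",
    "crop_patch",
    "save_weights",
    "load_weights",
]

ATTENTION_PATCH_SIZE = 100  # px, the predefined search box around the previous position


# --------------------------------------------------------------------------- #
# LSTM cell
# --------------------------------------------------------------------------- #
@dataclass
class LSTMParams:
    """Gate weight matrices/biases of one LSTM cell (input, forget, cell, output)."""

    W_ii: np.ndarray
    W_hi: np.ndarray
    W_if: np.ndarray
    W_hf: np.ndarray
    W_ig: np.ndarray
    W_hg: np.ndarray
    W_io: np.ndarray
    W_ho: np.ndarray
    b_ii: np.ndarray
    b_hi: np.ndarray
    b_if: np.ndarray
    b_hf: np.ndarray
    b_ig: np.ndarray
    b_hg: np.ndarray
    b_io: np.ndarray
    b_ho: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_hi.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_ii.shape[1]

    @staticmethod
    def zeros(input_size: int, hidden_size: int) -> "LSTMParams":
        ih = (hidden_size, input_size)
        hh = (hidden_size, hidden_size)
        z = np.zeros
        return LSTMParams(
            z(ih), z(hh), z(ih), z(hh), z(ih), z(hh), z(ih), z(hh),
            z(hidden_size), z(hidden_size), z(hidden_size), z(hidden_size),
            z(hidden_size), z(hidden_size), z(hidden_size), z(hidden_size),
        )


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray

    @staticmethod
    def zeros(hidden_size: int) -> "LSTMState":
        return LSTMState(h=np.zeros(hidden_size), c=np.zeros(hidden_size))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_step(x_t: np.ndarray, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One LSTM update: gates i, f, g, o; c_t = f*c + i*g; h_t = o*tanh(c_t)."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (params.input_size,):
        raise ValueError(f"input shape {x_t.shape} != ({params.input_size},)")
    if state.h.shape != (params.hidden_size,) or state.c.shape != (params.hidden_size,):
        raise ValueError("state shape inconsistent with params")
    h, c = state.h, state.c
    i = _sigmoid(params.W_ii @ x_t + params.b_ii + params.W_hi @ h + params.b_hi)
    f = _sigmoid(params.W_if @ x_t + params.b_if + params.W_hf @ h + params.b_hf)
    g = np.tanh(params.W_ig @ x_t + params.b_ig + params.W_hg @ h + params.b_hg)
    o = _sigmoid(params.W_io @ x_t + params.b_io + params.W_ho @ h + params.b_ho)
    c_t = f * c + i * g
    h_t = o * np.tanh(c_t)
    return LSTMState(h=h_t, c=c_t)


# --------------------------------------------------------------------------- #
# Module plumbing
# --------------------------------------------------------------------------- #
class Module:
    """Parameter container with recursive traversal and a flat state dict."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        out.append(item)
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, v in vars(self).items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out[name] = v.data
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix=name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(prefix=f"{name}.{i}."))
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in vars(self).items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                v.data = np.asarray(sd[name], dtype=float)
            elif isinstance(v, Module):
                v.load_state_dict(sd, prefix=name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(sd, prefix=f"{name}.{i}.")


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero: bool = False):
        scale = 0.0 if zero else math.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_out, n_in)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return self.W @ x + self.b


class Conv(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0):
        scale = math.sqrt(2.0 / (c_in * k * k))
        self.W = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.W, self.b, stride=self.stride, pad=self.pad)


def _avg_pool2(x: Tensor) -> Tensor:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).sum(axis=4).sum(axis=2) * 0.25


def _upsample2(x: Tensor) -> Tensor:
    c, h, w = x.shape
    idx_h = np.repeat(np.arange(h), 2)
    idx_w = np.repeat(np.arange(w), 2)
    return x[:, idx_h, :][:, :, idx_w]


def _softplus(x: Tensor) -> Tensor:
    # log(1 + e^x), numerically stable
    return x.relu() + ((-(x.abs())).exp() + 1.0).log()


def _smooth_l1_t(u: Tensor) -> Tensor:
    mask = (np.abs(u.data) < 1.0).astype(float)
    return u * u * 0.5 * mask + (u.abs() - 0.5) * (1.0 - mask)


# --------------------------------------------------------------------------- #
# Patch cropping
# --------------------------------------------------------------------------- #
def crop_patch(frame: np.ndarray, center: tuple[float, float], size: int
               ) -> tuple[np.ndarray, Box]:
    """Extract a ``size x size`` patch centered (to the pixel) on ``center``.

    Regions outside the frame are zero-padded.  Returns the patch and its
    anchor :class:`Box` in frame coordinates.
    """
    h, w = frame.shape
    tlx = int(round(center[0])) - size // 2
    tly = int(round(center[1])) - size // 2
    patch = np.zeros((size, size), dtype=float)
    x0, x1 = max(0, tlx), min(w, tlx + size)
    y0, y1 = max(0, tly), min(h, tly + size)
    if x1 > x0 and y1 > y0:
        patch[y0 - tly : y1 - tly, x0 - tlx : x1 - tlx] = frame[y0:y1, x0:x1]
    box = Box(x=tlx + (size - 1) / 2.0, y=tly + (size - 1) / 2.0, w=float(size), h=float(size))
    return patch, box


def _crop_box_region(frame: np.ndarray, box: Box, out_size: int) -> tuple[np.ndarray, Box]:
    """Crop the integer window covering ``box`` and resize to out_size x out_size.

    Returns the resized crop (float in [0, 1]) and the exact box the crop
    covers in frame coordinates (used for coordinate mapping).
    """
    h, w = frame.shape
    tlx = int(round(box.x0))
    tly = int(round(box.y0))
    bw = max(4, int(round(box.w)))
    bh = max(4, int(round(box.h)))
    patch = np.zeros((bh, bw), dtype=float)
    x0, x1 = max(0, tlx), min(w, tlx + bw)
    y0, y1 = max(0, tly), min(h, tly + bh)
    if x1 > x0 and y1 > y0:
        patch[y0 - tly : y1 - tly, x0 - tlx : x1 - tlx] = frame[y0:y1, x0:x1]
    crop_box = Box(x=tlx + (bw - 1) / 2.0, y=tly + (bh - 1) / 2.0, w=float(bw), h=float(bh))
    resized = resize(patch / 255.0, (out_size, out_size), order=1,
                     anti_aliasing=False, preserve_range=True)
    return resized, crop_box


# --------------------------------------------------------------------------- #
# Attention network
# --------------------------------------------------------------------------- #
class AttentionNet(Module):
    """Patch -> search-region box delta; final layer zero-initialized so the
    untrained network returns the anchor box."""

    def __init__(self, rng: np.random.Generator, channels: tuple[int, int, int] = (8, 16, 16),
                 hidden: int = 32):
        c1, c2, c3 = channels
        self.conv1 = Conv(1, c1, 3, rng, stride=2, pad=1)
        self.conv2 = Conv(c1, c2, 3, rng, stride=2, pad=1)
        self.conv3 = Conv(c2, c3, 3, rng, stride=2, pad=1)
        self.fc1 = Linear(c3, hidden, rng)
        self.fc2 = Linear(hidden, 4, rng, zero=True)

    def forward(self, patch: np.ndarray) -> Tensor:
        if patch.shape != (ATTENTION_PATCH_SIZE, ATTENTION_PATCH_SIZE):
            raise ValueError(
                f"attention patch must be {ATTENTION_PATCH_SIZE}x{ATTENTION_PATCH_SIZE}, "
                f"got {patch.shape}"
            )
        x = np.asarray(patch, dtype=float) / 255.0
        # 2x mean-pool down to 50x50 before the convolutions
        x = x.reshape(50, 2, 50, 2).mean(axis=(1, 3))
        t = Tensor(x[None, :, :])
        t = conv2d(t, self.conv1.W, self.conv1.b, stride=2, pad=1).relu()
        t = conv2d(t, self.conv2.W, self.conv2.b, stride=2, pad=1).relu()
        t = conv2d(t, self.conv3.W, self.conv3.b, stride=2, pad=1).relu()
        feat = t.reshape(t.shape[0], -1).mean(axis=1)
        return self.fc2(self.fc1(feat).relu())


def attention_forward(
    patch: np.ndarray,
    net: AttentionNet,
    anchor: Box | None = None,
    frame_shape: tuple[int, int] | None = None,
) -> Box:
    """Predict the reduced search-region box for a 100 x 100 patch.

    The network's four outputs are a box delta decoded against ``anchor``
    (the patch's own box; defaults to the patch in its local coordinates).
    When ``frame_shape`` is given the box is shifted to intersect the frame.
    """
    if anchor is None:
        s = ATTENTION_PATCH_SIZE
        anchor = Box(x=(s - 1) / 2.0, y=(s - 1) / 2.0, w=float(s), h=float(s))
    delta = net.forward(patch).data
    # keep the decoded box a sane sub-window of the patch
    delta = np.clip(delta, [-0.5, -0.5, -2.5, -2.5], [0.5, 0.5, 0.5, 0.5])
    box = decode_delta(BoxDelta(*delta), Anchor(anchor))
    if frame_shape is not None:
        h, w = frame_shape
        box = Box(box.x, box.y, min(box.w, w), min(box.h, h)).clamped_to(w, h)
    return box


# --------------------------------------------------------------------------- #
# Detector
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class DetectorConfig:
    """Sizes of the scaled detection core.

    Window sizes / stride follow the sliding-window anchor rule (IoU with
    the search box > 0.7), so windows are close to the search-box size.
    """

    input_size: int = 32
    backbone_channels: tuple[int, int, int] = (8, 16, 16)
    fpn_channels: int = 16
    window_sizes: tuple[tuple[float, float], ...] = ((28.0, 28.0), (32.0, 32.0), (36.0, 36.0))
    anchor_stride_px: float = 4.0
    roi_grid: int = 4
    trunk_size: int = 64
    cls_hidden: int = 32
    mask_grid: int = 10
    mask_features: int = 4
    box_size_px: float = 20.0
    mask_disk_radius_px: float = 5.0
    top_k: int = 3
    lstm_hidden: int = 16
    n_temporal: int = 5

    def __post_init__(self) -> None:
        if self.n_temporal < 1:
            raise ValueError("n_temporal must be >= 1")


@dataclass
class ProposalRecord:
    """One scored proposal: box in frame coordinates plus pooled features."""

    box: Box
    objectness: float
    feature_vector: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.objectness <= 1.0:
            raise ValueError("objectness must lie in [0, 1]")


@dataclass
class DetectorOutput:
    """Full per-proposal detector outputs for one search region."""

    records: list[ProposalRecord]
    cls_scores: list[float]          # P(landmark) in [0, 1]
    box_deltas: list[tuple[float, float]]  # center deltas vs proposal box
    masks: list[np.ndarray]          # (mask_grid, mask_grid) in (0, 1)
    refined_centers: list[tuple[float, float]]


class Detector(Module):
    """Backbone + 2-level FPN + anchor scoring (RPN) + three heads."""

    def __init__(self, config: DetectorConfig, rng: np.random.Generator):
        self.config = config
        c1, c2, c3 = config.backbone_channels
        f = config.fpn_channels
        self.conv1 = Conv(1, c1, 3, rng, pad=1)
        self.conv2 = Conv(c1, c2, 3, rng, pad=1)
        self.conv3 = Conv(c2, c3, 3, rng, pad=1)
        self.lat2 = Conv(c2, f, 1, rng)
        self.lat3 = Conv(c3, f, 1, rng)
        roi_dim = f * config.roi_grid**2
        self.rpn_fc = Linear(roi_dim, config.trunk_size, rng)
        self.rpn_obj = Linear(config.trunk_size, 1, rng)
        self.rpn_delta = Linear(config.trunk_size, 4, rng, zero=True)
        self.trunk = Linear(roi_dim, config.trunk_size, rng)
        self.cls_fc1 = Linear(config.trunk_size, config.cls_hidden, rng)
        self.cls_fc2 = Linear(config.cls_hidden, 2, rng)
        self.box_fc = Linear(config.trunk_size, 2, rng, zero=True)
        self.mask_fc = Linear(config.trunk_size, config.mask_grid**2 * config.mask_features, rng)
        self.mask_W = Tensor(rng.normal(0.0, 0.5, size=(config.mask_features, 2)),
                             requires_grad=True)

    # -- feature extraction ---------------------------------------------------
    def feature_maps(self, crop01: np.ndarray) -> tuple[Tensor, Tensor]:
        """Resized crop in [0,1] -> (P2 at stride 4, P3 at stride 8)."""
        t = Tensor(np.asarray(crop01, dtype=float)[None, :, :])
        c1 = _avg_pool2(conv2d(t, self.conv1.W, self.conv1.b, pad=1).relu())      # /2
        c2 = _avg_pool2(conv2d(c1, self.conv2.W, self.conv2.b, pad=1).relu())     # /4
        c3 = _avg_pool2(conv2d(c2, self.conv3.W, self.conv3.b, pad=1).relu())     # /8
        p3 = conv2d(c3, self.lat3.W, self.lat3.b)
        p2 = conv2d(c2, self.lat2.W, self.lat2.b) + _upsample2(p3)
        return p2, p3

    def _roi_features(self, fmap: Tensor, box: Box, crop_box: Box, stride: int) -> Tensor:
        """Bilinear-sample a roi_grid^2 point grid over ``box`` from ``fmap``."""
        g = self.config.roi_grid
        c, fh, fw = fmap.shape
        scale_x = self.config.input_size / crop_box.w
        scale_y = self.config.input_size / crop_box.h
        xs = box.x0 + (np.arange(g) + 0.5) / g * box.w
        ys = box.y0 + (np.arange(g) + 0.5) / g * box.h
        # frame coords -> crop pixel coords -> feature coords (pixel centers)
        fx = ((xs - (crop_box.x0 + 0.5)) * scale_x) / stride - 0.5
        fy = ((ys - (crop_box.y0 + 0.5)) * scale_y) / stride - 0.5
        fx = np.clip(fx, 0, fw - 1 - 1e-6)
        fy = np.clip(fy, 0, fh - 1 - 1e-6)
        mat = np.zeros((g * g, fh * fw))
        for j, yv in enumerate(fy):
            y0 = int(yv)
            wy = yv - y0
            for i, xv in enumerate(fx):
                x0 = int(xv)
                wx = xv - x0
                p = j * g + i
                mat[p, y0 * fw + x0] += (1 - wy) * (1 - wx)
                mat[p, y0 * fw + min(x0 + 1, fw - 1)] += (1 - wy) * wx
                mat[p, min(y0 + 1, fh - 1) * fw + x0] += wy * (1 - wx)
                mat[p, min(y0 + 1, fh - 1) * fw + min(x0 + 1, fw - 1)] += wy * wx
        sampled = fmap.reshape(c, fh * fw) @ Tensor(mat.T)  # (c, g*g)
        return sampled.flatten()

    def roi_features(self, fmaps: tuple[Tensor, Tensor], box: Box, crop_box: Box) -> Tensor:
        """Pool from the pyramid level matched to the box size."""
        p2, p3 = fmaps
        if box.w * box.h <= self.config.input_size**2 * 0.9:
            return self._roi_features(p2, box, crop_box, stride=4)
        return self._roi_features(p3, box, crop_box, stride=8)

    # -- heads ----------------------------------------------------------------
    def rpn(self, roi: Tensor) -> tuple[Tensor, Tensor]:
        hid = self.rpn_fc(roi).relu()
        return self.rpn_obj(hid), self.rpn_delta(hid)

    def head_trunk(self, roi: Tensor) -> Tensor:
        return self.trunk(roi).relu()

    def cls_head(self, feat: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (hidden activation, 2 class scores)."""
        a1 = self.cls_fc1(feat).relu()
        return a1, self.cls_fc2(a1)

    def cls_layer_grads(self, feat: Tensor, a1: Tensor) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Closed-form gradients of the two class scores w.r.t. supervised layers.

        Returns {layer: (grad_class0, grad_class1)} for the trunk feature and
        the hidden classification activation.  Used as (stop-gradient)
        denominators of the large-margin hinge.
        """
        w2 = self.cls_fc2.W.data  # (2, hidden)
        z1 = self.cls_fc1.W.data @ feat.data + self.cls_fc1.b.data
        relu_mask = (z1 > 0).astype(float)
        g_feat = [self.cls_fc1.W.data.T @ (w2[j] * relu_mask) for j in (0, 1)]
        return {
            "cls_fc1": (w2[0], w2[1]),
            "trunk": (g_feat[0], g_feat[1]),
        }

    def mask_head(self, feat: Tensor) -> Tensor:
        """Per-pixel feature vectors over the mask grid: (grid^2, F)."""
        g, f = self.config.mask_grid, self.config.mask_features
        return self.mask_fc(feat).relu().reshape(g * g, f)

    def mask_probs(self, pixel_feats: Tensor) -> np.ndarray:
        """Inference-time mask: two-way softmax over W-projected pixel features."""
        logits = pixel_feats.data @ self.mask_W.data  # (P, 2)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e[:, 1] / e.sum(axis=1)
        g = self.config.mask_grid
        return p.reshape(g, g)


def detector_forward(
    frame: np.ndarray,
    detector: Detector,
    search_box: Box,
    frame_index: int = 0,
    top_k: int | None = None,
    anchors: list[Anchor] | None = None,
) -> DetectorOutput:
    """Run the detection core inside ``search_box`` on one frame.

    Anchors come from the sliding-window rule against the search box; the
    RPN scores and regresses them; the ``top_k`` proposals (by objectness,
    ties broken by anchor order) are pooled and passed through the three
    heads.  All outputs are deterministic functions of (frame, weights).
    """
    cfg = detector.config
    top_k = top_k or cfg.top_k
    crop01, crop_box = _crop_box_region(frame, search_box, cfg.input_size)
    fmaps = detector.feature_maps(crop01)
    if anchors is None:
        anchors = generate_anchors(search_box, cfg.window_sizes, cfg.anchor_stride_px)
    scored = []
    for idx, a in enumerate(anchors):
        roi = detector.roi_features(fmaps, a.box, crop_box)
        obj_logit, delta = detector.rpn(roi)
        scored.append((float(obj_logit.data[0]), idx, a, delta.data))
    scored.sort(key=lambda t: (-t[0], t[1]))
    records: list[ProposalRecord] = []
    cls_scores, box_deltas, masks, refined = [], [], [], []
    for obj_logit, idx, a, delta in scored[:top_k]:
        d = np.clip(delta, -0.4, 0.4)
        prop = decode_delta(BoxDelta(*d), a)
        roi = detector.roi_features(fmaps, prop, crop_box)
        feat = detector.head_trunk(roi)
        _, scores = detector.cls_head(feat)
        e = np.exp(scores.data - scores.data.max())
        p_landmark = float(e[1] / e.sum())
        bd = detector.box_fc(feat).data
        pixel_feats = detector.mask_head(feat)
        mask = detector.mask_probs(pixel_feats)
        cx = prop.x + float(bd[0]) * prop.w
        cy = prop.y + float(bd[1]) * prop.h
        records.append(
            ProposalRecord(box=prop, objectness=float(_sigmoid(np.array(obj_logit))),
                           feature_vector=feat.data.copy(), frame_index=frame_index)
        )
        cls_scores.append(p_landmark)
        box_deltas.append((float(bd[0]), float(bd[1])))
        masks.append(mask)
        refined.append((cx, cy))
    if not records:
        raise ValueError("no anchor survives the IoU rule in this search box")
    return DetectorOutput(records=records, cls_scores=cls_scores, box_deltas=box_deltas,
                          masks=masks, refined_centers=refined)


# --------------------------------------------------------------------------- #
# Temporal (LSTM) heads
# --------------------------------------------------------------------------- #
class TemporalHead(Module):
    """LSTM over per-frame proposal features + FC heads for score and center.

    The input at each step is the proposal's pooled feature vector
    concatenated with the (scaled) center motion relative to the previous
    record in the window.  The mask head never passes through here.
    """

    MOTION_SCALE = 5.0  # px; normalizes per-frame center motion

    def __init__(self, config: DetectorConfig, rng: np.random.Generator):
        self.config = config
        n_in = config.trunk_size + 2
        nh = config.lstm_hidden
        s = 1.0 / math.sqrt(nh)
        def mk(r, c):
            return Tensor(rng.uniform(-s, s, size=(r, c)), requires_grad=True)
        def vk(r):
            return Tensor(np.zeros(r), requires_grad=True)
        self.W_ii, self.W_hi = mk(nh, n_in), mk(nh, nh)
        self.W_if, self.W_hf = mk(nh, n_in), mk(nh, nh)
        self.W_ig, self.W_hg = mk(nh, n_in), mk(nh, nh)
        self.W_io, self.W_ho = mk(nh, n_in), mk(nh, nh)
        self.b_ii, self.b_hi = vk(nh), vk(nh)
        self.b_if, self.b_hf = vk(nh), vk(nh)
        self.b_ig, self.b_hg = vk(nh), vk(nh)
        self.b_io, self.b_ho = vk(nh), vk(nh)
        self.fc_score = Linear(nh, 1, rng)
        self.fc_delta = Linear(nh, 2, rng, zero=True)

    def lstm_params(self) -> LSTMParams:
        """Numpy view of the cell weights (shared with :func:`lstm_step`)."""
        return LSTMParams(
            self.W_ii.data, self.W_hi.data, self.W_if.data, self.W_hf.data,
            self.W_ig.data, self.W_hg.data, self.W_io.data, self.W_ho.data,
            self.b_ii.data, self.b_hi.data, self.b_if.data, self.b_hf.data,
            self.b_ig.data, self.b_hg.data, self.b_io.data, self.b_ho.data,
        )

    def _step_t(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        i = (self.W_ii @ x + self.b_ii + self.W_hi @ h + self.b_hi).sigmoid()
        f = (self.W_if @ x + self.b_if + self.W_hf @ h + self.b_hf).sigmoid()
        g = (self.W_ig @ x + self.b_ig + self.W_hg @ h + self.b_hg).tanh()
        o = (self.W_io @ x + self.b_io + self.W_ho @ h + self.b_ho).sigmoid()
        c_t = f * c + i * g
        return o * c_t.tanh(), c_t

    def inputs_from_records(self, records: list[ProposalRecord]) -> list[np.ndarray]:
        xs = []
        prev = records[0].box
        for r in records:
            motion = np.array([(r.box.x - prev.x), (r.box.y - prev.y)]) / self.MOTION_SCALE
            xs.append(np.concatenate([r.feature_vector, motion]))
            prev = r.box
        return xs

    def forward_window(self, records: list[ProposalRecord]
                       ) -> tuple[Tensor, Tensor, LSTMState]:
        """Run the window through the cell; returns (score logit, delta, state)."""
        if not records:
            raise ValueError("temporal head needs at least one proposal record")
        nh = self.config.lstm_hidden
        h, c = Tensor(np.zeros(nh)), Tensor(np.zeros(nh))
        for x in self.inputs_from_records(records):
            h, c = self._step_t(Tensor(x), h, c)
        return self.fc_score(h), self.fc_delta(h), LSTMState(h=h.data.copy(), c=c.data.copy())


def temporal_head(
    records: list[ProposalRecord],
    head: TemporalHead,
) -> tuple[float, tuple[float, float], LSTMState]:
    """Refine the last record's score and center from its temporal window.

    Returns ``(class score in [0,1], refined center (x, y), final LSTM
    state)``.  Windows shorter than ``n_temporal`` (sequence start) are used
    as-is; the mask output is untouched by design.
    """
    if not records:
        raise ValueError("temporal head needs at least one proposal record")
    window = records[-head.config.n_temporal :]
    logit, delta, state = head.forward_window(window)
    score = float(np.ravel(_sigmoid(logit.data))[0])
    box = window[-1].box
    d = np.clip(delta.data, -0.5, 0.5)
    center = (box.x + float(d[0]) * box.w, box.y + float(d[1]) * box.h)
    return score, center, state


# --------------------------------------------------------------------------- #
# Weights container and (de)serialization
# --------------------------------------------------------------------------- #
@dataclass
class ModelWeights:
    attention: AttentionNet
    detector: Detector
    temporal: TemporalHead
    config: "TrainConfig"


FORMAT_VERSION = 1


def save_weights(weights: ModelWeights, path) -> None:
    """Single-file .npz archive with a version tag and the config embedded."""
    arrays = {}
    for name, module in (("attention", weights.attention), ("detector", weights.detector),
                         ("temporal", weights.temporal)):
        for k, v in module.state_dict(prefix=name + ".").items():
            arrays[k] = v
    arrays["__version__"] = np.array(FORMAT_VERSION)
    arrays["__config__"] = np.frombuffer(
        json.dumps(weights.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_weights(path) -> ModelWeights:
    with np.load(path) as data:
        version = int(data["__version__"])
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported weights version {version}")
        cfg = TrainConfig.from_dict(json.loads(bytes(data["__config__"].tobytes()).decode()))
        rng = np.random.default_rng(0)
        attention = AttentionNet(rng)
        detector = Detector(cfg.detector, rng)
        temporal = TemporalHead(cfg.detector, rng)
        sd = {k: data[k] for k in data.files if not k.startswith("__")}
        attention.load_state_dict(sd, prefix="attention.")
        detector.load_state_dict(sd, prefix="detector.")
        temporal.load_state_dict(sd, prefix="temporal.")
    return ModelWeights(attention=attention, detector=detector, temporal=temporal, config=cfg)


# --------------------------------------------------------------------------- #
# Training
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for the three training stages.

    The ``paper`` profile keeps the documented defaults (learning rate 1e-6,
    up to 1000 epochs); the ``scaled`` profile is the desk-scale setting used
    by the synthetic experiments (tiny backbone, lr 1e-3, far fewer epochs).
    Training stops early when the epoch-to-epoch decrease of the epoch-mean
    loss falls below ``stop_tol``.
    """

    profile: str = "scaled"
    lr: float = 1e-3
    epochs_attention: int = 40
    epochs_detector: int = 30
    epochs_temporal: int = 30
    stop_tol: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    attention_box_px: float = 32.0
    n_overlap_proposals: int = 2  # proposals with greatest anchor overlap fed to the LSTM
    max_temporal_windows: int = 6  # per landmark, bounds the precompute cost
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    margin_params: MarginClsParams = field(default_factory=MarginClsParams)
    lm_params: LMSoftmaxParams = field(default_factory=LMSoftmaxParams)
    joint_finetune: bool = False

    @staticmethod
    def paper_profile(seed: int = 0) -> "TrainConfig":
        return TrainConfig(profile="paper", lr=1e-6, epochs_attention=1000,
                           epochs_detector=1000, epochs_temporal=1000, seed=seed)

    @staticmethod
    def scaled_profile(seed: int = 0) -> "TrainConfig":
        return TrainConfig(profile="scaled", seed=seed)

    def to_dict(self) -> dict:
        return {
            "profile": self.profile, "lr": self.lr,
            "epochs_attention": self.epochs_attention,
            "epochs_detector": self.epochs_detector,
            "epochs_temporal": self.epochs_temporal,
            "stop_tol": self.stop_tol, "batch_size": self.batch_size,
            "seed": self.seed, "attention_box_px": self.attention_box_px,
            "n_overlap_proposals": self.n_overlap_proposals,
            "max_temporal_windows": self.max_temporal_windows,
            "detector": vars(self.detector).copy()
            if not isinstance(self.detector, DetectorConfig)
            else {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in self.detector.__dict__.items()},
            "loss_weights": [self.loss_weights.w1, self.loss_weights.w2, self.loss_weights.w3],
            "margin": {"gamma": self.margin_params.gamma_margin,
                       "epsilon": self.margin_params.epsilon,
                       "layers": list(self.margin_params.layers)},
            "lm": {"m": self.lm_params.m, "lambda": self.lm_params.lambda_reg},
            "joint_finetune": self.joint_finetune,
        }

    @staticmethod
    def from_dict(d: dict) -> "TrainConfig":
        det = d["detector"]
        det_cfg = DetectorConfig(
            input_size=det["input_size"],
            backbone_channels=tuple(det["backbone_channels"]),
            fpn_channels=det["fpn_channels"],
            window_sizes=tuple(tuple(w) for w in det["window_sizes"]),
            anchor_stride_px=det["anchor_stride_px"],
            roi_grid=det["roi_grid"], trunk_size=det["trunk_size"],
            cls_hidden=det["cls_hidden"], mask_grid=det["mask_grid"],
            mask_features=det["mask_features"], box_size_px=det["box_size_px"],
            mask_disk_radius_px=det["mask_disk_radius_px"], top_k=det["top_k"],
            lstm_hidden=det["lstm_hidden"], n_temporal=det["n_temporal"],
        )
        return TrainConfig(
            profile=d["profile"], lr=d["lr"],
            epochs_attention=d["epochs_attention"], epochs_detector=d["epochs_detector"],
            epochs_temporal=d["epochs_temporal"], stop_tol=d["stop_tol"],
            batch_size=d["batch_size"], seed=d["seed"],
            attention_box_px=d["attention_box_px"],
            n_overlap_proposals=d["n_overlap_proposals"],
            max_temporal_windows=d.get("max_temporal_windows", 6), detector=det_cfg,
            loss_weights=LossWeights(*d["loss_weights"]),
            margin_params=MarginClsParams(d["margin"]["gamma"], d["margin"]["epsilon"],
                                          tuple(d["margin"]["layers"])),
            lm_params=LMSoftmaxParams(d["lm"]["m"], d["lm"]["lambda"]),
            joint_finetune=d.get("joint_finetune", False),
        )


def _interpolated_positions(track: LandmarkTrack, n_frames: int) -> np.ndarray:
    """Linear interpolation of a sparse track to every frame (pseudo-dense)."""
    ks = track.frame_indices()
    xs = np.array([track.points[k][0] for k in ks])
    ys = np.array([track.points[k][1] for k in ks])
    t = np.arange(n_frames)
    return np.column_stack([np.interp(t, ks, xs), np.interp(t, ks, ys)])


def _attention_pairs(sequences, cfg: TrainConfig, rng: np.random.Generator):
    """(current frame, patch center=previous position, target center) triples."""
    pairs = []
    for seq, tracks in sequences:
        for tr in tracks:
            ks = tr.frame_indices()
            for k_prev, k_cur in zip(ks[:-1], ks[1:]):
                pairs.append((seq, k_cur, tr.points[k_prev], tr.points[k_cur]))
            # same-frame pairs teach the identity mapping
            for k in ks:
                pairs.append((seq, k, tr.points[k], tr.points[k]))
    return pairs


def _train_attention(net: AttentionNet, sequences, cfg: TrainConfig,
                     rng: np.random.Generator, log: dict) -> None:
    pairs = _attention_pairs(sequences, cfg, rng)
    if not pairs:
        raise ValueError("no annotated frames available for attention training")
    opt = Adam(net.parameters(), lr=cfg.lr)
    history = []
    prev_epoch_loss = None
    for epoch in range(cfg.epochs_attention):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            total = None
            for bi in batch:
                seq, k, p_prev, p_cur = pairs[bi]
                jitter = rng.uniform(-3, 3, size=2)
                center = (p_prev[0] + jitter[0], p_prev[1] + jitter[1])
                patch, anchor = crop_patch(seq.frames[k], center, ATTENTION_PATCH_SIZE)
                target = Box(p_cur[0], p_cur[1], cfg.attention_box_px, cfg.attention_box_px)
                t_delta = encode_delta(target, Anchor(anchor)).as_array()
                pred = net.forward(patch)
                term = ((pred - Tensor(t_delta)) ** 2).sum()
                total = term if total is None else total + term
            total = total * (1.0 / len(batch))
            total.backward()
            opt.step()
            losses.append(total.item())
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if prev_epoch_loss is not None and 0 <= prev_epoch_loss - epoch_loss < cfg.stop_tol:
            break
        prev_epoch_loss = epoch_loss
    log["attention_loss"] = history


def _sample_negative_center(shape, positions, rng, min_dist=14.0, margin=6.0):
    h, w = shape
    for _ in range(100):
        cand = np.array([rng.uniform(margin, w - 1 - margin), rng.uniform(margin, h - 1 - margin)])
        if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_dist for p in positions):
            return cand
    return cand


def _mask_targets(prop: Box, gt_xy, cfg: DetectorConfig) -> np.ndarray:
    """Binary disk labels on the mask grid over the proposal box."""
    g = cfg.mask_grid
    xs = prop.x0 + (np.arange(g) + 0.5) / g * prop.w
    ys = prop.y0 + (np.arange(g) + 0.5) / g * prop.h
    xx, yy = np.meshgrid(xs, ys)
    d2 = (xx - gt_xy[0]) ** 2 + (yy - gt_xy[1]) ** 2
    return (d2 <= cfg.mask_disk_radius_px**2).astype(int).ravel()


def _bce_logit(z: Tensor, target: float) -> Tensor:
    return z.relu() - z * target + ((-(z.abs())).exp() + 1.0).log()


def _margin_hinge_t(scores: Tensor, true_label: int, denoms: dict[str, float],
                    params: MarginClsParams) -> Tensor:
    """Differentiable deep-supervised hinge; denominators are constants."""
    f_t = scores[true_label]
    f_o = scores[1 - true_label]
    total = None
    for layer, denom in denoms.items():
        term = ((f_o - f_t) * (1.0 / denom) + params.gamma_margin).relu()
        total = term if total is None else total + term
    return total


def _lm_softmax_t(pixel_feats: Tensor, labels: np.ndarray, W: Tensor,
                  params: LMSoftmaxParams) -> Tensor:
    """Differentiable large-margin softmax over all mask pixels at once."""
    p = pixel_feats.shape[0]
    onehot = np.zeros((p, 2))
    onehot[np.arange(p), labels] = 1.0
    dots = pixel_feats @ W  # (P, 2)
    xnorm = ((pixel_feats * pixel_feats).sum(axis=1) + 1e-12).sqrt()  # (P,)
    wnorm = ((W * W).sum(axis=0) + 1e-12).sqrt()  # (2,)
    cos = dots / (xnorm.reshape(p, 1) * wnorm.reshape(1, 2))
    cos_y = (cos * onehot).sum(axis=1).clamp(-1.0 + 1e-7, 1.0 - 1e-7)
    theta = cos_y.arccos()
    k = np.minimum((theta.data * params.m / math.pi).astype(int), params.m - 1)
    sign = (-1.0) ** k
    phi_t = (theta * float(params.m)).cos() * sign - 2.0 * k
    wnorm_y = (wnorm.reshape(1, 2) * onehot).sum(axis=1)
    s_true = wnorm_y * xnorm * phi_t
    s_other = (dots * (1.0 - onehot)).sum(axis=1)
    d = s_other - s_true
    return _softplus(d).sum() + params.lambda_reg * (W * W).sum()


def _detector_samples(sequences, cfg: TrainConfig, rng: np.random.Generator):
    """(frame, search_box, gt_xy or None) training crops; ~1 negative per positive."""
    samples = []
    s = cfg.attention_box_px
    for seq, tracks in sequences:
        frame_positions: dict[int, list] = {}
        for tr in tracks:
            for k, p in tr.points.items():
                frame_positions.setdefault(k, []).append(p)
        for tr in tracks:
            for k, p in tr.points.items():
                jit = rng.uniform(-4, 4, size=2)
                samples.append(
                    (seq.frames[k], Box(p[0] + jit[0], p[1] + jit[1], s, s), p, k)
                )
                neg = _sample_negative_center(seq.frames[k].shape, frame_positions[k], rng)
                samples.append((seq.frames[k], Box(neg[0], neg[1], s, s), None, k))
    return samples


def _train_detector(det: Detector, sequences, cfg: TrainConfig,
                    rng: np.random.Generator, log: dict) -> None:
    samples = _detector_samples(sequences, cfg, rng)
    if not samples:
        raise ValueError("no annotated frames available for detector training")
    opt = Adam(det.parameters(), lr=cfg.lr)
    dcfg = det.config
    history = []
    prev_epoch_loss = None
    for epoch in range(cfg.epochs_detector):
        order = rng.permutation(len(samples))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            total = None
            for bi in batch:
                frame, sbox, gt_xy, _k = samples[bi]
                crop01, crop_box = _crop_box_region(frame, sbox, dcfg.input_size)
                fmaps = det.feature_maps(crop01)
                anchors = generate_anchors(sbox, dcfg.window_sizes, dcfg.anchor_stride_px)
                # subsample anchors for speed, deterministic per draw
                sel = rng.choice(len(anchors), size=min(4, len(anchors)), replace=False)
                sample_loss = None
                for ai in sel:
                    a = anchors[ai]
                    roi = det.roi_features(fmaps, a.box, crop_box)
                    obj_logit, delta = det.rpn(roi)
                    term = _bce_logit(obj_logit[0], 1.0 if gt_xy is not None else 0.0)
                    if gt_xy is not None:
                        gt_box = Box(gt_xy[0], gt_xy[1], dcfg.box_size_px, dcfg.box_size_px)
                        t = encode_delta(gt_box, a).as_array()
                        term = term + _smooth_l1_t(delta - Tensor(t)).sum()
                        prop = decode_delta(BoxDelta(*np.clip(delta.data, -0.4, 0.4)), a)
                    else:
                        prop = a.box
                    # heads on the (detached-box) proposal
                    roi_p = det.roi_features(fmaps, prop, crop_box)
                    feat = det.head_trunk(roi_p)
                    a1, scores = det.cls_head(feat)
                    grads = det.cls_layer_grads(feat, a1)
                    label = 1 if gt_xy is not None else 0
                    denoms = {}
                    for layer in cfg.margin_params.layers:
                        g0, g1 = grads[layer]
                        go, gt_ = (g0, g1) if label == 1 else (g1, g0)
                        denoms[layer] = cfg.margin_params.epsilon + float(
                            np.linalg.norm(go - gt_))
                    l_cls = _margin_hinge_t(scores, label, denoms, cfg.margin_params)
                    if gt_xy is not None:
                        bd = det.box_fc(feat)
                        t_center = Tensor(np.array([(gt_xy[0] - prop.x) / prop.w,
                                                    (gt_xy[1] - prop.y) / prop.h]))
                        l_box = _smooth_l1_t(bd - t_center).sum()
                        pixel_feats = det.mask_head(feat)
                        labels = _mask_targets(prop, gt_xy, dcfg)
                        l_mask = _lm_softmax_t(pixel_feats, labels, det.mask_W,
                                               cfg.lm_params) * (1.0 / labels.size)
                    else:
                        l_box = Tensor(0.0)
                        pixel_feats = det.mask_head(feat)
                        labels = np.zeros(dcfg.mask_grid**2, dtype=int)
                        l_mask = _lm_softmax_t(pixel_feats, labels, det.mask_W,
                                               cfg.lm_params) * (1.0 / labels.size)
                    lw = cfg.loss_weights
                    head_loss = lw.w1 * l_cls + lw.w2 * l_mask + lw.w3 * l_box
                    term = term + head_loss
                    sample_loss = term if sample_loss is None else sample_loss + term
                sample_loss = sample_loss * (1.0 / len(sel))
                total = sample_loss if total is None else total + sample_loss
            total = total * (1.0 / len(batch))
            total.backward()
            opt.step()
            losses.append(total.item())
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if prev_epoch_loss is not None and 0 <= prev_epoch_loss - epoch_loss < cfg.stop_tol:
            break
        prev_epoch_loss = epoch_loss
    log["detector_loss"] = history


def _temporal_windows(det: Detector, sequences, cfg: TrainConfig,
                      rng: np.random.Generator):
    """Precompute proposal-record windows for LSTM training.

    For each landmark and each annotated frame with at least n_temporal - 1
    predecessors, run the frozen detector on the window's frames with search
    boxes centered on (interpolated) landmark positions, keep the
    ``n_overlap_proposals`` best-overlap proposals per frame, and emit one
    positive window (target = annotated position at the window end) plus one
    background window (target score 0).
    """
    dcfg = det.config
    windows = []
    s = cfg.attention_box_px
    for seq, tracks in sequences:
        for tr in tracks:
            interp = _interpolated_positions(tr, seq.n_frames)
            ks = [k for k in tr.frame_indices() if k >= dcfg.n_temporal - 1]
            for k_end in ks[: cfg.max_temporal_windows]:
                frames_idx = range(k_end - dcfg.n_temporal + 1, k_end + 1)
                pos_records = []
                ok = True
                for k in frames_idx:
                    center = interp[k] + rng.uniform(-2, 2, size=2)
                    sbox = Box(center[0], center[1], s, s)
                    try:
                        out = detector_forward(seq.frames[k], det, sbox, frame_index=k)
                    except ValueError:
                        ok = False
                        break
                    gt_box = Box(interp[k][0], interp[k][1], dcfg.box_size_px, dcfg.box_size_px)
                    ranked = sorted(
                        range(len(out.records)),
                        key=lambda i: -iou(out.records[i].box, gt_box),
                    )[: cfg.n_overlap_proposals]
                    pos_records.append(out.records[ranked[0]])
                if ok:
                    windows.append((pos_records, 1.0, tr.points[k_end]))
                # background window: static off-landmark region
                neg_center = _sample_negative_center(
                    seq.frames[0].shape, [interp[k] for k in frames_idx], rng)
                neg_records = []
                ok = True
                for k in frames_idx:
                    sbox = Box(neg_center[0], neg_center[1], s, s)
                    try:
                        out = detector_forward(seq.frames[k], det, sbox, frame_index=k)
                    except ValueError:
                        ok = False
                        break
                    neg_records.append(out.records[0])
                if ok:
                    windows.append((neg_records, 0.0, None))
    return windows


def _train_temporal(head: TemporalHead, det: Detector, sequences, cfg: TrainConfig,
                    rng: np.random.Generator, log: dict) -> None:
    windows = _temporal_windows(det, sequences, cfg, rng)
    if not windows:
        raise ValueError("no temporal training windows could be built")
    opt = Adam(head.parameters(), lr=cfg.lr)
    history = []
    prev_epoch_loss = None
    for epoch in range(cfg.epochs_temporal):
        order = rng.permutation(len(windows))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            total = None
            for bi in batch:
                records, target_score, target_xy = windows[bi]
                logit, delta, _state = head.forward_window(records)
                term = _bce_logit(logit[0], target_score)
                if target_xy is not None:
                    box = records[-1].box
                    t = Tensor(np.array([(target_xy[0] - box.x) / box.w,
                                         (target_xy[1] - box.y) / box.h]))
                    term = term + _smooth_l1_t(delta - t).sum() * 4.0
                total = term if total is None else total + term
            total = total * (1.0 / len(batch))
            total.backward()
            opt.step()
            losses.append(total.item())
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if prev_epoch_loss is not None and 0 <= prev_epoch_loss - epoch_loss < cfg.stop_tol:
            break
        prev_epoch_loss = epoch_loss
    log["temporal_loss"] = history


def train_model(
    train_sequences: list[tuple[USSequence, list[LandmarkTrack]]],
    config: TrainConfig | None = None,
) -> tuple[ModelWeights, dict]:
    """Train the cascade on annotated sequences.

    The attention network trains first (its own objective), then the
    detector (weighted cls/mask/box objective plus the proposal stage's
    objectness/regression terms), then the LSTM heads on frozen-detector
    proposal windows.  Returns the weights and a log of per-epoch losses.
    """
    config = config or TrainConfig.scaled_profile()
    if not train_sequences:
        raise ValueError("train_model needs at least one annotated sequence")
    for seq, tracks in train_sequences:
        if not tracks or all(not t.points for t in tracks):
            raise ValueError(f"sequence {seq.meta.sequence_id} has no annotated frames")
    rng = np.random.default_rng(config.seed)
    attention = AttentionNet(rng)
    detector = Detector(config.detector, rng)
    temporal = TemporalHead(config.detector, rng)
    log: dict = {"profile": config.profile, "lr": config.lr, "seed": config.seed}
    _train_attention(attention, train_sequences, config, rng, log)
    _train_detector(detector, train_sequences, config, rng, log)
    _train_temporal(temporal, detector, train_sequences, config, rng, log)
    return ModelWeights(attention=attention, detector=detector, temporal=temporal,
                        config=config), log
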