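"""Axis-aligned box algebra for anchor-based landmark detection.

Boxes are parameterized by their center ``(x, y)`` and size ``(w, h)`` in
pixel coordinates (x = column, y = row, 0-based, sub-pixel allowed).  The
module owns the delta encoding used by every regression head

    t_x = (x - x_a) / w_a,   t_y = (y - y_a) / h_a,
    t_w = log(w / w_a),      t_h = log(h / h_a),

the continuous intersection-over-union, sliding-window anchor generation
under the "IoU with the search box > 0.7" retention rule, and the robust
(smooth-L1) scalar loss used for box regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Box",
    "Anchor",
    "BoxDelta",
    "encode_delta",
    "decode_delta",
    "iou",
    "generate_anchors",
    "smooth_l1",
    "DEFAULT_WINDOW_SIZES",
    "DEFAULT_STRIDE_PX",
]

#: Default sliding-window sizes (w, h) in pixels for anchor generation.
DEFAULT_WINDOW_SIZES: tuple[tuple[float, float], ...] = ((16.0, 16.0), (20.0, 20.0), (24.0, 24.0))

#: Default sliding-window stride in pixels.
DEFAULT_STRIDE_PX: float = 4.0


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle: center ``(x, y)``, width ``w``, height ``h`` (px)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box width/height must be positive, got w={self.w}, h={self.h}")

    @property
    def x0(self) -> float:
        return self.x - self.w / 2.0

    @property
    def x1(self) -> float:
        return self.x + self.w / 2.0

    @property
    def y0(self) -> float:
        return self.y - self.h / 2.0

    @property
    def y1(self) -> float:
        return self.y + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def contains(self, x: float, y: float) -> bool:
        """True if the point lies inside the (closed) rectangle."""
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    @staticmethod
    def from_corners(x0: float, y0: float, x1: float, y1: float) -> "Box":
        return Box((x0 + x1) / 2.0, (y0 + y1) / 2.0, x1 - x0, y1 - y0)

    def clamped_to(self, width: int, height: int) -> "Box":
        """Shift the box (size preserved) so it lies inside a ``width x height`` frame.

        If the box is larger than the frame along an axis it is centered on
        that axis instead.
        """
        x, y = self.x, self.y
        if self.w >= width:
            x = width / 2.0
        else:
            x = min(max(x, self.w / 2.0), width - self.w / 2.0)
        if self.h >= height:
            y = height / 2.0
        else:
            y = min(max(y, self.h / 2.0), height - self.h / 2.0)
        return Box(x, y, self.w, self.h)


@dataclass(frozen=True)
class Anchor:
    """Reference box centered on a sliding-window position."""

    box: Box


@dataclass(frozen=True)
class BoxDelta:
    """Regression targets/outputs ``(t_x, t_y, t_w, t_h)`` relative to an anchor."""

    t_x: float
    t_y: float
    t_w: float
    t_h: float

    def __post_init__(self) -> None:
        for name in ("t_x", "t_y", "t_w", "t_h"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"delta component {name} is not finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.t_x, self.t_y, self.t_w, self.t_h], dtype=float)


def encode_delta(box: Box, anchor: Anchor) -> BoxDelta:
    """Encode ``box`` relative to ``anchor`` (center offsets in anchor units, log sizes)."""
    a = anchor.box
    return BoxDelta(
        t_x=(box.x - a.x) / a.w,
        t_y=(box.y - a.y) / a.h,
        t_w=math.log(box.w / a.w),
        t_h=math.log(box.h / a.h),
    )


def decode_delta(delta: BoxDelta, anchor: Anchor) -> Box:
    """Exact inverse of :func:`encode_delta`."""
    a = anchor.box
    return Box(
        x=delta.t_x * a.w + a.x,
        y=delta.t_y * a.h + a.y,
        w=a.w * math.exp(delta.t_w),
        h=a.h * math.exp(delta.t_h),
    )


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two continuous axis-aligned rectangles, in [0, 1]."""
    iw = min(a.x1, b.x1) - max(a.x0, b.x0)
    ih = min(a.y1, b.y1) - max(a.y0, b.y0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    # corner re-derivation can overshoot the true area by a few ulp
    return min(1.0, inter / (a.area + b.area - inter))


def generate_anchors(
    search_box: Box,
    window_sizes: list[tuple[float, float]] | tuple[tuple[float, float], ...] = DEFAULT_WINDOW_SIZES,
    stride_px: float = DEFAULT_STRIDE_PX,
    min_iou: float = 0.7,
) -> list[Anchor]:
    """Sliding-window anchors inside ``search_box`` retained under the IoU rule.

    Window centers lie on a ``stride_px`` grid anchored at the search-box
    center, and only windows whose IoU with the search box exceeds
    ``min_iou`` are kept.  Ordering is deterministic: row-major over the grid
    (y, then x), then window size, ties broken by (y, x, area).

    Raises
    ------
    ValueError
        If no window passes the IoU rule (windows too small relative to the
        search box).
    """
    if stride_px <= 0:
        raise ValueError("stride_px must be positive")
    kept: list[tuple[tuple[float, float, float], Anchor]] = []
    # grid of candidate centers covering the search box, symmetric about its center
    nx = max(0, int(math.floor((search_box.w / 2.0) / stride_px)))
    ny = max(0, int(math.floor((search_box.h / 2.0) / stride_px)))
    ys = [search_box.y + j * stride_px for j in range(-ny, ny + 1)]
    xs = [search_box.x + i * stride_px for i in range(-nx, nx + 1)]
    for y in ys:
        for x in xs:
            for (w, h) in window_sizes:
                if w <= 0 or h <= 0:
                    raise ValueError("window sizes must be positive")
                cand = Box(x, y, float(w), float(h))
                if iou(cand, search_box) > min_iou:
                    kept.append(((y, x, cand.area), Anchor(cand)))
    if not kept:
        raise ValueError(
            "no anchor passes the IoU > %.2f rule against the search box; "
            "use larger window sizes (closer to the search-box size)" % min_iou
        )
    kept.sort(key=lambda t: t[0])
    return [a for _, a in kept]


def smooth_l1(u) -> float:
    """Robust scalar loss: ``0.5 u**2`` if ``|u| < 1`` else ``|u| - 0.5``.

    Accepts scalars or numpy arrays (applied elementwise).
    """
    u = np.asarray(u, dtype=float)
    out = np.where(np.abs(u) < 1.0, 0.5 * u * u, np.abs(u) - 0.5)
    return float(out) if out.ndim == 0 else out
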