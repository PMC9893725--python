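"""Synthetic B-mode-like sequences with known landmark trajectories.

The generator emulates the salient features of free-breathing liver
ultrasound at desk scale: multiplicative speckle (smoothed Rayleigh field),
one to five hypoechoic landmark structures, confounder structures rendered
from the *same* template as landmarks (so appearance alone cannot separate
them), optional vertical acoustic-shadow bands, quasi-periodic sinusoidal
motion with slow drift and occasional abrupt jumps (cough/sneeze-like), and
sparse annotations on 10%-13% of frames.

Everything is a pure function of the configuration, including its seed, so
a config fully reproduces a dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import LandmarkTrack, SequenceMeta, USSequence, write_sequence

__all__ = [
    "MotionModel",
    "SyntheticConfig",
    "motion_trajectory",
    "render_frame",
    "simulate_sequence",
    "save_dataset",
]


@dataclass(frozen=True)
class MotionModel:
    """Sinusoid + drift + instantaneous jumps, per landmark.

    position(t) = start + amplitude*sin(2 pi t / period + phase) + drift*t
                  + sum of jumps with event_time <= t
    """

    amplitude_px: tuple[float, float] = (0.0, 0.0)
    period_s: float = 4.0
    phase: float = 0.0
    drift_px_per_s: tuple[float, float] = (0.0, 0.0)
    abrupt_events: tuple[tuple[float, tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if min(self.amplitude_px) < 0:
            raise ValueError("amplitude components must be nonnegative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated sequence.

    Ranges mirror the acquisition protocol being emulated: frame rate in
    [6, 30] Hz, pixel spacing in [0.27, 0.77] mm, 1-5 landmarks, annotations
    on 10%-13% of frames.  Motion draw ranges are what free breathing looks
    like at this scale: breathing periods of a few seconds, amplitudes of a
    few pixels, slow drift, and (with probability ``abrupt_prob``) one abrupt
    jump per landmark.
    """

    height: int = 64
    width: int = 64
    n_frames: int = 80
    frame_rate_hz: float = 15.0
    mm_per_pixel: float = 0.5
    n_landmarks: int = 2
    landmark_radius_px: float = 4.5
    landmark_contrast: float = 0.85
    n_confounders: int = 2
    shadow: tuple[float, float, float] | None = None  # (center_x, width_px, attenuation)
    speckle_scale: float = 1.0
    annotation_fraction: float = 0.12
    seed: int = 0
    # motion draw ranges (free-breathing emulation)
    amplitude_range_px: tuple[float, float] = (2.0, 6.0)
    period_range_s: tuple[float, float] = (2.5, 5.0)
    drift_range_px_per_s: tuple[float, float] = (-0.3, 0.3)
    abrupt_prob: float = 0.3
    abrupt_jump_px: tuple[float, float] = (3.0, 6.0)

    def __post_init__(self) -> None:
        if not 6.0 <= self.frame_rate_hz <= 30.0:
            raise ValueError("frame_rate_hz must lie in [6, 30]")
        if not 0.27 <= self.mm_per_pixel <= 0.77:
            raise ValueError("mm_per_pixel must lie in [0.27, 0.77]")
        if not 1 <= self.n_landmarks <= 5:
            raise ValueError("n_landmarks must lie in [1, 5]")
        if not 0.10 <= self.annotation_fraction <= 0.13:
            raise ValueError("annotation_fraction must lie in [0.10, 0.13]")
        # 0 renders invisible landmarks; allowed as a diagnostic degenerate case
        if not 0.0 <= self.landmark_contrast <= 1.0:
            raise ValueError("landmark_contrast must lie in [0, 1]")
        if self.landmark_radius_px <= 0 or self.speckle_scale <= 0:
            raise ValueError("landmark_radius_px and speckle_scale must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.shadow is not None and not 0.0 < self.shadow[2] < 1.0:
            raise ValueError("shadow attenuation must lie in (0, 1)")


def motion_trajectory(
    model: MotionModel,
    n_frames: int,
    frame_rate_hz: float,
    start_xy: tuple[float, float],
    bounds: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-frame (x, y) positions; raises if the path leaves ``bounds`` (w, h)."""
    t = np.arange(n_frames) / frame_rate_hz
    ax, ay = model.amplitude_px
    dx, dy = model.drift_px_per_s
    x = start_xy[0] + ax * np.sin(2 * math.pi * t / model.period_s + model.phase) + dx * t
    y = start_xy[1] + ay * np.sin(2 * math.pi * t / model.period_s + model.phase) + dy * t
    for event_t, (jx, jy) in model.abrupt_events:
        mask = t >= event_t
        x = x + jx * mask
        y = y + jy * mask
    traj = np.column_stack([x, y])
    if bounds is not None:
        w, h = bounds
        if (traj[:, 0].min() < 0 or traj[:, 0].max() > w - 1
                or traj[:, 1].min() < 0 or traj[:, 1].max() > h - 1):
            raise ValueError(
                "trajectory exits frame bounds; shrink amplitude/drift or move the start"
            )
    return traj


def _structure_attenuation(shape: tuple[int, int], positions: np.ndarray,
                           radius: float, contrast: float) -> np.ndarray:
    """Multiplicative field: radially smooth hypoechoic (darker) Gaussian disks."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    att = np.ones(shape, dtype=float)
    sigma = radius / 2.0
    for (cx, cy) in positions:
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        att *= 1.0 - contrast * np.exp(-r2 / (2.0 * sigma**2))
    return att


def render_frame(
    config: SyntheticConfig,
    landmark_positions: np.ndarray,
    confounder_positions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one frame: speckle x landmark/confounder disks x shadow -> uint8.

    Confounders use the same disk template as landmarks, so only context
    (position and motion) can disambiguate them.  Deterministic given the rng
    state.
    """
    shape = (config.height, config.width)
    speckle = rng.rayleigh(scale=config.speckle_scale, size=shape)
    tissue = gaussian_filter(speckle, sigma=1.0)
    img = tissue / np.mean(tissue) * 110.0
    positions = [np.asarray(landmark_positions, dtype=float).reshape(-1, 2),
                 np.asarray(confounder_positions, dtype=float).reshape(-1, 2)]
    all_pos = np.concatenate([p for p in positions if p.size], axis=0) if any(
        p.size for p in positions) else np.empty((0, 2))
    if all_pos.size:
        img = img * _structure_attenuation(
            shape, all_pos, config.landmark_radius_px, config.landmark_contrast
        )
    if config.shadow is not None:
        cx, width_px, attenuation = config.shadow
        cols = np.abs(np.arange(config.width) - cx) <= width_px / 2.0
        img[:, cols] *= attenuation
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _draw_motion(cfg: SyntheticConfig, rng: np.random.Generator) -> MotionModel:
    amp = rng.uniform(*cfg.amplitude_range_px, size=2)
    amp[1] *= 0.6  # respiration moves the liver mostly along one axis
    period = rng.uniform(*cfg.period_range_s)
    phase = rng.uniform(0.0, 2 * math.pi)
    drift = rng.uniform(*cfg.drift_range_px_per_s, size=2)
    events: tuple = ()
    if rng.uniform() < cfg.abrupt_prob:
        t_event = rng.uniform(0.2, 0.8) * cfg.n_frames / cfg.frame_rate_hz
        jump = rng.uniform(*cfg.abrupt_jump_px) * rng.choice([-1.0, 1.0], size=2)
        events = ((float(t_event), (float(jump[0]), float(jump[1]))),)
    return MotionModel(
        amplitude_px=(float(amp[0]), float(amp[1])),
        period_s=float(period),
        phase=float(phase),
        drift_px_per_s=(float(drift[0]), float(drift[1])),
        abrupt_events=events,
    )


_MAX_PLACEMENT_TRIES = 200


def simulate_sequence(
    config: SyntheticConfig,
) -> tuple[USSequence, list[LandmarkTrack], list[LandmarkTrack]]:
    """Simulate one sequence.

    Returns ``(sequence, dense_truth, sparse_annotations)``.  Landmark motion
    models are drawn independently per landmark; confounders are static and
    placed at least ``3 * landmark_radius_px`` from every point of every
    landmark trajectory; sparse annotations keep
    ``max(1, floor(annotation_fraction * n_frames))`` frames, always
    including frame 0.
    """
    rng = np.random.default_rng(config.seed)
    margin = config.landmark_radius_px + 2.0
    # landmark trajectories
    trajectories: list[np.ndarray] = []
    for _ in range(config.n_landmarks):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            model = _draw_motion(config, rng)
            start = (
                rng.uniform(margin, config.width - 1 - margin),
                rng.uniform(margin, config.height - 1 - margin),
            )
            try:
                traj = motion_trajectory(
                    model, config.n_frames, config.frame_rate_hz, start,
                    bounds=(config.width, config.height),
                )
            except ValueError:
                continue
            if traj[:, 0].min() >= margin / 2 and traj[:, 0].max() <= config.width - 1 - margin / 2:
                trajectories.append(traj)
                break
        else:
            raise ValueError("could not place a landmark trajectory inside the frame")
    # static confounders, kept away from every landmark trajectory
    confounders: list[tuple[float, float]] = []
    min_dist = 3.0 * config.landmark_radius_px
    for _ in range(config.n_confounders):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            cand = (
                rng.uniform(margin, config.width - 1 - margin),
                rng.uniform(margin, config.height - 1 - margin),
            )
            ok = all(
                np.min(np.hypot(traj[:, 0] - cand[0], traj[:, 1] - cand[1])) >= min_dist
                for traj in trajectories
            ) and all(math.hypot(c[0] - cand[0], c[1] - cand[1]) >= min_dist
                      for c in confounders)
            if ok:
                confounders.append(cand)
                break
        else:
            raise ValueError("could not place a confounder away from landmark paths")
    conf_arr = np.asarray(confounders, dtype=float).reshape(-1, 2)
    frames = [
        render_frame(config, np.stack([t[k] for t in trajectories]), conf_arr, rng)
        for k in range(config.n_frames)
    ]
    meta = SequenceMeta(
        sequence_id=f"SYN-{config.seed:04d}",
        mm_per_pixel=config.mm_per_pixel,
        frame_rate_hz=config.frame_rate_hz,
        source_tag="SYN",
    )
    seq = USSequence(meta=meta, frames=frames)
    truth = [
        LandmarkTrack(
            landmark_id=f"L{i + 1}",
            points={k: (float(traj[k, 0]), float(traj[k, 1])) for k in range(config.n_frames)},
        )
        for i, traj in enumerate(trajectories)
    ]
    n_annot = max(1, int(math.floor(config.annotation_fraction * config.n_frames)))
    annotations = []
    for track in truth:
        others = rng.choice(np.arange(1, config.n_frames), size=n_annot - 1, replace=False) \
            if n_annot > 1 else np.array([], dtype=int)
        keep = sorted({0, *map(int, others)})
        annotations.append(
            LandmarkTrack(landmark_id=track.landmark_id,
                          points={k: track.points[k] for k in keep})
        )
    return seq, truth, annotations


def save_dataset(
    seq: USSequence,
    truth: list[LandmarkTrack],
    annotations: list[LandmarkTrack],
    path: str | Path,
) -> Path:
    """Write the sequence layout plus ``annotations/`` (sparse) and ``truth/`` (dense)."""
    path = Path(path)
    write_sequence(seq, path)
    for sub, tracks in (("annotations", annotations), ("truth", truth)):
        d = path / sub
        d.mkdir(parents=True, exist_ok=True)
        for t in tracks:
            lines = [f"{k} {t.points[k][0]:.4f} {t.points[k][1]:.4f}"
                     for k in t.frame_indices()]
            (d / f"{t.landmark_id}.txt").write_text("\n".join(lines) + "\n")
    return path
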