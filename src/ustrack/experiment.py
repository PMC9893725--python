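"""Desk-scale end-to-end experiment: simulate, train, track, evaluate.

This is the recipe behind the ``e2e-demo`` CLI subcommand.  It generates
synthetic training and held-out test sequences (64 x 64 frames,
high-contrast hypoechoic landmarks), trains the cascade with the ``scaled``
profile, then measures on the held-out sequences:

* attention containment — the fraction of frames on which the predicted
  search-region box contains the true landmark, given a patch centered on
  the previous frame's true position;
* tracking error — full cascade tracking from the frame-0 annotation,
  evaluated against the dense ground truth in px and mm.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .boxes import Box
from .evaluation import aggregate, errors_for_track
from .io import LandmarkTrack
from .nets import (
    ATTENTION_PATCH_SIZE,
    ModelWeights,
    TrainConfig,
    attention_forward,
    crop_patch,
    train_model,
)
from .synth import SyntheticConfig, simulate_sequence
from .tracker import SelectionParams, track_sequence

__all__ = ["make_datasets", "attention_containment", "run_e2e_demo"]


def make_datasets(
    seed: int,
    n_train: int = 3,
    n_test: int = 2,
    n_frames: int = 60,
    **overrides,
) -> tuple[list, list]:
    """Simulate train and held-out test sets of high-contrast sequences.

    Returns ``(train, test)`` where each element is the
    ``(sequence, dense_truth, sparse_annotations)`` triple from the
    simulator.  Per-sequence seeds are derived from ``seed``.
    """
    base = SyntheticConfig(seed=0, **overrides)
    train = [replace(base, seed=seed * 1000 + i) for i in range(n_train)]
    test = [replace(base, seed=seed * 1000 + 500 + i) for i in range(n_test)]
    train_sets = [simulate_sequence(replace(c, n_frames=n_frames)) for c in train]
    test_sets = [simulate_sequence(replace(c, n_frames=n_frames)) for c in test]
    return train_sets, test_sets


def attention_containment(
    weights: ModelWeights, test_sets: list, search_size: float | None = None
) -> float:
    """Fraction of held-out frames whose attention box contains the truth.

    For each frame t >= 1 the input patch is centered on the true position
    at t - 1 (the tracking prior under good conditions); the predicted box
    (at the configured search-region size) must contain the true position
    at t.
    """
    s = search_size or weights.config.attention_box_px
    n_hit = 0
    n_tot = 0
    for seq, truth, _ann in test_sets:
        h, w = seq.shape
        for tr in truth:
            for k in range(1, seq.n_frames):
                prev = tr.points[k - 1]
                cur = tr.points[k]
                patch, anchor = crop_patch(seq.frames[k], prev, ATTENTION_PATCH_SIZE)
                abox = attention_forward(patch, weights.attention, anchor=anchor,
                                         frame_shape=(h, w))
                box = Box(abox.x, abox.y, s, s).clamped_to(w, h)
                n_hit += box.contains(cur[0], cur[1])
                n_tot += 1
    return n_hit / n_tot


def _first_frame_annotations(truth: list[LandmarkTrack]) -> list[LandmarkTrack]:
    return [LandmarkTrack(landmark_id=t.landmark_id, points={0: t.points[0]})
            for t in truth]


def run_e2e_demo(
    seed: int,
    config: TrainConfig | None = None,
    n_train: int = 3,
    n_test: int = 2,
    n_frames: int = 60,
    selection: SelectionParams = SelectionParams(),
    **synth_overrides,
) -> dict:
    """Run the full scaled experiment; returns a reproducible report dict."""
    config = config or TrainConfig.scaled_profile(seed=seed)
    train_sets, test_sets = make_datasets(seed, n_train=n_train, n_test=n_test,
                                          n_frames=n_frames, **synth_overrides)
    train_input = [(seq, ann) for seq, _truth, ann in train_sets]
    weights, log = train_model(train_input, config)

    containment = attention_containment(weights, test_sets)

    records = []
    per_sequence = {}
    for seq, truth, _ann in test_sets:
        results = track_sequence(seq, _first_frame_annotations(truth), weights, selection)
        seq_records = []
        for tr, res in zip(truth, results):
            recs = errors_for_track(tr, res.to_track(), seq.meta,
                                    patient_id=seq.meta.sequence_id)
            seq_records.extend(recs)
        records.extend(seq_records)
        errs_mm = np.array([r.error_mm for r in seq_records])
        per_sequence[seq.meta.sequence_id] = {
            "mean_mm": float(errs_mm.mean()),
            "n_frames": int(errs_mm.size),
        }
    errs_mm = np.array([r.error_mm for r in records])
    mm_per_px = test_sets[0][0].meta.mm_per_pixel
    table = aggregate(records, grouping="source")
    report = {
        "seed": seed,
        "profile": config.profile,
        "n_train_sequences": n_train,
        "n_test_sequences": n_test,
        "n_frames": n_frames,
        "attention_containment": float(containment),
        "mean_error_mm": float(errs_mm.mean()),
        "std_error_mm": float(errs_mm.std(ddof=1)) if errs_mm.size > 1 else 0.0,
        "p95_error_mm": float(np.percentile(errs_mm, 95)),
        "max_error_mm": float(errs_mm.max()),
        "mean_error_px": float(errs_mm.mean() / mm_per_px),
        "p95_error_px": float(np.percentile(errs_mm, 95) / mm_per_px),
        "n_error_frames": int(errs_mm.size),
        "per_sequence": per_sequence,
        "source_table": table,
        "training_log": {k: v for k, v in log.items()},
    }
    return report
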