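"""Tracking-error computation and aggregation.

The error for a frame is the Euclidean distance between predicted and
ground-truth landmark positions, converted to millimetres with the
sequence's pixel spacing.  Errors are computed only on frames that carry
ground truth; summaries report mean, sample standard deviation, the 95th
percentile (linear interpolation) and the maximum.  Group-level aggregation
pools frame-level records (it is not a mean of means); "AVE.MaxError" is the
mean of the per-landmark maxima within the group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import LandmarkTrack, SequenceMeta

__all__ = [
    "ErrorRecord",
    "LandmarkSummary",
    "tracking_error",
    "errors_for_track",
    "summarize_landmark",
    "aggregate",
    "crossval_split",
    "confidence_interval",
]


@dataclass(frozen=True)
class ErrorRecord:
    """One frame-level tracking error, with grouping keys."""

    landmark_id: str
    frame_index: int
    error_mm: float
    patient_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.error_mm < 0:
            raise ValueError("error_mm must be nonnegative")


@dataclass(frozen=True)
class LandmarkSummary:
    mean_mm: float
    std_mm: float
    p95_mm: float
    max_mm: float
    n: int


def tracking_error(
    truth_xy: tuple[float, float],
    pred_xy: tuple[float, float],
    meta: SequenceMeta,
    squared: bool = False,
) -> float:
    """Euclidean distance (mm) between truth and prediction on one frame.

    ``squared=True`` returns the squared distance instead; the plain
    distance is the default used everywhere in this package.
    """
    dx = truth_xy[0] - pred_xy[0]
    dy = truth_xy[1] - pred_xy[1]
    d_px = float(np.hypot(dx, dy))
    d_mm = d_px * meta.mm_per_pixel
    return d_mm**2 if squared else d_mm


def errors_for_track(
    truth: LandmarkTrack,
    pred: LandmarkTrack,
    meta: SequenceMeta,
    patient_id: str = "",
    source: str = "",
) -> list[ErrorRecord]:
    """Per-frame errors on the frames where ``truth`` has ground truth."""
    records = []
    for k in truth.frame_indices():
        if k not in pred.points:
            raise ValueError(f"prediction for landmark {truth.landmark_id} misses frame {k}")
        records.append(
            ErrorRecord(
                landmark_id=truth.landmark_id,
                frame_index=k,
                error_mm=tracking_error(truth.points[k], pred.points[k], meta),
                patient_id=patient_id,
                source=source or meta.source_tag,
            )
        )
    return records


def _stats(errors: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(np.mean(errors))
    std = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    p95 = float(np.percentile(errors, 95))  # linear interpolation
    return mean, std, p95, float(np.max(errors))


def summarize_landmark(records: list[ErrorRecord]) -> LandmarkSummary:
    """Mean / sample std / 95th percentile / max over one landmark's records."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    errors = np.array([r.error_mm for r in records])
    mean, std, p95, mx = _stats(errors)
    return LandmarkSummary(mean_mm=mean, std_mm=std, p95_mm=p95, max_mm=mx, n=errors.size)


_GROUP_KEYS = {
    "landmark": lambda r: r.landmark_id,
    "patient": lambda r: r.patient_id,
    "source": lambda r: r.source,
}


def aggregate(records: list[ErrorRecord], grouping: str = "landmark") -> dict[str, dict]:
    """Pooled per-group statistics over frame-level records.

    Returns ``{group: {mean_mm, std_mm, p95_mm, ave_max_mm, n_landmarks,
    n_frames}}`` where ``ave_max_mm`` is the mean of per-landmark maximum
    errors within the group.
    """
    if grouping not in _GROUP_KEYS:
        raise KeyError(f"unknown grouping {grouping!r}; use landmark|patient|source")
    if not records:
        raise ValueError("no records to aggregate")
    key = _GROUP_KEYS[grouping]
    table: dict[str, dict] = {}
    groups = sorted({key(r) for r in records})
    for g in groups:
        sub = [r for r in records if key(r) == g]
        errors = np.array([r.error_mm for r in sub])
        mean, std, p95, _ = _stats(errors)
        per_landmark_max = [
            max(r.error_mm for r in sub if r.landmark_id == lid)
            for lid in sorted({r.landmark_id for r in sub})
        ]
        table[g] = {
            "mean_mm": mean,
            "std_mm": std,
            "p95_mm": p95,
            "ave_max_mm": float(np.mean(per_landmark_max)),
            "n_landmarks": len(per_landmark_max),
            "n_frames": int(errors.size),
        }
    return table


def crossval_split(
    sequence_ids: list[str], n_folds: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Seeded shuffle into ``n_folds`` near-equal folds; returns (train, test) pairs.

    24 ids with 5 folds yield test folds of sizes 5, 5, 5, 5, 4.
    """
    ids = list(sequence_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} sequences, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    folds = [sorted(ids[i] for i in chunk) for chunk in np.array_split(order, n_folds)]
    splits = []
    for k in range(n_folds):
        test = folds[k]
        train = sorted(x for j, f in enumerate(folds) if j != k for x in f)
        splits.append((train, test))
    return splits


def confidence_interval(
    records: list[ErrorRecord] | np.ndarray, level: float = 0.99
) -> tuple[float, float]:
    """Student-t confidence interval for the mean frame error."""
    if len(records) and isinstance(records[0], ErrorRecord):
        errors = np.array([r.error_mm for r in records], dtype=float)
    else:
        errors = np.asarray(records, dtype=float)
    if errors.size < 2:
        raise ValueError("confidence interval needs at least 2 records")
    mean = float(np.mean(errors))
    sem = float(stats.sem(errors))
    if sem == 0.0:
        return (mean, mean)
    lo, hi = stats.t.interval(level, df=errors.size - 1, loc=mean, scale=sem)
    return float(lo), float(hi)
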