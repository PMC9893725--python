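"""Per-landmark tracking: the inference cascade and candidate selection.

Each landmark is tracked independently.  Per frame the cascade runs:
attention network (100 x 100 patch at the previous position -> reduced
search region), detector (proposals + scores inside that region), LSTM
temporal head (re-scores and re-centers each proposal from the last <= 5
frames of context), and finally a similarity-based selection that combines
the detector score with proximity to the previous position:

    x_t = argmax_k  gamma * S_k + (1 - gamma) / (1 + exp(||x_k - x_{t-1}||))

with gamma = 0.5 by default.  The proximity term is what disambiguates
confounder structures that look exactly like the landmark.  The expression
is sometimes written with an argmin; because S_k and the proximity term
both increase for better candidates, the combined score is maximized here
(a ``printed_argmin`` flag preserves the literal minimizing behavior for
audit).  Distances are in pixels by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .boxes import Box
from .io import LandmarkTrack, USSequence
from .nets import (
    ATTENTION_PATCH_SIZE,
    LSTMState,
    ModelWeights,
    ProposalRecord,
    attention_forward,
    crop_patch,
    detector_forward,
    temporal_head,
)

__all__ = [
    "Candidate",
    "SelectionParams",
    "TrackState",
    "TrackResult",
    "init_track",
    "select_localization",
    "combined_score",
    "track_frame",
    "track_sequence",
]


@dataclass(frozen=True)
class Candidate:
    """A candidate localization: position (px) and bounded detector score."""

    position: tuple[float, float]
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"candidate score must lie in [0, 1], got {self.score}")


@dataclass(frozen=True)
class SelectionParams:
    """Trade-off gamma between detector score and proximity; px distances."""

    gamma_sel: float = 0.5
    printed_argmin: bool = False
    distance_in_mm: bool = False
    mm_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_sel <= 1.0:
            raise ValueError("gamma_sel must lie in [0, 1]")


@dataclass
class TrackState:
    """Per-landmark temporal memory carried across frames."""

    prev_position: tuple[float, float]
    search_box: Box
    lstm_state: LSTMState | None = None
    recent_records: list[ProposalRecord] = field(default_factory=list)
    frame_shape: tuple[int, int] = (0, 0)


@dataclass
class TrackResult:
    """Dense tracking output for one landmark."""

    landmark_id: str
    positions: list[tuple[float, float]]
    scores: list[float]
    flags: list[str | None]

    def to_track(self) -> LandmarkTrack:
        return LandmarkTrack(
            landmark_id=self.landmark_id,
            points={k: p for k, p in enumerate(self.positions)},
        )


def init_track(first_frame: np.ndarray, landmark_xy: tuple[float, float]) -> TrackState:
    """Start a track: 100 x 100 search box centered on the given landmark."""
    h, w = first_frame.shape
    x, y = landmark_xy
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise ValueError(f"landmark ({x}, {y}) outside {h}x{w} frame")
    s = float(ATTENTION_PATCH_SIZE)
    box = Box(x, y, s, s).clamped_to(w, h)
    return TrackState(prev_position=(float(x), float(y)), search_box=box,
                      frame_shape=(h, w))


def combined_score(candidate: Candidate, prev_position: tuple[float, float],
                   params: SelectionParams = SelectionParams()) -> float:
    """gamma * S_k + (1 - gamma) / (1 + exp(distance to previous position))."""
    d = math.hypot(candidate.position[0] - prev_position[0],
                   candidate.position[1] - prev_position[1])
    if params.distance_in_mm:
        d *= params.mm_per_pixel
    # guard the exponential for far candidates
    proximity = 1.0 / (1.0 + math.exp(min(d, 700.0)))
    return params.gamma_sel * candidate.score + (1.0 - params.gamma_sel) * proximity


def select_localization(
    candidates: list[Candidate],
    state: TrackState,
    params: SelectionParams = SelectionParams(),
) -> Candidate:
    """Pick the candidate optimizing the combined score.

    Maximizes by default; ties are broken by higher raw score, then smaller
    distance to the previous position, then input order.
    """
    if not candidates:
        raise ValueError("select_localization needs at least one candidate")
    sign = 1.0 if params.printed_argmin else -1.0

    def key(ic):
        i, c = ic
        d = math.hypot(c.position[0] - state.prev_position[0],
                       c.position[1] - state.prev_position[1])
        return (sign * combined_score(c, state.prev_position, params), -c.score, d, i)

    return min(enumerate(candidates), key=key)[1]


def track_frame(
    frame: np.ndarray,
    state: TrackState,
    weights: ModelWeights,
    selection: SelectionParams = SelectionParams(),
    frame_index: int = 0,
    candidate_fn=None,
) -> tuple[tuple[float, float], TrackState, str | None, float]:
    """Track one landmark through one frame.

    Returns ``(position, new_state, flag, chosen_score)``.  ``candidate_fn``
    (frame_index, frame, state) -> list[Candidate] replaces the
    attention/detector/temporal stages when given (used for controlled
    selection experiments); the fallback path keeps the previous position
    and leaves the temporal memory untouched.
    """
    h, w = frame.shape
    if candidate_fn is not None:
        candidates = candidate_fn(frame_index, frame, state)
        if not candidates:
            return state.prev_position, state, "empty-candidates", 0.0
        chosen = select_localization(candidates, state, selection)
        new_state = replace(
            state,
            prev_position=chosen.position,
            search_box=Box(chosen.position[0], chosen.position[1],
                           state.search_box.w, state.search_box.h).clamped_to(w, h),
        )
        return chosen.position, new_state, None, chosen.score

    cfg = weights.config
    patch, patch_box = crop_patch(frame, state.prev_position, ATTENTION_PATCH_SIZE)
    attn_box = attention_forward(patch, weights.attention, anchor=patch_box,
                                 frame_shape=(h, w))
    # the detector's search region keeps the configured size; the attention
    # network contributes its position
    s = cfg.attention_box_px
    search = Box(attn_box.x, attn_box.y, s, s).clamped_to(w, h)
    try:
        out = detector_forward(frame, weights.detector, search, frame_index=frame_index)
    except ValueError:
        return state.prev_position, state, "no-proposals", 0.0
    candidates: list[Candidate] = []
    cand_aux: list[tuple[ProposalRecord, LSTMState]] = []
    for rec in out.records:
        window = state.recent_records + [rec]
        score, center, lstm_state = temporal_head(window, weights.temporal)
        cx = min(max(center[0], 0.0), w - 1.0)
        cy = min(max(center[1], 0.0), h - 1.0)
        candidates.append(Candidate(position=(cx, cy), score=score))
        cand_aux.append((rec, lstm_state))
    chosen = select_localization(candidates, state, selection)
    idx = candidates.index(chosen)
    rec, lstm_state = cand_aux[idx]
    records = (state.recent_records + [rec])[-cfg.detector.n_temporal :]
    new_state = TrackState(
        prev_position=chosen.position,
        search_box=Box(chosen.position[0], chosen.position[1],
                       float(ATTENTION_PATCH_SIZE), float(ATTENTION_PATCH_SIZE)
                       ).clamped_to(w, h),
        lstm_state=lstm_state,
        recent_records=records,
        frame_shape=(h, w),
    )
    return chosen.position, new_state, None, chosen.score


def track_sequence(
    sequence: USSequence,
    first_frame_annotations: list[LandmarkTrack],
    weights: ModelWeights,
    selection: SelectionParams = SelectionParams(),
    candidate_fn=None,
    n_frames: int | None = None,
) -> list[TrackResult]:
    """Track every landmark through the sequence (landmarks independent).

    Frame 0 is the given annotation verbatim; frames 1..n-1 come from
    :func:`track_frame`.  ``n_frames`` truncates tracking to a prefix.
    """
    n = sequence.n_frames if n_frames is None else min(n_frames, sequence.n_frames)
    results = []
    for track in first_frame_annotations:
        if 0 not in track.points:
            raise ValueError(f"landmark {track.landmark_id} has no frame-0 annotation")
        p0 = track.points[0]
        state = init_track(sequence.frames[0], p0)
        positions = [(float(p0[0]), float(p0[1]))]
        scores = [1.0]
        flags: list[str | None] = [None]
        for k in range(1, n):
            pos, state, flag, sc = track_frame(
                sequence.frames[k], state, weights, selection,
                frame_index=k, candidate_fn=candidate_fn,
            )
            positions.append(pos)
            scores.append(sc)
            flags.append(flag)
        results.append(TrackResult(landmark_id=track.landmark_id, positions=positions,
                                   scores=scores, flags=flags))
    return results
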