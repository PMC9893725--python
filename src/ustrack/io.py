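"""Reading and writing ultrasound sequences and landmark annotations.

On-disk layout (one directory per sequence, mirroring the liver-ultrasound
challenge conventions):

    <sequence_dir>/
        meta.yaml            # mm_per_pixel, frame_rate_hz, source_tag
        frames/00000.png ... # 8-bit grayscale, numeric sortable names
        annotations/<landmark_id>.txt   # rows: frame_index x y

Coordinates are 0-based ``(x, y) = (column, row)`` with pixel centers at
integer coordinates; sub-pixel positions are allowed.  This convention is
owned here and consumed unchanged by every other module.  Annotation files
may be sparse (any subset of frames); prediction files are dense (one row
per frame per landmark).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

__all__ = [
    "SequenceMeta",
    "USSequence",
    "LandmarkTrack",
    "read_sequence",
    "write_sequence",
    "read_annotations",
    "write_predictions",
    "px_to_mm",
]

_META_FILENAME = "meta.yaml"
_REQUIRED_META = ("mm_per_pixel", "frame_rate_hz")


@dataclass(frozen=True)
class SequenceMeta:
    """Per-sequence acquisition metadata (isotropic pixel spacing)."""

    sequence_id: str
    mm_per_pixel: float
    frame_rate_hz: float
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")


@dataclass
class USSequence:
    """An ordered stack of same-size 8-bit grayscale frames plus metadata."""

    meta: SequenceMeta
    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError(f"a sequence needs >= 2 frames, got {len(self.frames)}")
        shape0 = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not a 2D grayscale image")
            if f.shape != shape0:
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected {shape0} like frame 0"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames[0].shape


@dataclass
class LandmarkTrack:
    """Sparse or dense mapping frame_index -> (x, y) for one landmark."""

    landmark_id: str
    points: dict[int, tuple[float, float]] = field(default_factory=dict)

    def frame_indices(self) -> list[int]:
        return sorted(self.points)

    def is_dense(self, n_frames: int) -> bool:
        return all(k in self.points for k in range(n_frames))


def read_sequence(path: str | Path, meta_overrides: dict | None = None) -> USSequence:
    """Load a sequence directory; frames ordered by their numeric file names."""
    path = Path(path)
    meta_path = path / _META_FILENAME
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    raw = yaml.safe_load(meta_path.read_text()) or {}
    if meta_overrides:
        raw.update(meta_overrides)
    for key in _REQUIRED_META:
        if key not in raw:
            raise KeyError(f"metadata file {meta_path} is missing required field '{key}'")
    meta = SequenceMeta(
        sequence_id=str(raw.get("sequence_id", path.name)),
        mm_per_pixel=float(raw["mm_per_pixel"]),
        frame_rate_hz=float(raw["frame_rate_hz"]),
        source_tag=str(raw.get("source_tag", "")),
    )
    frame_dir = path / "frames"
    files = sorted(frame_dir.glob("*.png"), key=lambda p: int(p.stem))
    if len(files) < 2:
        raise ValueError(f"sequence at {path} has {len(files)} frame(s); need >= 2")
    frames = []
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:  # collapse grayscale PNGs saved with redundant channels
            img = img[..., 0]
        frames.append(np.asarray(img, dtype=np.uint8))
    shape0 = frames[0].shape
    for f, img in zip(files, frames):
        if img.shape != shape0:
            raise ValueError(f"frame {f.name} has shape {img.shape}, expected {shape0}")
    return USSequence(meta=meta, frames=frames)


def write_sequence(seq: USSequence, path: str | Path) -> Path:
    """Write the sequence directory layout; inverse of :func:`read_sequence`."""
    path = Path(path)
    frame_dir = path / "frames"
    frame_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "sequence_id": seq.meta.sequence_id,
        "mm_per_pixel": seq.meta.mm_per_pixel,
        "frame_rate_hz": seq.meta.frame_rate_hz,
        "source_tag": seq.meta.source_tag,
    }
    (path / _META_FILENAME).write_text(yaml.safe_dump(meta, sort_keys=True))
    for i, frame in enumerate(seq.frames):
        iio.imwrite(frame_dir / f"{i:05d}.png", np.asarray(frame, dtype=np.uint8))
    return path


def _parse_annotation_file(path: Path, origin_offset: float) -> LandmarkTrack:
    track = LandmarkTrack(landmark_id=path.stem)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns 'frame x y', got {line!r}")
        try:
            frame_index = int(float(parts[0]))
            x = float(parts[1]) - origin_offset
            y = float(parts[2]) - origin_offset
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
        if frame_index < 0:
            raise ValueError(f"{path}:{lineno}: negative frame index {frame_index}")
        if x < 0 or y < 0:
            raise ValueError(f"{path}:{lineno}: out-of-bounds coordinate ({x}, {y})")
        track.points[frame_index] = (x, y)
    return track


def read_annotations(
    path: str | Path,
    origin_offset: float = 0.0,
    frame_shape: tuple[int, int] | None = None,
) -> list[LandmarkTrack]:
    """Read landmark annotation file(s): one file per landmark, rows ``frame x y``.

    ``path`` may be a single .txt file or a directory of them.
    ``origin_offset`` is subtracted from the stored coordinates, so data
    annotated with a 1-based origin can be read with ``origin_offset=1``.
    When ``frame_shape`` (height, width) is given, coordinates are checked
    against the frame bounds.
    """
    path = Path(path)
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no annotation files under {path}")
    tracks = [_parse_annotation_file(f, origin_offset) for f in files]
    if frame_shape is not None:
        h, w = frame_shape
        for t in tracks:
            for k, (x, y) in t.points.items():
                if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                    raise ValueError(
                        f"landmark {t.landmark_id} frame {k}: ({x}, {y}) outside "
                        f"{h}x{w} frame"
                    )
    return tracks


def write_predictions(tracks: list[LandmarkTrack], path: str | Path,
                      n_frames: int) -> Path:
    """Write dense per-frame predictions, one file per landmark.

    Every track must contain a point for every frame index in
    ``[0, n_frames)``; rows are ``frame_index x y`` with 4-decimal precision.
    ``path`` is a directory unless there is exactly one track and ``path``
    ends in ``.txt``.
    """
    path = Path(path)
    if not tracks and path.suffix == ".txt":
        path.write_text("")
        return path
    single_file = len(tracks) == 1 and path.suffix == ".txt"
    if not single_file:
        path.mkdir(parents=True, exist_ok=True)
    for track in tracks:
        for k in range(n_frames):
            if k not in track.points:
                raise ValueError(
                    f"track {track.landmark_id} is missing frame {k}; predictions must be dense"
                )
        out = path if single_file else path / f"{track.landmark_id}.txt"
        lines = [
            f"{k} {track.points[k][0]:.4f} {track.points[k][1]:.4f}"
            for k in range(n_frames)
        ]
        out.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def px_to_mm(distance_px: float, meta: SequenceMeta) -> float:
    """Convert a pixel distance to millimetres via the isotropic pixel spacing."""
    if distance_px < 0:
        raise ValueError("distance_px must be nonnegative")
    return distance_px * meta.mm_per_pixel
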