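"""Per-frame detection / annotation containers and coordinate-level transforms.

Three sequence containers share the same frame-indexed layout:

* :class:`DetSequence` — scored detections with masks (the detector contract);
* :class:`GroundTruthSequence` — annotated instances with persistent ids;
* :class:`TrackingResult` — tracker output, ids assigned at run time.

Transforms here never touch image content: they move coordinates (letterbox
to/from the square model resolution), drop detections by score, and thin
sequences to lower frame rates by keeping every k-th frame.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ValidationError
from .geometry import BBox, MaskPoly

__all__ = [
    "Detection",
    "GTInstance",
    "TrackedInstance",
    "DetSequence",
    "GroundTruthSequence",
    "TrackingResult",
    "LetterboxSpec",
    "filter_by_score",
    "downsample_sequence",
    "to_model_coords",
    "from_model_coords",
]


@dataclass
class Detection:
    """One detected body in one frame: box + mask + confidence + class label."""

    frame_index: int
    bbox: BBox
    mask: MaskPoly
    score: float = 1.0
    label: str = "b"

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")


@dataclass
class GTInstance:
    """One annotated instance with an id persistent across frames."""

    frame_index: int
    instance_id: int
    bbox: BBox
    mask: MaskPoly
    label: str = "b"


@dataclass
class TrackedInstance:
    """One tracker output row; the mask always originates from a detection."""

    frame_index: int
    track_id: int
    bbox: BBox
    mask: MaskPoly
    score: float = 1.0


class _FrameSequence:
    """Shared frame bookkeeping for the three sequence kinds."""

    def __init__(self, fps, frame_w, frame_h, frames, source_indices=None):
        if not fps > 0:
            raise ValidationError(f"fps must be positive, got {fps}")
        self.fps = float(fps)
        self.frame_w = int(frame_w)
        self.frame_h = int(frame_h)
        self.frames = [list(f) for f in frames]
        self.source_indices = list(source_indices) if source_indices is not None else None
        for i, frame in enumerate(self.frames):
            for obj in frame:
                if obj.frame_index != i:
                    raise ValidationError(
                        f"object in frame slot {i} carries frame_index {obj.frame_index}"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_objects(self) -> int:
        return sum(len(f) for f in self.frames)

    @property
    def frame_size(self) -> tuple[int, int]:
        return (self.frame_w, self.frame_h)

    def _clone(self, frames, fps=None, source_indices=None):
        return type(self)(
            fps if fps is not None else self.fps,
            self.frame_w,
            self.frame_h,
            frames,
            source_indices,
        )


class DetSequence(_FrameSequence):
    """Ordered per-frame lists of :class:`Detection`."""


class GroundTruthSequence(_FrameSequence):
    """Ordered per-frame lists of :class:`GTInstance`; ids unique within a frame."""

    def __init__(self, fps, frame_w, frame_h, frames, source_indices=None):
        super().__init__(fps, frame_w, frame_h, frames, source_indices)
        for i, frame in enumerate(self.frames):
            ids = [o.instance_id for o in frame]
            if len(ids) != len(set(ids)):
                dup = sorted({v for v in ids if ids.count(v) > 1})
                raise ValidationError(f"duplicate instance ids {dup} in frame {i}")

    def instance_ids(self) -> set[int]:
        return {o.instance_id for f in self.frames for o in f}


class TrackingResult(_FrameSequence):
    """Ordered per-frame lists of :class:`TrackedInstance`; ids unique within a frame."""

    def __init__(self, fps, frame_w, frame_h, frames, source_indices=None):
        super().__init__(fps, frame_w, frame_h, frames, source_indices)
        for i, frame in enumerate(self.frames):
            ids = [o.track_id for o in frame]
            if len(ids) != len(set(ids)):
                dup = sorted({v for v in ids if ids.count(v) > 1})
                raise ValidationError(f"duplicate track ids {dup} in frame {i}")

    def track_ids(self) -> set[int]:
        return {o.track_id for f in self.frames for o in f}


def filter_by_score(dets: DetSequence, min_score: float) -> DetSequence:
    """Keep detections with ``score >= min_score``; frame structure preserved.

    The boundary is inclusive: the stated minimum acceptable confidence is
    itself accepted (default operating point 0.7 for the detector contract).
    """
    if not (0.0 <= min_score <= 1.0):
        raise ConfigError(f"min_score {min_score} outside [0, 1]")
    frames = [[d for d in f if d.score >= min_score] for f in dets.frames]
    return dets._clone(frames, source_indices=dets.source_indices)


def downsample_sequence(seq, target_fps: float):
    """Thin a sequence to ``target_fps`` by keeping frames 0, k, 2k, ...

    ``seq.fps`` must be an integer multiple of ``target_fps``; no resampling
    or interpolation is performed.  Frame indices are renumbered from 0 and
    the original indices are kept in ``source_indices``.
    """
    if not target_fps > 0:
        raise ValueError(f"target_fps must be positive, got {target_fps}")
    ratio = seq.fps / target_fps
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"fps {seq.fps} is not an integer multiple of target {target_fps}"
        )
    orig = seq.source_indices if seq.source_indices is not None else list(range(seq.n_frames))
    kept = list(range(0, seq.n_frames, k))
    frames = []
    for new_idx, old_idx in enumerate(kept):
        frame = []
        for obj in seq.frames[old_idx]:
            obj = copy.copy(obj)
            obj.frame_index = new_idx
            frame.append(obj)
        frames.append(frame)
    return seq._clone(frames, fps=target_fps, source_indices=[orig[i] for i in kept])


# ---------------------------------------------------------------------------
# Letterboxing between the capture resolution and the square model resolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LetterboxSpec:
    """Zero-pad a ``src_w x src_h`` frame to a square, then scale to ``model_size``.

    The default places all padding at the bottom/right (``pad_top = pad_left
    = 0`` for landscape input) so original coordinates are unchanged before
    scaling; the pad fields make either convention recoverable.
    """

    src_w: int
    src_h: int
    model_size: int = 512
    pad_top: float = 0.0
    pad_left: float = 0.0

    @property
    def scale(self) -> float:
        return self.model_size / max(self.src_w, self.src_h)

    def __post_init__(self):
        if self.src_w <= 0 or self.src_h <= 0 or self.model_size <= 0:
            raise ConfigError("letterbox dimensions must be positive")
        if self.pad_top < 0 or self.pad_left < 0:
            raise ConfigError("letterbox padding must be nonnegative")

    @staticmethod
    def for_frame(src_w: int, src_h: int, model_size: int = 512,
                  center: bool = False) -> "LetterboxSpec":
        pad = abs(src_w - src_h)
        pad_top = pad_left = 0.0
        if center:
            if src_w >= src_h:
                pad_top = pad / 2.0
            else:
                pad_left = pad / 2.0
        return LetterboxSpec(src_w, src_h, model_size, pad_top, pad_left)


def _map_point(p, spec: LetterboxSpec, inverse: bool):
    x, y = float(p[0]), float(p[1])
    s = spec.scale
    if inverse:
        return (x / s - spec.pad_left, y / s - spec.pad_top)
    return ((x + spec.pad_left) * s, (y + spec.pad_top) * s)


def _map(obj, spec: LetterboxSpec, inverse: bool):
    if isinstance(obj, BBox):
        x, y = _map_point((obj.x, obj.y), spec, inverse)
        s = 1.0 / spec.scale if inverse else spec.scale
        return BBox(x, y, obj.w * s, obj.h * s)
    if isinstance(obj, MaskPoly):
        s = 1.0 / spec.scale if inverse else spec.scale
        if inverse:
            rings = [r / spec.scale - np.array([spec.pad_left, spec.pad_top]) for r in obj.rings]
        else:
            rings = [(r + np.array([spec.pad_left, spec.pad_top])) * s for r in obj.rings]
        return MaskPoly(rings)
    return _map_point(obj, spec, inverse)


def to_model_coords(obj, spec: LetterboxSpec):
    """Map a point, :class:`BBox`, or :class:`MaskPoly` into model coordinates."""
    return _map(obj, spec, inverse=False)


def from_model_coords(obj, spec: LetterboxSpec):
    """Inverse of :func:`to_model_coords`; round-trips within 1e-6 px."""
    return _map(obj, spec, inverse=True)
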