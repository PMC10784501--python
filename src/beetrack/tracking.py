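"""IoU-gated Hungarian association and track lifecycle management.

Per frame the tracker (1) advances every track's constant-velocity Kalman
state, (2) solves a Hungarian assignment between detections and predicted
boxes maximizing total IoU, discarding assigned pairs below the gate
``iou_min``, (3) updates matched tracks and attaches the matched detection's
mask, (4) opens a new track for every unmatched detection, and (5) deletes
tracks unseen for more than ``t_lost`` frames.  A deleted identity is never
reused: an object that reappears after deletion becomes a new track.

Output rows are emitted only for tracks matched in the current frame (the
reported box and mask are the matched detection's, so localization is never
a filter extrapolation), once a track has accumulated ``min_hits`` matches
or during the warm-up period covering the sequence's first ``min_hits``
frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import linear_sum_assignment

from .data import DetSequence, Detection, TrackedInstance, TrackingResult
from .errors import ConfigError
from .geometry import BBox, MaskPoly, bbox_iou_matrix, mask_iou
from .kalman import KalmanParams, KalmanState, kf_predict, kf_update, state_from_bbox

__all__ = ["TrackerConfig", "Track", "BeeTracker", "associate", "tracker_step",
           "run_tracker", "solve_iou_assignment"]


def solve_iou_assignment(iou: np.ndarray, iou_min: float):
    """Maximum-total-IoU assignment (cost = 1 - IoU) with gating.

    Returns ``(matches, unmatched_rows, unmatched_cols)``; assigned pairs
    with IoU below ``iou_min`` are demoted to unmatched on both sides.
    """
    iou = np.asarray(iou, dtype=float)
    n, m = iou.shape
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    rows, cols = linear_sum_assignment(1.0 - iou)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if iou[r, c] >= iou_min]
    mr = {r for r, _ in matches}
    mc = {c for _, c in matches}
    return (matches,
            [i for i in range(n) if i not in mr],
            [j for j in range(m) if j not in mc])


@dataclass(frozen=True)
class TrackerConfig:
    """Gate, lifecycle thresholds, association mode, and filter noise levels."""

    iou_min: float = 0.5
    t_lost: int = 1
    min_hits: int = 1
    association: str = "bbox"  # "bbox" (default) or "mask"
    kalman: KalmanParams = field(default_factory=KalmanParams)

    def __post_init__(self):
        if not (0.0 < self.iou_min < 1.0):
            raise ConfigError(f"iou_min must be in (0, 1), got {self.iou_min}")
        if self.t_lost < 1 or self.min_hits < 1:
            raise ConfigError("t_lost and min_hits must be >= 1")
        if self.association not in ("bbox", "mask"):
            raise ConfigError(f"unknown association mode {self.association!r}")

    @staticmethod
    def from_file(path) -> "TrackerConfig":
        """Load from a flat key-value (YAML) file; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected flat key-value pairs")
        kf_keys = {f.name for f in KalmanParams.__dataclass_fields__.values()}
        top_keys = {"iou_min", "t_lost", "min_hits", "association"}
        top, kf = {}, {}
        for k, v in raw.items():
            if k in top_keys:
                top[k] = v
            elif k in kf_keys:
                kf[k] = v
            else:
                raise ConfigError(f"{path}: unknown config key {k!r}")
        return TrackerConfig(kalman=KalmanParams(**kf), **top)


@dataclass
class Track:
    """One tracked identity with its filter state and lifecycle counters."""

    track_id: int
    state: KalmanState
    hits: int = 1
    time_since_update: int = 0
    age: int = 0
    current_mask: MaskPoly | None = None
    current_bbox: BBox | None = None     # matched detection's box (reported)
    current_score: float = 1.0
    predicted_bbox: BBox | None = None


def associate(dets: list[Detection], tracks: list[Track], iou_min: float,
              mode: str = "bbox", frame_size=None):
    """Hungarian assignment between detections and tracks' predicted boxes.

    Maximizes total IoU (cost = 1 - IoU); assigned pairs with IoU below
    ``iou_min`` are demoted to unmatched on both sides.  Returns
    ``(matches, unmatched_det_indices, unmatched_track_indices)`` with
    matches as ``(det_index, track_index)`` pairs.
    """
    if not dets or not tracks:
        return [], list(range(len(dets))), list(range(len(tracks)))
    trk_boxes = np.stack([t.predicted_bbox.as_array() for t in tracks])
    det_boxes = np.stack([d.bbox.as_array() for d in dets])
    iou = bbox_iou_matrix(det_boxes, trk_boxes)
    if mode == "mask":
        # refine overlapping candidates with mask IoU; the track's mask is its
        # last matched mask carried to the predicted center
        for di, ti in zip(*np.nonzero(iou > 0)):
            t = tracks[ti]
            if t.current_mask is None or t.current_bbox is None:
                continue
            pcx, pcy = t.predicted_bbox.center
            ccx, ccy = t.current_bbox.center
            shifted = t.current_mask.translate(pcx - ccx, pcy - ccy)
            iou[di, ti] = mask_iou(dets[di].mask, shifted, frame_size)
    return solve_iou_assignment(iou, iou_min)


class BeeTracker:
    """Stateful frame-by-frame tracker; ids are assigned in creation order."""

    def __init__(self, config: TrackerConfig | None = None, frame_size=None):
        self.config = config or TrackerConfig()
        self.frame_size = frame_size
        self.tracks: list[Track] = []
        self.next_id = 1
        self.n_created = 0

    def step(self, frame_dets: list[Detection], frame_index: int) -> list[TrackedInstance]:
        cfg = self.config
        # 1. predict
        for t in self.tracks:
            t.state, t.predicted_bbox = kf_predict(t.state, cfg.kalman)
            t.age += 1
        # 2. associate
        matches, unmatched_d, unmatched_t = associate(
            frame_dets, self.tracks, cfg.iou_min, cfg.association, self.frame_size
        )
        # 3. update matched
        outputs: list[TrackedInstance] = []
        for di, ti in matches:
            det = frame_dets[di]
            t = self.tracks[ti]
            t.state = kf_update(t.state, det.bbox, cfg.kalman)
            t.hits += 1
            t.time_since_update = 0
            t.current_mask = det.mask
            t.current_bbox = det.bbox
            t.current_score = det.score
            if t.hits >= cfg.min_hits or frame_index < cfg.min_hits:
                outputs.append(
                    TrackedInstance(frame_index, t.track_id, det.bbox, det.mask, det.score)
                )
        # 4. create a track per unmatched detection
        for di in unmatched_d:
            det = frame_dets[di]
            t = Track(
                track_id=self.next_id,
                state=state_from_bbox(det.bbox, cfg.kalman),
                current_mask=det.mask,
                current_bbox=det.bbox,
                current_score=det.score,
            )
            self.next_id += 1
            self.n_created += 1
            self.tracks.append(t)
            if t.hits >= cfg.min_hits or frame_index < cfg.min_hits:
                outputs.append(
                    TrackedInstance(frame_index, t.track_id, det.bbox, det.mask, det.score)
                )
        # 5. age out unmatched tracks
        for ti in unmatched_t:
            self.tracks[ti].time_since_update += 1
        self.tracks = [t for t in self.tracks if t.time_since_update <= cfg.t_lost]
        outputs.sort(key=lambda o: o.track_id)
        return outputs


def tracker_step(tracks: list[Track], frame_dets: list[Detection],
                 config: TrackerConfig, next_id: int = 1, frame_index: int = 0):
    """Functional single-frame step: ``(tracks, outputs, next_id)``.

    Thin wrapper over :class:`BeeTracker` for callers that manage the track
    list and id counter themselves.
    """
    trk = BeeTracker(config)
    trk.tracks = tracks
    trk.next_id = next_id
    outputs = trk.step(frame_dets, frame_index)
    return trk.tracks, outputs, trk.next_id


def run_tracker(dets: DetSequence, config: TrackerConfig | None = None) -> TrackingResult:
    """Track a whole detection sequence; deterministic given input and config."""
    config = config or TrackerConfig()
    tracker = BeeTracker(config, frame_size=dets.frame_size)
    frames = [tracker.step(frame, i) for i, frame in enumerate(dets.frames)]
    return TrackingResult(dets.fps, dets.frame_w, dets.frame_h, frames,
                          source_indices=dets.source_indices)
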