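"""Per-identity trajectories and the active / inactive classification.

A trajectory is the ordered list of a track's box centers.  Frames where a
track produced no output (coasting) are left as gaps — they are neither
interpolated nor bridged, so path length sums only steps between frames
that are actually consecutive.  Mean speed is path length divided by the
track's duration; the activity label is a plain threshold on mean speed
(the default of 5 px/s separates walking agents from resting jitter at the
10 fps operating point, and is a convenience, not a validated behavioral
criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrackingResult

__all__ = ["TrajectoryRecord", "ActivityLabel", "extract_trajectories",
           "classify_activity", "trajectory_points_table", "trajectory_summary_table"]


@dataclass
class TrajectoryRecord:
    """Center path of one track id, with simple motion summaries."""

    track_id: int
    points: list[tuple[int, float, float]]  # (frame_index, x, y)
    path_length: float                      # px, consecutive-frame steps only
    mean_speed: float                       # px/s
    duration: float                         # s, first..last observed frame


@dataclass(frozen=True)
class ActivityLabel:
    label: str           # "active" | "inactive"
    threshold_used: float  # px/s


def extract_trajectories(res: TrackingResult,
                         center: str = "bbox") -> list[TrajectoryRecord]:
    """One record per track id; centers are box centers by default.

    ``center="mask_centroid"`` uses the rasterized mask centroid instead.
    """
    if not res.fps or res.fps <= 0:
        raise ValueError("tracking result has no valid fps")
    if center not in ("bbox", "mask_centroid"):
        raise ValueError(f"unknown center source {center!r}")
    by_id: dict[int, list[tuple[int, float, float]]] = {}
    for fi, frame in enumerate(res.frames):
        for obj in frame:
            if center == "bbox":
                cx, cy = obj.bbox.center
            else:
                grid, (x0, y0) = obj.mask.rasterize(res.frame_size)
                js, is_ = np.nonzero(grid)
                cx = x0 + is_.mean() + 0.5
                cy = y0 + js.mean() + 0.5
            by_id.setdefault(obj.track_id, []).append((fi, float(cx), float(cy)))
    records = []
    for tid in sorted(by_id):
        pts = sorted(by_id[tid])
        path = 0.0
        for (f0, x0, y0), (f1, x1, y1) in zip(pts, pts[1:]):
            if f1 - f0 == 1:  # gaps contribute nothing
                path += float(np.hypot(x1 - x0, y1 - y0))
        duration = (pts[-1][0] - pts[0][0] + 1) / res.fps
        records.append(TrajectoryRecord(tid, pts, path, path / duration, duration))
    return records


def classify_activity(t: TrajectoryRecord, threshold: float = 5.0) -> ActivityLabel:
    """Inactive iff mean speed is below ``threshold`` px/s."""
    if t.duration <= 0:
        raise ValueError("trajectory has non-positive duration")
    label = "inactive" if t.mean_speed < threshold else "active"
    return ActivityLabel(label, threshold)


def trajectory_points_table(records: list[TrajectoryRecord]) -> pd.DataFrame:
    """Long-form (track_id, frame, x, y) table for export or plotting."""
    rows = [
        {"track_id": r.track_id, "frame": f, "x": x, "y": y}
        for r in records for f, x, y in r.points
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])


def trajectory_summary_table(records: list[TrajectoryRecord],
                             threshold: float = 5.0) -> pd.DataFrame:
    rows = [
        {
            "track_id": r.track_id,
            "n_points": len(r.points),
            "path_length_px": r.path_length,
            "mean_speed_px_s": r.mean_speed,
            "duration_s": r.duration,
            "activity": classify_activity(r, threshold).label,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["track_id", "n_points", "path_length_px",
                                       "mean_speed_px_s", "duration_s", "activity"])
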