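"""Synthetic dense-swarm scenes and detector-noise corruption.

The generator emulates the statistical structure of an observation-hive
recording — a 1920 x 1080 field of view holding a few hundred bee-sized
elliptical agents — without rendering image content.  Agents belong to two
behavioral regimes: *active* agents walk with a per-agent base speed and a
heading random walk, reflecting off the arena (or, in the well-separated
layout, off their own grid cell); *inactive* agents jitter around a home
position by at most one pixel.  Each agent is an oriented ellipse aligned
to its heading; an agent is annotated in a frame only when at least
``visibility_min`` of its body is inside the frame and not covered by an
agent above it in the depth order — mirroring the labeling rule of keeping
only bodies that are more than 80% visible.

:func:`corrupt_detections` turns ground truth into detector-like output:
independent misses, Gaussian localization jitter, optional mask
erosion/dilation, Poisson-distributed spurious detections, and sampled
confidence scores.  All randomness flows from the two explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry import box as _shapely_box
from shapely.ops import unary_union

from .data import DetSequence, Detection, GTInstance, GroundTruthSequence
from .errors import ConfigError
from .geometry import BBox, MaskPoly

__all__ = ["SceneConfig", "CorruptionConfig", "AgentState",
           "simulate_scene", "corrupt_detections", "ellipse_polygon"]


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one generated sequence.

    Defaults mirror the recording setup the tracker targets: a 1920 x 1080
    frame holding about 370 bees, captured for 10 s.  Body half-axes assume
    a ~14 mm bee on a 40 cm field of view (~0.21 mm/px).  Speeds are
    order-of-magnitude walking speeds in px/frame; they are not calibrated
    measurements.
    """

    frame_w: int = 1920
    frame_h: int = 1080
    n_agents: int = 370
    fps: float = 30.0
    duration: float = 10.0
    body_a: float = 33.0            # half length of the body ellipse, px
    body_b: float = 12.0            # half width, px
    speed_mean: float = 1.6         # px/frame; ~1 cm/s walking at 30 fps
    speed_sd: float = 0.6
    speed_floor: float = 0.4        # px/frame, keeps "active" clearly mobile
    heading_sd: float = 0.06        # rad/frame; ~1 rad/s turn-rate noise at 30 fps
    inactive_fraction: float = 0.5
    inactive_jitter_sd: float = 0.05  # px; jitter is clamped to +/- 1 px
    visibility_min: float = 0.8
    well_separated: bool = False    # confine each agent to its own grid cell
    n_vertices: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.n_agents < 1:
            raise ConfigError("n_agents must be >= 1")
        if not (0.0 <= self.inactive_fraction <= 1.0):
            raise ConfigError("inactive_fraction must be in [0, 1]")
        if not (0.0 < self.visibility_min <= 1.0):
            raise ConfigError("visibility_min must be in (0, 1]")
        if self.body_a < self.body_b or self.body_b <= 0:
            raise ConfigError("body half-axes must satisfy a >= b > 0")
        if 2 * self.body_a >= min(self.frame_w, self.frame_h):
            raise ConfigError("body ellipse does not fit inside the frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


@dataclass
class AgentState:
    """Generator-side truth for one agent."""

    id: int
    center: tuple[float, float]
    heading: float
    speed: float
    regime: str  # "active" | "inactive"


@dataclass(frozen=True)
class CorruptionConfig:
    """Detector-noise model applied to ground truth."""

    miss_rate: float = 0.0          # per-object drop probability
    fp_rate: float = 0.0            # expected spurious detections per frame
    jitter_sd: float = 0.0          # px, center localization noise
    mask_erode_dilate: float = 0.0  # px, sd of a signed morphological offset
    score_mean: float = 0.9
    score_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ConfigError("miss_rate must be in [0, 1]")
        if self.fp_rate < 0 or self.jitter_sd < 0 or self.mask_erode_dilate < 0:
            raise ConfigError("rates and noise scales must be nonnegative")


def ellipse_polygon(cx: float, cy: float, heading: float, a: float, b: float,
                    n_vertices: int = 16) -> np.ndarray:
    """Vertex ring of an oriented ellipse (major axis along ``heading``)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ex, ey = a * np.cos(theta), b * np.sin(theta)
    c, s = math.cos(heading), math.sin(heading)
    return np.column_stack([cx + c * ex - s * ey, cy + s * ex + c * ey])


def _cell_layout(cfg: SceneConfig):
    """Grid cells for the well-separated layout; each agent owns one cell."""
    n, W, H = cfg.n_agents, cfg.frame_w, cfg.frame_h
    ncols = max(1, math.ceil(math.sqrt(n * W / H)))
    nrows = math.ceil(n / ncols)
    cw, ch = W / ncols, H / nrows
    margin = cfg.body_a + 1.0
    if cw <= 2 * margin or ch <= 2 * margin:
        raise ConfigError(
            f"{n} well-separated agents do not fit: cell {cw:.0f}x{ch:.0f} "
            f"vs body margin {margin:.0f}"
        )
    bounds = []
    for i in range(n):
        col, row = i % ncols, i // ncols
        bounds.append((col * cw + margin, (col + 1) * cw - margin,
                       row * ch + margin, (row + 1) * ch - margin))
    return np.array(bounds)


def simulate_scene(cfg: SceneConfig, return_agents: bool = False):
    """Generate a ground-truth sequence; deterministic given ``cfg.seed``.

    With ``return_agents=True`` also returns ``(agents, paths)`` where
    ``agents`` is the list of :class:`AgentState` at frame 0 and ``paths``
    is an ``(n_frames, n_agents, 2)`` array of true centers, for tests that
    compare recovered trajectories against the generator's truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n, W, H = cfg.n_agents, cfg.frame_w, cfg.frame_h
    n_frames = cfg.n_frames

    n_inactive = int(round(cfg.inactive_fraction * n))
    inactive = np.zeros(n, dtype=bool)
    inactive[rng.permutation(n)[:n_inactive]] = True

    if cfg.well_separated:
        bounds = _cell_layout(cfg)
        span_x = bounds[:, 1] - bounds[:, 0]
        span_y = bounds[:, 3] - bounds[:, 2]
        pos = np.column_stack([
            bounds[:, 0] + span_x * (0.35 + 0.3 * rng.random(n)),
            bounds[:, 2] + span_y * (0.35 + 0.3 * rng.random(n)),
        ])
    else:
        m = cfg.body_b
        bounds = np.tile([m, W - m, m, H - m], (n, 1)).astype(float)
        pos = np.column_stack([
            rng.uniform(bounds[:, 0], bounds[:, 1]),
            rng.uniform(bounds[:, 2], bounds[:, 3]),
        ])
    home = pos.copy()
    heading = rng.uniform(-np.pi, np.pi, n)
    speed = np.maximum(rng.normal(cfg.speed_mean, cfg.speed_sd, n), cfg.speed_floor)
    speed[inactive] = 0.0

    agents = [
        AgentState(i + 1, (float(pos[i, 0]), float(pos[i, 1])), float(heading[i]),
                   float(speed[i]), "inactive" if inactive[i] else "active")
        for i in range(n)
    ]

    frame_rect = _shapely_box(0.0, 0.0, float(W), float(H))
    frames = []
    paths = np.empty((n_frames, n, 2))
    for f in range(n_frames):
        paths[f] = pos
        frames.append(_render_frame(f, pos, heading, cfg, frame_rect))

        # advance to the next frame
        turn = rng.normal(0.0, cfg.heading_sd, n)
        jitter = np.clip(rng.normal(0.0, cfg.inactive_jitter_sd, (n, 2)), -1.0, 1.0)
        heading = np.where(inactive, heading, heading + turn)  # resting bees do not spin
        step = np.column_stack([np.cos(heading), np.sin(heading)]) * speed[:, None]
        new = pos + step
        # reflect at the arena (or cell) walls, flipping the heading component
        lo_x, hi_x, lo_y, hi_y = bounds[:, 0], bounds[:, 1], bounds[:, 2], bounds[:, 3]
        for _ in range(2):  # a large step can bounce at most twice
            over = new[:, 0] > hi_x
            new[over, 0] = 2 * hi_x[over] - new[over, 0]
            heading[over] = np.pi - heading[over]
            under = new[:, 0] < lo_x
            new[under, 0] = 2 * lo_x[under] - new[under, 0]
            heading[under] = np.pi - heading[under]
            over = new[:, 1] > hi_y
            new[over, 1] = 2 * hi_y[over] - new[over, 1]
            heading[over] = -heading[over]
            under = new[:, 1] < lo_y
            new[under, 1] = 2 * lo_y[under] - new[under, 1]
            heading[under] = -heading[under]
        pos = np.where(inactive[:, None], home + jitter, new)

    gt = GroundTruthSequence(cfg.fps, W, H, frames)
    if return_agents:
        return gt, agents, paths
    return gt


def _render_frame(f: int, pos, heading, cfg: SceneConfig, frame_rect):
    """Annotated instances for one frame, applying the visibility rule."""
    n, W, H = cfg.n_agents, cfg.frame_w, cfg.frame_h
    rings = [
        ellipse_polygon(pos[i, 0], pos[i, 1], heading[i], cfg.body_a, cfg.body_b,
                        cfg.n_vertices)
        for i in range(n)
    ]
    mins = np.array([r.min(axis=0) for r in rings])
    maxs = np.array([r.max(axis=0) for r in rings])
    # pairwise bounding-rectangle overlap -> candidate occluders
    ox = (mins[:, None, 0] < maxs[None, :, 0]) & (mins[None, :, 0] < maxs[:, None, 0])
    oy = (mins[:, None, 1] < maxs[None, :, 1]) & (mins[None, :, 1] < maxs[:, None, 1])
    touch = ox & oy
    np.fill_diagonal(touch, False)
    in_frame = (mins[:, 0] >= 0) & (mins[:, 1] >= 0) & \
               (maxs[:, 0] <= W) & (maxs[:, 1] <= H)

    out = []
    polys: dict[int, _ShapelyPolygon] = {}

    def poly(i):
        if i not in polys:
            polys[i] = _ShapelyPolygon(rings[i])
        return polys[i]

    for i in range(n):
        occluders = [j for j in np.nonzero(touch[i])[0] if j > i]  # later = on top
        if in_frame[i] and not occluders:
            mask = MaskPoly([rings[i]])
            bbox = BBox(mins[i, 0], mins[i, 1],
                        maxs[i, 0] - mins[i, 0], maxs[i, 1] - mins[i, 1])
        else:
            body = poly(i)
            clipped = body if in_frame[i] else body.intersection(frame_rect)
            if clipped.is_empty or clipped.area == 0:
                continue
            visible = clipped
            if occluders:
                visible = clipped.difference(unary_union([poly(j) for j in occluders]))
            if visible.area / body.area < cfg.visibility_min:
                continue
            mask = MaskPoly.from_shapely(clipped)
            x0, y0, x1, y1 = clipped.bounds
            bbox = BBox(x0, y0, x1 - x0, y1 - y0)
        out.append(GTInstance(f, i + 1, bbox, mask))
    return out


def corrupt_detections(gt: GroundTruthSequence, cfg: CorruptionConfig) -> DetSequence:
    """Detector-like corruption of ground truth; ids are stripped.

    Misses are coupled across miss rates: with a fixed seed, every object
    dropped at a lower rate is also dropped at any higher rate, so detection
    recall degrades monotonically in ``miss_rate`` by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    # typical body extent, used to shape spurious detections
    ws = [o.bbox.w for f in gt.frames for o in f]
    hs = [o.bbox.h for f in gt.frames for o in f]
    fp_a = (float(np.median(ws)) / 2.0) if ws else 20.0
    fp_b = (float(np.median(hs)) / 2.0) if hs else 20.0

    frames = []
    for fi, frame in enumerate(gt.frames):
        k = len(frame)
        u_drop = rng.random(k)
        offsets = rng.normal(0.0, 1.0, (k, 2)) * cfg.jitter_sd
        scores = np.clip(rng.normal(cfg.score_mean, cfg.score_sd, k), 0.0, 1.0)
        deltas = (rng.normal(0.0, 1.0, k) * cfg.mask_erode_dilate
                  if cfg.mask_erode_dilate > 0 else np.zeros(k))
        dets = []
        for j, obj in enumerate(frame):
            if u_drop[j] < cfg.miss_rate:
                continue
            dx, dy = offsets[j]
            mask = obj.mask.translate(dx, dy)
            bbox = obj.bbox.translate(dx, dy)
            if deltas[j] != 0.0:
                grown = mask.to_shapely().buffer(float(deltas[j]))
                if grown.is_empty or grown.area == 0:
                    continue  # eroded away entirely
                mask = MaskPoly.from_shapely(grown)
                x0, y0, x1, y1 = grown.bounds
                bbox = BBox(x0, y0, x1 - x0, y1 - y0)
            dets.append(Detection(fi, bbox, mask, float(scores[j])))
        n_fp = rng.poisson(cfg.fp_rate)
        for _ in range(n_fp):
            cx = rng.uniform(fp_a, gt.frame_w - fp_a)
            cy = rng.uniform(fp_a, gt.frame_h - fp_a)
            hd = rng.uniform(-np.pi, np.pi)
            ring = ellipse_polygon(cx, cy, hd, fp_a, max(fp_b, 2.0), 16)
            score = float(np.clip(rng.normal(cfg.score_mean, cfg.score_sd), 0.0, 1.0))
            x0, y0 = ring.min(axis=0)
            x1, y1 = ring.max(axis=0)
            dets.append(Detection(fi, BBox(x0, y0, x1 - x0, y1 - y0),
                                  MaskPoly([ring]), score))
        frames.append(dets)
    return DetSequence(gt.fps, gt.frame_w, gt.frame_h, frames,
                       source_indices=gt.source_indices)
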