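"""Boxes, polygon masks, rasterization, and intersection-over-union primitives.

Coordinate convention
---------------------
Pixel coordinates are 0-based with the origin at the top-left corner and the
x axis pointing right, y pointing down.  A box ``(x, y, w, h)`` covers the
half-open region ``[x, x+w) x [y, y+h)``, so its area is exactly ``w * h``
and two boxes sharing an edge do not intersect.

Rasterization rule
------------------
Pixel ``(i, j)`` has its center at ``(i + 0.5, j + 0.5)``.  A pixel belongs
to a polygon mask iff its center is inside the polygon under the even-odd
(parity) rule, evaluated over all rings of the mask together.  This decides
every boundary-pixel dispute deterministically and makes the discrete mask
of an integer-aligned rectangle agree exactly with the half-open box above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.ops import unary_union

from .errors import ValidationError

__all__ = [
    "BBox",
    "MaskPoly",
    "bbox_iou",
    "bbox_iou_matrix",
    "mask_iou",
    "pixel_iou",
    "rect_mask",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box; ``x, y`` is the top-left corner, half-open extent."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(f"invalid box: w={self.w}, h={self.h} (must be > 0)")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.w, self.h], dtype=float)

    @staticmethod
    def from_array(a) -> "BBox":
        x, y, w, h = (float(v) for v in a)
        return BBox(x, y, w, h)

    def translate(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x + dx, self.y + dy, self.w, self.h)


def bbox_iou(a: BBox, b: BBox) -> float:
    """IoU of two boxes under the half-open convention; symmetric, in [0, 1]."""
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def bbox_iou_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise IoU between boxes ``A (N, 4)`` and ``B (M, 4)`` as [x, y, w, h] rows."""
    A = np.asarray(A, dtype=float).reshape(-1, 4)
    B = np.asarray(B, dtype=float).reshape(-1, 4)
    ax1, ay1 = A[:, 0:1], A[:, 1:2]
    ax2, ay2 = ax1 + A[:, 2:3], ay1 + A[:, 3:4]
    bx1, by1 = B[:, 0], B[:, 1]
    bx2, by2 = bx1 + B[:, 2], by1 + B[:, 3]
    ix = np.minimum(ax2, bx2[None, :]) - np.maximum(ax1, bx1[None, :])
    iy = np.minimum(ay2, by2[None, :]) - np.maximum(ay1, by1[None, :])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (A[:, 2] * A[:, 3])[:, None]
    area_b = (B[:, 2] * B[:, 3])[None, :]
    union = area_a + area_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


@dataclass
class MaskPoly:
    """Polygon mask: one or more rings of (x, y) vertices, even-odd semantics."""

    rings: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        clean = []
        for k, ring in enumerate(self.rings):
            arr = np.asarray(ring, dtype=float).reshape(-1, 2)
            if arr.shape[0] < 3:
                raise ValidationError(
                    f"polygon ring {k} has {arr.shape[0]} vertices (need >= 3)"
                )
            clean.append(arr)
        if not clean:
            raise ValidationError("mask has no rings")
        self.rings = clean

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def from_flat(flat_rings: list[list[float]]) -> "MaskPoly":
        """Build from COCO-style flat [x0, y0, x1, y1, ...] lists."""
        return MaskPoly([np.asarray(r, dtype=float).reshape(-1, 2) for r in flat_rings])

    def to_flat(self) -> list[list[float]]:
        return [ring.reshape(-1).tolist() for ring in self.rings]

    @staticmethod
    def from_shapely(geom) -> "MaskPoly":
        """Exterior and interior rings of a (Multi)Polygon become mask rings."""
        rings: list[np.ndarray] = []
        geoms = getattr(geom, "geoms", [geom])
        for g in geoms:
            if g.is_empty or g.area == 0:
                continue
            rings.append(np.asarray(g.exterior.coords[:-1], dtype=float))
            for hole in g.interiors:
                rings.append(np.asarray(hole.coords[:-1], dtype=float))
        if not rings:
            raise ValidationError("empty geometry cannot form a mask")
        return MaskPoly(rings)

    def to_shapely(self):
        """Union of the rings as a shapely geometry (rings assumed disjoint or nested)."""
        polys = []
        for ring in self.rings:
            p = _ShapelyPolygon(ring)
            if not p.is_valid:
                p = p.buffer(0)
            polys.append(p)
        return unary_union(polys)

    def translate(self, dx: float, dy: float) -> "MaskPoly":
        return MaskPoly([ring + np.array([dx, dy]) for ring in self.rings])

    # -- rasterization --------------------------------------------------------

    def rasterize(self, frame_size: tuple[int, int] | None = None):
        """Discrete pixel set of the mask.

        Returns ``(grid, (x0, y0))`` where ``grid[j, i]`` is True iff pixel
        ``(x0 + i, y0 + j)`` belongs to the mask.  When ``frame_size`` =
        ``(w, h)`` is given, pixels outside the frame are clipped away.
        """
        return _rasterize_rings(self.rings, frame_size)

    def area_pixels(self, frame_size: tuple[int, int] | None = None) -> int:
        grid, _ = self.rasterize(frame_size)
        return int(grid.sum())

    def derived_bbox(self, frame_size: tuple[int, int] | None = None) -> BBox:
        """Tight half-open bounds of the rasterized pixel set."""
        grid, (x0, y0) = self.rasterize(frame_size)
        if not grid.any():
            raise ValidationError("mask rasterizes to an empty pixel set")
        js, is_ = np.nonzero(grid)
        return BBox(
            x0 + is_.min(), y0 + js.min(), is_.max() - is_.min() + 1, js.max() - js.min() + 1
        )


def _rasterize_rings(rings, frame_size=None):
    """Even-odd scanline fill at pixel centers over the rings' joint bounds."""
    pts = np.concatenate(rings, axis=0)
    x0 = int(np.floor(pts[:, 0].min()))
    x1 = int(np.ceil(pts[:, 0].max()))
    y0 = int(np.floor(pts[:, 1].min()))
    y1 = int(np.ceil(pts[:, 1].max()))
    if frame_size is not None:
        fw, fh = frame_size
        x0, x1 = max(x0, 0), min(x1, int(fw))
        y0, y1 = max(y0, 0), min(y1, int(fh))
    w, h = max(x1 - x0, 0), max(y1 - y0, 0)
    grid = np.zeros((h, w), dtype=bool)
    if w == 0 or h == 0:
        return grid, (x0, y0)

    # edge list over all rings (closing edge included)
    e1 = np.concatenate([r for r in rings], axis=0)
    e2 = np.concatenate([np.roll(r, -1, axis=0) for r in rings], axis=0)
    ey1, ey2 = e1[:, 1], e2[:, 1]
    ex1, ex2 = e1[:, 0], e2[:, 0]
    nonhoriz = ey1 != ey2
    ex1, ex2, ey1, ey2 = ex1[nonhoriz], ex2[nonhoriz], ey1[nonhoriz], ey2[nonhoriz]
    if ex1.size == 0:
        return grid, (x0, y0)
    slope = (ex2 - ex1) / (ey2 - ey1)

    for j in range(h):
        yc = y0 + j + 0.5
        # an edge crosses the scanline iff exactly one endpoint lies below it
        crosses = (ey1 <= yc) != (ey2 <= yc)
        if not crosses.any():
            continue
        xs = np.sort(ex1[crosses] + (yc - ey1[crosses]) * slope[crosses])
        for k in range(0, xs.size - 1, 2):
            lo, hi = xs[k], xs[k + 1]
            i_lo = max(int(np.ceil(lo - 0.5)) - x0, 0)  # first i with i + 0.5 >= lo
            i_hi = min(int(np.ceil(hi - 0.5)) - x0, w)  # first i with i + 0.5 >= hi
            if i_hi > i_lo:
                grid[j, i_lo:i_hi] = True
    return grid, (x0, y0)


def pixel_iou(grid_a, off_a, grid_b, off_b) -> float:
    """IoU of two rasterized masks given as (bool grid, (x0, y0)) pairs."""
    na, nb = int(grid_a.sum()), int(grid_b.sum())
    if na == 0 and nb == 0:
        return 0.0
    ax0, ay0 = off_a
    bx0, by0 = off_b
    x0 = max(ax0, bx0)
    y0 = max(ay0, by0)
    x1 = min(ax0 + grid_a.shape[1], bx0 + grid_b.shape[1])
    y1 = min(ay0 + grid_a.shape[0], by0 + grid_b.shape[0])
    inter = 0
    if x1 > x0 and y1 > y0:
        sub_a = grid_a[y0 - ay0 : y1 - ay0, x0 - ax0 : x1 - ax0]
        sub_b = grid_b[y0 - by0 : y1 - by0, x0 - bx0 : x1 - bx0]
        inter = int(np.count_nonzero(sub_a & sub_b))
    union = na + nb - inter
    return inter / union if union > 0 else 0.0


def mask_iou(a: MaskPoly, b: MaskPoly, frame_size: tuple[int, int] | None = None) -> float:
    """Pixel-set IoU of two polygon masks; 0 when the union is empty."""
    ga, oa = a.rasterize(frame_size)
    gb, ob = b.rasterize(frame_size)
    return pixel_iou(ga, oa, gb, ob)


def rect_mask(box: BBox) -> MaskPoly:
    """Rectangular mask whose rasterization equals the box's half-open pixel set."""
    return MaskPoly(
        [np.array([[box.x, box.y], [box.x2, box.y], [box.x2, box.y2], [box.x, box.y2]])]
    )
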