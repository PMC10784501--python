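"""Read and write the COCO-dialect annotation files and MOTChallenge text.

The dialect is the usual COCO layout — ``images``, ``categories`` (a single
category ``"b"``), ``annotations`` with ``bbox`` as ``[x, y, w, h]`` and
``segmentation`` as flat polygon rings — plus ``score`` on detections and a
persistent ``instance_id`` (accepted aliases: ``track_id``, or either key
inside ``attributes``) on ground truth and tracking output.  Uncompressed
RLE segmentations are accepted on read; polygons are always written.
Sequence-level frame rate lives in ``info.fps``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import box as _shapely_box
from shapely.ops import unary_union

from .data import (
    DetSequence,
    Detection,
    GTInstance,
    GroundTruthSequence,
    TrackedInstance,
    TrackingResult,
)
from .errors import ParseError, ValidationError
from .geometry import BBox, MaskPoly

__all__ = [
    "read_ground_truth",
    "read_detections",
    "read_tracking_result",
    "write_ground_truth",
    "write_detections",
    "write_tracking_result",
    "write_mot_rows",
]

_ID_KEYS = ("instance_id", "track_id")


def _rle_to_mask(rle: dict) -> MaskPoly:
    """Uncompressed COCO RLE (column-major runs) to a polygon mask.

    Each run of foreground pixels becomes a stack of unit squares; their
    union's rings reproduce the exact pixel set under the center-parity
    rasterization rule.
    """
    try:
        h, w = rle["size"]
        counts = rle["counts"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed RLE segmentation: {rle!r}") from exc
    if isinstance(counts, str):
        raise ParseError("compressed RLE strings are not supported; use uncompressed counts")
    grid = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            grid[pos : pos + c] = True
        pos += c
        val = not val
    grid = grid.reshape((w, h)).T  # column-major
    cells = [
        _shapely_box(i, j, i + 1, j + 1)
        for j, i in zip(*np.nonzero(grid))
    ]
    if not cells:
        raise ValidationError("RLE segmentation rasterizes to an empty pixel set")
    return MaskPoly.from_shapely(unary_union(cells))


def _parse_segmentation(seg, ann_id) -> MaskPoly:
    if isinstance(seg, dict):
        return _rle_to_mask(seg)
    if not isinstance(seg, list) or not seg:
        raise ParseError(f"annotation {ann_id}: missing or empty segmentation")
    try:
        return MaskPoly.from_flat(seg)
    except ValidationError as exc:
        raise ValidationError(f"annotation {ann_id}: {exc}") from exc


def _load(path):
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except FileNotFoundError:
        raise
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "images" not in doc:
        raise ParseError(f"{path}: not a COCO-dialect document (no 'images')")
    return doc


def _frame_table(doc):
    """image id -> frame slot, plus (w, h, fps)."""
    images = doc.get("images", [])
    if not images:
        raise ParseError("document has no images")
    order = sorted(
        images, key=lambda im: (im.get("frame_index", im.get("id", 0)), im.get("id", 0))
    )
    slots, widths, heights = {}, set(), set()
    for rank, im in enumerate(order):
        try:
            slots[im["id"]] = im.get("frame_index", rank)
            widths.add(int(im["width"]))
            heights.add(int(im["height"]))
        except KeyError as exc:
            raise ParseError(f"image record {im!r} missing {exc}") from exc
    if len(widths) != 1 or len(heights) != 1:
        raise ValidationError(f"inconsistent image dimensions: {widths}x{heights}")
    n = len(order)
    if sorted(slots.values()) != list(range(n)):
        raise ValidationError("image frame indices are not contiguous from 0")
    fps = float(doc.get("info", {}).get("fps", 0) or 0)
    return slots, widths.pop(), heights.pop(), fps, n


def _parse_objects(doc, need_id: bool, need_score: bool):
    slots, w, h, fps, n = _frame_table(doc)
    frames = [[] for _ in range(n)]
    for ann in doc.get("annotations", []):
        ann_id = ann.get("id", "<no id>")
        try:
            frame = slots[ann["image_id"]]
        except KeyError as exc:
            raise ParseError(f"annotation {ann_id}: unknown or missing image_id") from exc
        mask = _parse_segmentation(ann.get("segmentation"), ann_id)
        if "bbox" in ann:
            try:
                bbox = BBox.from_array(ann["bbox"])
            except (TypeError, ValueError, ValidationError) as exc:
                raise ParseError(f"annotation {ann_id}: bad bbox {ann.get('bbox')!r}") from exc
        else:
            xs = np.concatenate([r[:, 0] for r in mask.rings])
            ys = np.concatenate([r[:, 1] for r in mask.rings])
            bbox = BBox(xs.min(), ys.min(), xs.max() - xs.min(), ys.max() - ys.min())
        inst = None
        attrs = ann.get("attributes", {}) if isinstance(ann.get("attributes"), dict) else {}
        for key in _ID_KEYS:
            if key in ann:
                inst = int(ann[key])
                break
            if key in attrs:
                inst = int(attrs[key])
                break
        if need_id and inst is None:
            raise ParseError(f"annotation {ann_id}: no instance/track id field")
        score = float(ann.get("score", 1.0))
        label = str(ann.get("category_name", "b"))
        frames[frame].append((inst, bbox, mask, score, label, ann_id))
    return frames, w, h, fps


def read_ground_truth(path) -> GroundTruthSequence:
    """Load annotated instances with persistent ids from a COCO-dialect file."""
    doc = _load(path)
    raw, w, h, fps = _parse_objects(doc, need_id=True, need_score=False)
    frames = []
    for i, frame in enumerate(raw):
        seen = {}
        out = []
        for inst, bbox, mask, _score, label, ann_id in frame:
            if inst in seen:
                raise ValidationError(
                    f"duplicate (frame {i}, instance_id {inst}) at annotations "
                    f"{seen[inst]} and {ann_id}"
                )
            seen[inst] = ann_id
            out.append(GTInstance(i, inst, bbox, mask, label))
        frames.append(out)
    return GroundTruthSequence(fps or 1.0, w, h, frames)


def read_detections(path) -> DetSequence:
    """Load scored detections (no ids) from a COCO-dialect file."""
    doc = _load(path)
    raw, w, h, fps = _parse_objects(doc, need_id=False, need_score=True)
    frames = [
        [Detection(i, bbox, mask, score, label) for _inst, bbox, mask, score, label, _a in frame]
        for i, frame in enumerate(raw)
    ]
    return DetSequence(fps or 1.0, w, h, frames)


def read_tracking_result(path) -> TrackingResult:
    """Load tracker output (ids + scores) from a COCO-dialect file."""
    doc = _load(path)
    raw, w, h, fps = _parse_objects(doc, need_id=True, need_score=True)
    frames = [
        [TrackedInstance(i, inst, bbox, mask, score) for inst, bbox, mask, score, _l, _a in frame]
        for i, frame in enumerate(raw)
    ]
    return TrackingResult(fps or 1.0, w, h, frames)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _round(v, nd=6):
    return round(float(v), nd)


def _base_doc(seq):
    return {
        "info": {"fps": seq.fps},
        "images": [
            {
                "id": i + 1,
                "frame_index": i,
                "width": seq.frame_w,
                "height": seq.frame_h,
                "file_name": f"frame_{i:06d}.png",
            }
            for i in range(seq.n_frames)
        ],
        "categories": [{"id": 1, "name": "b"}],
        "annotations": [],
    }


def _ann(ann_id, frame, obj, nd=6):
    seg = [[_round(v, nd) for v in ring] for ring in obj.mask.to_flat()]
    return {
        "id": ann_id,
        "image_id": frame + 1,
        "category_id": 1,
        "bbox": [_round(obj.bbox.x, nd), _round(obj.bbox.y, nd),
                 _round(obj.bbox.w, nd), _round(obj.bbox.h, nd)],
        "segmentation": seg,
        "area": _round(obj.bbox.area, nd),
        "iscrowd": 0,
    }


def _write(doc, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def write_ground_truth(seq: GroundTruthSequence, path, nd: int = 6) -> None:
    doc = _base_doc(seq)
    k = 1
    for i, frame in enumerate(seq.frames):
        for obj in frame:
            rec = _ann(k, i, obj, nd)
            rec["instance_id"] = int(obj.instance_id)
            doc["annotations"].append(rec)
            k += 1
    _write(doc, path)


def write_detections(seq: DetSequence, path, nd: int = 6) -> None:
    doc = _base_doc(seq)
    k = 1
    for i, frame in enumerate(seq.frames):
        for obj in frame:
            rec = _ann(k, i, obj, nd)
            rec["score"] = _round(obj.score, nd)
            doc["annotations"].append(rec)
            k += 1
    _write(doc, path)


def write_tracking_result(res: TrackingResult, path, nd: int = 6) -> None:
    doc = _base_doc(res)
    k = 1
    for i, frame in enumerate(res.frames):
        for obj in frame:
            rec = _ann(k, i, obj, nd)
            rec["track_id"] = int(obj.track_id)
            rec["score"] = _round(obj.score, nd)
            doc["annotations"].append(rec)
            k += 1
    _write(doc, path)


def write_mot_rows(res: TrackingResult, path) -> None:
    """Export MOTChallenge text: frame, id, left, top, w, h, conf, -1, -1, -1.

    Frame numbers are 1-based in this export only, per that format.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, frame in enumerate(res.frames):
            for obj in frame:
                b = obj.bbox
                fh.write(
                    f"{i + 1},{obj.track_id},{b.x:.2f},{b.y:.2f},{b.w:.2f},{b.h:.2f},"
                    f"{obj.score:.4f},-1,-1,-1\n"
                )
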