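"""Evaluation layers: instance-segmentation AP, CLEAR MOT, and MOTS.

Three evaluators share the same inputs (a :class:`GroundTruthSequence` and
either scored detections or a :class:`TrackingResult`):

* :func:`compute_ap` — average precision of scored masks at a fixed IoU
  threshold (inclusive ``>= 0.5`` by default), all-point interpolation of
  the precision-recall curve.  With a single class, mAP equals AP.
* :func:`clear_mot` — box-level MOTA / MOTP / recall with frame-to-frame
  correspondence carry-over and identity-switch counting.
* :func:`mots_eval` — mask-level MOTSA / MOTSP / recall.  Matching uses the
  strict ``> 0.5`` mask-IoU rule, which makes the per-frame matching unique
  when result masks are pairwise disjoint; overlapping result masks are a
  validation error by default (``overlap="resolve"`` assigns disputed pixels
  to the lowest track id instead).

MOTP and MOTSP are reported as mean IoU of the matches in percent — the
benchmark-server convention, where 100 means perfect localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .data import DetSequence, GroundTruthSequence, TrackingResult
from .errors import MaskOverlapError, ValidationError
from .geometry import bbox_iou_matrix, pixel_iou

__all__ = ["MatchCounts", "APResult", "ClearMotReport", "MotsReport",
           "compute_ap", "clear_mot", "mots_eval", "write_report"]


@dataclass
class MatchCounts:
    """Object- or pixel-level confusion counts."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be nonnegative")


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------


@dataclass
class APResult:
    """Precision-recall curve and its area for a single-class evaluator."""

    recall: np.ndarray
    precision: np.ndarray
    ap: float
    counts: MatchCounts
    iou_thresh: float
    degenerate: bool = False  # no ground truth and no detections

    @property
    def map(self) -> float:
        """With one object class, mAP and AP coincide."""
        return self.ap

    def to_dict(self) -> dict:
        return {
            "ap": self.ap, "map": self.map, "iou_thresh": self.iou_thresh,
            "tp": self.counts.tp, "fp": self.counts.fp, "fn": self.counts.fn,
            "degenerate": self.degenerate,
        }


def _frame_rasters(objs, frame_size):
    return [o.mask.rasterize(frame_size) for o in objs]


def _area_under_pr(rec: np.ndarray, pre: np.ndarray, interpolation: str) -> float:
    if rec.size == 0:
        return 0.0
    if interpolation == "11pt":
        pts = []
        for t in np.linspace(0, 1, 11):
            sel = rec >= t - 1e-12
            pts.append(pre[sel].max() if sel.any() else 0.0)
        return float(np.mean(pts))
    # all-point: area under the precision envelope of the exact step curve
    mrec = np.concatenate(([0.0], rec))
    mpre = np.concatenate(([pre[0] if pre.size else 0.0], pre))
    for i in range(mpre.size - 1, 0, -1):
        mpre[i - 1] = max(mpre[i - 1], mpre[i])
    return float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))


def compute_ap(gt: GroundTruthSequence, dets: DetSequence, iou_thresh: float = 0.5,
               iou_on: str = "mask", interpolation: str = "all") -> APResult:
    """Average precision of scored detections against annotated instances.

    Detections are ranked by descending score (ties broken by input order)
    and greedily matched to the highest-IoU unmatched ground truth in their
    frame with IoU ``>= iou_thresh``; everything else is a false positive,
    unmatched ground truths are false negatives.
    """
    if gt.n_frames != dets.n_frames:
        raise ValidationError(
            f"frame count mismatch: gt {gt.n_frames} vs detections {dets.n_frames}"
        )
    n_gt = gt.n_objects
    order = []
    for fi, frame in enumerate(dets.frames):
        for di, d in enumerate(frame):
            order.append((-d.score, len(order), fi, di))
    order.sort()
    if n_gt == 0 and not order:
        return APResult(np.array([]), np.array([]), 1.0, MatchCounts(),
                        iou_thresh, degenerate=True)
    if not order:
        return APResult(np.array([]), np.array([]), 0.0,
                        MatchCounts(fn=n_gt), iou_thresh)

    frame_size = gt.frame_size
    if iou_on == "mask":
        gt_r = [_frame_rasters(f, frame_size) for f in gt.frames]
        det_r = [_frame_rasters(f, frame_size) for f in dets.frames]
        gt_bounds = [_bounds_array(r) for r in gt_r]
        det_bounds = [_bounds_array(r) for r in det_r]
    else:
        gt_bounds = [np.array([[o.bbox.x, o.bbox.y, o.bbox.x2, o.bbox.y2]
                               for o in f]).reshape(-1, 4) for f in gt.frames]
        det_bounds = [np.array([[o.bbox.x, o.bbox.y, o.bbox.x2, o.bbox.y2]
                                for o in f]).reshape(-1, 4) for f in dets.frames]
    gt_used = [np.zeros(len(f), dtype=bool) for f in gt.frames]
    tp_flags = np.zeros(len(order), dtype=bool)
    for k, (_negs, _ord, fi, di) in enumerate(order):
        best_iou, best_j = 0.0, -1
        det = dets.frames[fi][di]
        cand = _overlapping_pairs(det_bounds[fi][di:di + 1], gt_bounds[fi])[:, 1]
        for j in cand:
            if gt_used[fi][j]:
                continue
            if iou_on == "mask":
                iou = pixel_iou(*det_r[fi][di], *gt_r[fi][j])
            else:
                g = gt.frames[fi][j]
                iou = bbox_iou_matrix(det.bbox.as_array(), g.bbox.as_array())[0, 0]
            if iou > best_iou:
                best_iou, best_j = iou, int(j)
        if best_j >= 0 and best_iou >= iou_thresh:
            tp_flags[k] = True
            gt_used[fi][best_j] = True
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_gt if n_gt > 0 else np.zeros_like(tp_cum, dtype=float)
    ap = _area_under_pr(recall, precision, interpolation) if n_gt > 0 else 0.0
    counts = MatchCounts(tp=int(tp_cum[-1]), fp=int(fp_cum[-1]),
                         fn=int(n_gt - tp_cum[-1]))
    return APResult(recall, precision, ap, counts, iou_thresh)


# ---------------------------------------------------------------------------
# CLEAR MOT
# ---------------------------------------------------------------------------


@dataclass
class ClearMotReport:
    """Box-level multi-object tracking accuracy and precision, in percent."""

    mota: float
    motp: float
    recall: float
    n_gt: int
    n_matches: int
    fn: int
    fp: int
    idsw: int
    per_frame: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"mota": self.mota, "motp": self.motp, "recall": self.recall,
                "n_gt": self.n_gt, "n_matches": self.n_matches,
                "fn": self.fn, "fp": self.fp, "idsw": self.idsw}

    def summary(self) -> str:
        return (f"MOTA {self.mota:.2f}%  MOTP {self.motp:.2f}%  "
                f"recall {self.recall:.2f}%  "
                f"(GT {self.n_gt}, FN {self.fn}, FP {self.fp}, IDSW {self.idsw})")


def _check_compatible(gt, res):
    if gt.n_frames != res.n_frames:
        raise ValidationError(
            f"frame count mismatch: gt {gt.n_frames} vs result {res.n_frames}"
        )
    if gt.frame_size != res.frame_size:
        raise ValidationError(
            f"resolution mismatch: gt {gt.frame_size} vs result {res.frame_size}"
        )


def clear_mot(gt: GroundTruthSequence, res: TrackingResult,
              iou_min: float = 0.5) -> ClearMotReport:
    """CLEAR MOT over box IoU.

    Correspondences from the previous frame are kept while their IoU stays
    at or above ``iou_min``; the remainder is matched per frame by a
    Hungarian assignment maximizing IoU.  An identity switch is counted when
    a ground-truth object is matched to a different result id than its last
    known match (gaps included).
    """
    _check_compatible(gt, res)
    prev: dict[int, int] = {}
    last: dict[int, int] = {}
    fn = fp = idsw = n_matches = 0
    iou_sum = 0.0
    rows = []
    for fi in range(gt.n_frames):
        gt_objs = gt.frames[fi]
        res_objs = res.frames[fi]
        g_ids = [o.instance_id for o in gt_objs]
        r_ids = [o.track_id for o in res_objs]
        g_pos = {g: i for i, g in enumerate(g_ids)}
        r_pos = {r: i for i, r in enumerate(r_ids)}
        if gt_objs and res_objs:
            iou = bbox_iou_matrix(
                np.stack([o.bbox.as_array() for o in gt_objs]),
                np.stack([o.bbox.as_array() for o in res_objs]),
            )
        else:
            iou = np.zeros((len(gt_objs), len(res_objs)))
        matches: dict[int, int] = {}
        used_r: set[int] = set()
        for g_id, r_id in prev.items():
            gi, ri = g_pos.get(g_id), r_pos.get(r_id)
            if gi is not None and ri is not None and iou[gi, ri] >= iou_min:
                matches[g_id] = r_id
                used_r.add(r_id)
        free_g = [i for i, g in enumerate(g_ids) if g not in matches]
        free_r = [i for i, r in enumerate(r_ids) if r not in used_r]
        if free_g and free_r:
            sub = iou[np.ix_(free_g, free_r)]
            ri_, ci_ = linear_sum_assignment(-sub)
            for a, b in zip(ri_, ci_):
                if sub[a, b] >= iou_min:
                    matches[g_ids[free_g[a]]] = r_ids[free_r[b]]
        frame_idsw = 0
        for g_id, r_id in matches.items():
            if g_id in last and last[g_id] != r_id:
                frame_idsw += 1
            last[g_id] = r_id
            iou_sum += iou[g_pos[g_id], r_pos[r_id]]
        frame_fn = len(gt_objs) - len(matches)
        frame_fp = len(res_objs) - len(matches)
        fn += frame_fn
        fp += frame_fp
        idsw += frame_idsw
        n_matches += len(matches)
        rows.append({"frame": fi, "gt": len(gt_objs), "matches": len(matches),
                     "fn": frame_fn, "fp": frame_fp, "idsw": frame_idsw})
        prev = matches
    n_gt = gt.n_objects
    mota = 100.0 * (1.0 - (fn + fp + idsw) / n_gt) if n_gt else 100.0
    motp = 100.0 * iou_sum / n_matches if n_matches else 0.0
    recall = 100.0 * n_matches / n_gt if n_gt else 100.0
    return ClearMotReport(mota, motp, recall, n_gt, n_matches, fn, fp, idsw,
                          per_frame=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# MOTS
# ---------------------------------------------------------------------------


@dataclass
class MotsReport:
    """Mask-level tracking-and-segmentation metrics, in percent."""

    motsa: float
    motsp: float
    smotsa: float
    recall: float
    n_gt: int
    tp: int
    fp: int
    fn: int
    ids: int
    tp_iou_sum: float
    per_frame: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"motsa": self.motsa, "motsp": self.motsp, "smotsa": self.smotsa,
                "recall": self.recall, "n_gt": self.n_gt, "tp": self.tp,
                "fp": self.fp, "fn": self.fn, "ids": self.ids,
                "tp_iou_sum": self.tp_iou_sum}

    def summary(self) -> str:
        return (f"MOTSA {self.motsa:.2f}%  MOTSP {self.motsp:.2f}%  "
                f"recall {self.recall:.2f}%  "
                f"(GT {self.n_gt}, TP {self.tp}, FP {self.fp}, FN {self.fn}, "
                f"IDS {self.ids})")


def _raster_bounds_overlap(ra, rb):
    (ga, (ax, ay)), (gb, (bx, by)) = ra, rb
    return not (ax + ga.shape[1] <= bx or bx + gb.shape[1] <= ax
                or ay + ga.shape[0] <= by or by + gb.shape[0] <= ay)


def _bounds_array(rasters) -> np.ndarray:
    """(n, 4) rows of [x0, y0, x1, y1] pixel bounds per raster."""
    if not rasters:
        return np.zeros((0, 4))
    return np.array([[off[0], off[1], off[0] + g.shape[1], off[1] + g.shape[0]]
                     for g, off in rasters], dtype=float)


def _overlapping_pairs(bounds_a: np.ndarray, bounds_b: np.ndarray):
    """Index pairs whose pixel bounds intersect (vectorized prefilter)."""
    if bounds_a.size == 0 or bounds_b.size == 0:
        return np.zeros((0, 2), dtype=int)
    ox = (np.minimum(bounds_a[:, None, 2], bounds_b[None, :, 2])
          > np.maximum(bounds_a[:, None, 0], bounds_b[None, :, 0]))
    oy = (np.minimum(bounds_a[:, None, 3], bounds_b[None, :, 3])
          > np.maximum(bounds_a[:, None, 1], bounds_b[None, :, 1]))
    return np.argwhere(ox & oy)


def _resolve_overlaps(rasters, ids):
    """Assign disputed pixels to the lowest track id; returns new rasters."""
    order = np.argsort(ids, kind="stable")
    claimed: list = []
    out = list(rasters)
    for k in order:
        grid, off = rasters[k]
        grid = grid.copy()
        for cg, coff in claimed:
            if _raster_bounds_overlap((grid, off), (cg, coff)):
                x0 = max(off[0], coff[0]); y0 = max(off[1], coff[1])
                x1 = min(off[0] + grid.shape[1], coff[0] + cg.shape[1])
                y1 = min(off[1] + grid.shape[0], coff[1] + cg.shape[0])
                grid[y0 - off[1]:y1 - off[1], x0 - off[0]:x1 - off[0]] &= ~cg[
                    y0 - coff[1]:y1 - coff[1], x0 - coff[0]:x1 - coff[0]]
        out[k] = (grid, off)
        claimed.append((grid, off))
    return out


def mots_eval(gt: GroundTruthSequence, res: TrackingResult,
              iou_thresh: float = 0.5, overlap: str = "error") -> MotsReport:
    """Mask-level tracking evaluation with the strict ``IoU > iou_thresh`` rule.

    ``overlap`` controls what happens when result masks within a frame share
    pixels: ``"error"`` raises :class:`MaskOverlapError` listing the pairs,
    ``"resolve"`` gives each disputed pixel to the lowest track id.
    """
    if overlap not in ("error", "resolve"):
        raise ValueError(f"unknown overlap mode {overlap!r}")
    _check_compatible(gt, res)
    frame_size = gt.frame_size
    tp = fp = fn = ids_count = 0
    iou_sum = 0.0
    last: dict[int, int] = {}
    rows = []
    bad_pairs = []
    for fi in range(gt.n_frames):
        gt_objs, res_objs = gt.frames[fi], res.frames[fi]
        r_ids = [o.track_id for o in res_objs]
        res_r = [o.mask.rasterize(frame_size) for o in res_objs]
        # pairwise disjointness of result masks
        res_bounds = _bounds_array(res_r)
        overlapping = []
        for a, b in _overlapping_pairs(res_bounds, res_bounds):
            if a < b and pixel_iou(*res_r[a], *res_r[b]) > 0:
                overlapping.append((fi, r_ids[a], r_ids[b]))
        if overlapping:
            if overlap == "error":
                bad_pairs.extend(overlapping)
                continue
            res_r = _resolve_overlaps(res_r, r_ids)
        gt_r = [o.mask.rasterize(frame_size) for o in gt_objs]
        # candidate IoUs above the strict threshold
        cands = []
        for gi, ri in _overlapping_pairs(_bounds_array(gt_r), res_bounds):
            v = pixel_iou(*gt_r[gi], *res_r[ri])
            if v > iou_thresh:
                cands.append((v, int(gi), int(ri)))
        cands.sort(key=lambda c: (-c[0], c[1], c[2]))
        used_g: set[int] = set()
        used_r: set[int] = set()
        frame_ids = 0
        frame_tp = 0
        for v, gi, ri in cands:
            if gi in used_g or ri in used_r:
                continue
            used_g.add(gi)
            used_r.add(ri)
            g_id, r_id = gt_objs[gi].instance_id, r_ids[ri]
            if g_id in last and last[g_id] != r_id:
                frame_ids += 1
            last[g_id] = r_id
            iou_sum += v
            frame_tp += 1
        frame_fp = len(res_objs) - frame_tp
        frame_fn = len(gt_objs) - frame_tp
        tp += frame_tp
        fp += frame_fp
        fn += frame_fn
        ids_count += frame_ids
        rows.append({"frame": fi, "gt": len(gt_objs), "tp": frame_tp,
                     "fp": frame_fp, "fn": frame_fn, "ids": frame_ids})
    if bad_pairs:
        raise MaskOverlapError(bad_pairs)
    n_gt = gt.n_objects
    motsa = 100.0 * (tp - fp - ids_count) / n_gt if n_gt else 100.0
    smotsa = 100.0 * (iou_sum - fp - ids_count) / n_gt if n_gt else 100.0
    motsp = 100.0 * iou_sum / tp if tp else 0.0
    recall = 100.0 * tp / n_gt if n_gt else 100.0
    return MotsReport(motsa, motsp, smotsa, recall, n_gt, tp, fp, fn,
                      ids_count, iou_sum, per_frame=pd.DataFrame(rows))


def write_report(report, path) -> None:
    """Write a metrics report: flat key-value YAML plus per-frame CSV."""
    import yaml
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    def _plain(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, np.integer)):
            return int(v)
        if isinstance(v, (float, np.floating)):
            return float(v)
        return v

    with open(path, "w") as fh:
        yaml.safe_dump({k: _plain(v) for k, v in report.to_dict().items()}, fh)
    per_frame = getattr(report, "per_frame", None)
    if per_frame is not None:
        per_frame.to_csv(path.with_suffix(".frames.csv"), index=False)
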