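"""Hand-checkable values and invariances for AP, CLEAR MOT, and MOTS."""

import numpy as np
import pytest

import beetrack as bt
from beetrack.errors import MaskOverlapError, ValidationError

from conftest import rect_det, rect_gt, rect_tracked


def gt_seq(frames, fps=10.0, size=(640, 480)):
    return bt.GroundTruthSequence(fps, *size, frames)


def det_seq(frames, fps=10.0, size=(640, 480)):
    return bt.DetSequence(fps, *size, frames)


def res_seq(frames, fps=10.0, size=(640, 480)):
    return bt.TrackingResult(fps, *size, frames)


class TestComputeAP:
    def test_perfect_detector(self):
        gt = gt_seq([[rect_gt(0, 1, 10, 10, 20, 20), rect_gt(0, 2, 100, 10, 20, 20)],
                     [rect_gt(1, 1, 12, 10, 20, 20)]])
        dets = det_seq([[rect_det(0, 10, 10, 20, 20, 0.6), rect_det(0, 100, 10, 20, 20, 0.9)],
                        [rect_det(1, 12, 10, 20, 20, 0.8)]])
        out = bt.compute_ap(gt, dets)
        assert out.ap == pytest.approx(1.0)
        assert out.map == out.ap  # single class
        assert (out.counts.tp, out.counts.fp, out.counts.fn) == (3, 0, 0)

    def test_duplicate_prediction_ranked_second(self):
        """1 GT, 2 predictions on it: the higher-scored one is TP, the
        duplicate FP; with all-point interpolation AP stays 1.0."""
        gt = gt_seq([[rect_gt(0, 1, 10, 10, 20, 20)]])
        dets = det_seq([[rect_det(0, 10, 10, 20, 20, 0.9),
                         rect_det(0, 11, 10, 20, 20, 0.8)]])
        out = bt.compute_ap(gt, dets)
        assert (out.counts.tp, out.counts.fp) == (1, 1)
        assert out.ap == pytest.approx(1.0)

    def test_half_recall_gives_half_ap(self):
        gt = gt_seq([[rect_gt(0, 1, 10, 10, 20, 20), rect_gt(0, 2, 100, 10, 20, 20)]])
        dets = det_seq([[rect_det(0, 10, 10, 20, 20, 0.9)]])
        out = bt.compute_ap(gt, dets)
        assert out.ap == pytest.approx(0.5)

    def test_degenerate_empty_case_flagged(self):
        out = bt.compute_ap(gt_seq([[]]), det_seq([[]]))
        assert out.ap == 1.0 and out.degenerate

    def test_no_detections_zero_ap(self):
        out = bt.compute_ap(gt_seq([[rect_gt(0, 1, 10, 10, 20, 20)]]), det_seq([[]]))
        assert out.ap == 0.0 and out.counts.fn == 1

    def test_invariant_to_frame_order_and_score_scale(self):
        rng = np.random.default_rng(9)
        frames_gt, frames_det = [], []
        for f in range(4):
            frames_gt.append([rect_gt(f, k + 1, 10 + 60 * k, 10, 20, 20)
                              for k in range(4)])
            dets = []
            for k in range(4):
                if rng.random() < 0.8:
                    dets.append(rect_det(f, 10 + 60 * k + rng.uniform(-3, 3), 10,
                                         20, 20, rng.uniform(0.3, 0.99)))
            frames_det.append(dets)
        gt, dets = gt_seq(frames_gt), det_seq(frames_det)
        base = bt.compute_ap(gt, dets).ap

        perm = [2, 0, 3, 1]

        def renum(obj, f):
            import copy
            o = copy.copy(obj)
            o.frame_index = f
            return o

        gt_p = gt_seq([[renum(o, i) for o in frames_gt[p]] for i, p in enumerate(perm)])
        det_p = det_seq([[renum(o, i) for o in frames_det[p]] for i, p in enumerate(perm)])
        assert bt.compute_ap(gt_p, det_p).ap == pytest.approx(base, abs=1e-12)

        det_sq = det_seq([[bt.Detection(d.frame_index, d.bbox, d.mask, d.score ** 2)
                           for d in f] for f in frames_det])
        assert bt.compute_ap(gt, det_sq).ap == pytest.approx(base, abs=1e-12)

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bt.compute_ap(gt_seq([[]]), det_seq([[], []]))


class TestClearMot:
    def test_relabeled_ground_truth_is_perfect(self):
        frames_gt, frames_res = [], []
        for f in range(5):
            frames_gt.append([rect_gt(f, k + 1, 10 + 50 * k + f, 10, 20, 20)
                              for k in range(3)])
            frames_res.append([rect_tracked(f, 100 - k, 10 + 50 * k + f, 10, 20, 20)
                               for k in range(3)])
        rep = bt.clear_mot(gt_seq(frames_gt), res_seq(frames_res))
        assert rep.mota == pytest.approx(100.0)
        assert rep.motp == pytest.approx(100.0)
        assert rep.idsw == 0

    def test_hand_counted_single_frame(self):
        """10 GT, 8 matched, 2 missed, 1 false positive."""
        gt_objs = [rect_gt(0, k + 1, 10 + 50 * k, 10, 20, 20) for k in range(10)]
        res_objs = [rect_tracked(0, k + 1, 10 + 50 * k, 10, 20, 20) for k in range(8)]
        res_objs.append(rect_tracked(0, 99, 10, 400, 20, 20))
        rep = bt.clear_mot(gt_seq([gt_objs], size=(1000, 480)),
                           res_seq([res_objs], size=(1000, 480)))
        assert rep.mota == pytest.approx(70.0)
        assert rep.recall == pytest.approx(80.0)
        assert (rep.fn, rep.fp, rep.idsw) == (2, 1, 0)

    def test_identity_switch_counted_once(self):
        frames_gt = [[rect_gt(f, 1, 10 + f, 10, 20, 20)] for f in range(10)]
        frames_res = [[rect_tracked(f, 7 if f < 5 else 8, 10 + f, 10, 20, 20)]
                      for f in range(10)]
        rep = bt.clear_mot(gt_seq(frames_gt), res_seq(frames_res))
        assert rep.idsw == 1
        assert rep.recall == pytest.approx(100.0)

    def test_switch_across_gap_detected(self):
        frames_gt = [[rect_gt(f, 1, 10, 10, 20, 20)] for f in range(5)]
        frames_res = [[rect_tracked(0, 7, 10, 10, 20, 20)], [], [],
                      [rect_tracked(3, 8, 10, 10, 20, 20)],
                      [rect_tracked(4, 8, 10, 10, 20, 20)]]
        rep = bt.clear_mot(gt_seq(frames_gt), res_seq(frames_res))
        assert rep.idsw == 1 and rep.fn == 2

    def test_frame_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bt.clear_mot(gt_seq([[]]), res_seq([[], []]))


class TestMots:
    def test_result_equal_to_ground_truth(self):
        frames_gt = [[rect_gt(f, k + 1, 10 + 50 * k, 10 + f, 20, 12) for k in range(4)]
                     for f in range(3)]
        frames_res = [[rect_tracked(f, k + 11, 10 + 50 * k, 10 + f, 20, 12)
                       for k in range(4)] for f in range(3)]
        rep = bt.mots_eval(gt_seq(frames_gt), res_seq(frames_res))
        assert rep.motsa == pytest.approx(100.0)
        assert rep.motsp == pytest.approx(100.0)
        assert rep.recall == pytest.approx(100.0)

    def test_motsp_is_mean_tp_iou(self):
        """Result masks fully inside their GT with 80 of 100 pixels ->
        every TP IoU is exactly 0.8, so MOTSP = 80."""
        frames_gt = [[rect_gt(0, k + 1, 50 * k, 0, 10, 10) for k in range(5)]]
        frames_res = [[rect_tracked(0, k + 1, 50 * k, 1, 10, 8) for k in range(5)]]
        rep = bt.mots_eval(gt_seq(frames_gt), res_seq(frames_res))
        assert rep.tp == 5
        assert rep.motsp == pytest.approx(80.0)

    def test_hand_counted_motsa(self):
        """10 GT over two frames: 9 TP, 1 FP, 1 identity switch -> 70%."""
        f0_gt = [rect_gt(0, k + 1, 50 * k, 0, 10, 10) for k in range(5)]
        f1_gt = [rect_gt(1, k + 1, 50 * k, 2, 10, 10) for k in range(5)]
        f0_res = [rect_tracked(0, k + 1, 50 * k, 0, 10, 10) for k in range(5)]
        # frame 1: gt 1..4 tracked, gt 1 by a *new* id (switch), gt 5 missed,
        # plus one spurious mask far away
        f1_res = [rect_tracked(1, 99, 0, 2, 10, 10)] + \
                 [rect_tracked(1, k + 1, 50 * k, 2, 10, 10) for k in range(1, 4)] + \
                 [rect_tracked(1, 50, 300, 200, 10, 10)]
        rep = bt.mots_eval(gt_seq([f0_gt, f1_gt]), res_seq([f0_res, f1_res]))
        assert (rep.tp, rep.fp, rep.ids, rep.fn) == (9, 1, 1, 1)
        assert rep.motsa == pytest.approx(70.0)

    def test_strict_threshold_excludes_exact_half(self):
        # IoU exactly 0.5: 10x10 GT vs 10x10 shifted so overlap/union = 0.5
        # (shift 10/3 not integer; use 5x10 inside 10x10 -> IoU 0.5)
        frames_gt = [[rect_gt(0, 1, 0, 0, 10, 10)]]
        frames_res = [[rect_tracked(0, 1, 0, 0, 5, 10)]]
        rep = bt.mots_eval(gt_seq(frames_gt), res_seq(frames_res))
        assert rep.tp == 0  # 0.5 is not > 0.5
        out = bt.compute_ap(gt_seq(frames_gt),
                            det_seq([[rect_det(0, 0, 0, 5, 10, 0.9)]]))
        assert out.counts.tp == 1  # mAP boundary is inclusive

    def test_overlapping_result_masks_rejected_with_pairs(self):
        frames_gt = [[rect_gt(0, 1, 0, 0, 10, 10)]]
        frames_res = [[rect_tracked(0, 1, 0, 0, 10, 10),
                       rect_tracked(0, 2, 5, 0, 10, 10)]]
        with pytest.raises(MaskOverlapError) as err:
            bt.mots_eval(gt_seq(frames_gt), res_seq(frames_res))
        assert err.value.pairs == [(0, 1, 2)]

    def test_overlap_resolution_prefers_lower_id(self):
        frames_gt = [[rect_gt(0, 1, 0, 0, 10, 10)]]
        frames_res = [[rect_tracked(0, 2, 5, 0, 10, 10),
                       rect_tracked(0, 1, 0, 0, 10, 10)]]
        rep = bt.mots_eval(gt_seq(frames_gt), res_seq(frames_res), overlap="resolve")
        # id 1 keeps its full mask -> IoU 1.0 with the GT; id 2 loses the
        # disputed half and becomes a false positive
        assert rep.tp == 1 and rep.fp == 1
        assert rep.motsp == pytest.approx(100.0)

    def test_counts_agree_with_clear_mot_on_box_masks(self):
        rng = np.random.default_rng(17)
        frames_gt, frames_res = [], []
        for f in range(6):
            gt_f, res_f = [], []
            for k in range(5):
                x = 70 * k + rng.integers(0, 4)
                gt_f.append(rect_gt(f, k + 1, x, 10, 20, 20))
                if rng.random() < 0.8:
                    res_f.append(rect_tracked(f, k + 1, x + rng.integers(0, 3),
                                              10, 20, 20))
            frames_gt.append(gt_f)
            frames_res.append(res_f)
        gt, res = gt_seq(frames_gt), res_seq(frames_res)
        cm = bt.clear_mot(gt, res)
        ms = bt.mots_eval(gt, res)
        assert (cm.n_matches, cm.fp, cm.fn, cm.idsw) == (ms.tp, ms.fp, ms.fn, ms.ids)
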