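"""Association optimality, gating, and track lifecycle management."""

import itertools

import numpy as np
import pytest

import beetrack as bt
from beetrack.tracking import BeeTracker, solve_iou_assignment, tracker_step

from conftest import rect_det


def brute_force_best_total(iou, iou_min):
    """Exhaustive-permutation oracle for the gated assignment total."""
    n, m = iou.shape
    best = 0.0
    k = min(n, m)
    rows = list(range(n))
    for r_sel in itertools.combinations(rows, k):
        for c_sel in itertools.permutations(range(m), k):
            total = sum(iou[r, c] for r, c in zip(r_sel, c_sel) if iou[r, c] >= iou_min)
            best = max(best, total)
    return best


class TestAssignment:
    def test_prefers_global_optimum(self):
        iou = np.array([[0.6, 0.2], [0.1, 0.7]])
        matches, ud, ut = solve_iou_assignment(iou, 0.1)
        assert set(matches) == {(0, 0), (1, 1)}
        assert ud == [] and ut == []

    def test_gate_demotes_low_iou_pairs(self):
        matches, ud, ut = solve_iou_assignment(np.array([[0.4]]), 0.5)
        assert matches == [] and ud == [0] and ut == [0]

    def test_empty_inputs(self):
        matches, ud, ut = solve_iou_assignment(np.zeros((0, 3)), 0.5)
        assert matches == [] and ud == [] and ut == [0, 1, 2]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n, m = (int(v) for v in rng.integers(1, 6, size=2))
            iou = rng.random((n, m))
            matches, _, _ = solve_iou_assignment(iou, 1e-9)
            total = sum(iou[r, c] for r, c in matches)
            assert total == pytest.approx(brute_force_best_total(iou, 0.0), abs=1e-9)

    def test_gating_never_emits_low_iou_matches(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            iou = rng.random((4, 5))
            matches, _, _ = solve_iou_assignment(iou, 0.5)
            assert all(iou[r, c] >= 0.5 for r, c in matches)

    def test_associate_on_boxes(self):
        # t0 at x=0, detection shifted 2.5 px -> IoU 0.6; t1 far away with a
        # detection shifted to IoU 0.7; optimum keeps the diagonal pairing
        cfg = bt.TrackerConfig()
        trk = BeeTracker(cfg)
        trk.step([rect_det(0, 0, 0, 10, 10), rect_det(0, 100, 0, 10, 10)], 0)
        for t in trk.tracks:
            t.predicted_bbox = bt.bbox_from_state(t.state)
        dets = [rect_det(1, 2.5, 0, 10, 10), rect_det(1, 100 + 30 / 17, 0, 10, 10)]
        matches, ud, ut = bt.associate(dets, trk.tracks, 0.5)
        assert set(matches) == {(0, 0), (1, 1)}


class TestLifecycle:
    def test_overlapping_detection_matches_without_new_track(self):
        trk = BeeTracker(bt.TrackerConfig())
        trk.step([rect_det(0, 50, 50, 20, 20)], 0)
        outs = trk.step([rect_det(1, 51, 50, 20, 20)], 1)
        assert [o.track_id for o in outs] == [1]
        assert len(trk.tracks) == 1

    def test_lost_track_deleted_and_reappearance_is_new_id(self):
        cfg = bt.TrackerConfig(t_lost=1)
        trk = BeeTracker(cfg)
        trk.step([rect_det(0, 50, 50, 20, 20)], 0)
        for f in range(1, 3):  # absent for t_lost + 1 frames
            trk.step([], f)
        assert trk.tracks == []
        outs = trk.step([rect_det(3, 50, 50, 20, 20)], 3)
        assert [o.track_id for o in outs] == [2]

    def test_coasting_track_survives_within_t_lost(self):
        cfg = bt.TrackerConfig(t_lost=2)
        trk = BeeTracker(cfg)
        trk.step([rect_det(0, 50, 50, 20, 20)], 0)
        trk.step([], 1)
        trk.step([], 2)
        outs = trk.step([rect_det(3, 50, 50, 20, 20)], 3)
        assert [o.track_id for o in outs] == [1]  # same identity kept

    def test_three_detections_open_three_tracks(self):
        tracks, outs, next_id = tracker_step(
            [], [rect_det(0, 0, 0, 10, 10), rect_det(0, 50, 0, 10, 10),
                 rect_det(0, 100, 0, 10, 10)],
            bt.TrackerConfig(), next_id=1)
        assert sorted(o.track_id for o in outs) == [1, 2, 3]
        assert next_id == 4

    def test_coasting_frames_produce_no_output(self):
        trk = BeeTracker(bt.TrackerConfig(t_lost=3))
        trk.step([rect_det(0, 50, 50, 20, 20)], 0)
        assert trk.step([], 1) == []

    def test_min_hits_warmup(self):
        cfg = bt.TrackerConfig(min_hits=3)
        trk = BeeTracker(cfg)
        # warm-up: first frames still report (age < min_hits)
        assert len(trk.step([rect_det(0, 50, 50, 20, 20)], 0)) == 1
        # a later-born track stays silent until it accumulates min_hits
        trk.step([rect_det(1, 51, 50, 20, 20)], 1)
        trk.step([rect_det(2, 52, 50, 20, 20)], 2)
        outs = trk.step([rect_det(3, 53, 50, 20, 20),
                         rect_det(3, 300, 300, 20, 20)], 3)
        assert [o.track_id for o in outs] == [1]


class TestRunTracker:
    def test_empty_sequence(self):
        seq = bt.DetSequence(10, 640, 480, [[], [], []])
        res = bt.run_tracker(seq)
        assert res.n_objects == 0 and res.n_frames == 3

    def test_deterministic(self, separated_scene, perfect_detections):
        r1 = bt.run_tracker(perfect_detections)
        r2 = bt.run_tracker(perfect_detections)
        for f1, f2 in zip(r1.frames, r2.frames):
            assert [(o.track_id, tuple(o.bbox.as_array())) for o in f1] == \
                   [(o.track_id, tuple(o.bbox.as_array())) for o in f2]

    def test_perfect_separated_agents_keep_identity(self, separated_scene,
                                                    perfect_detections):
        cfg, gt, _agents, _paths = separated_scene
        res = bt.run_tracker(perfect_detections)
        assert len(res.track_ids()) == cfg.n_agents
        spans = {tid: 0 for tid in res.track_ids()}
        for frame in res.frames:
            for o in frame:
                spans[o.track_id] += 1
        assert all(n == gt.n_frames for n in spans.values())

    def test_id_conservation(self):
        """ids ever created == detections that failed to match an existing track."""
        rng = np.random.default_rng(5)
        frames = []
        for f in range(20):
            frame = []
            for k in range(3):
                if rng.random() < 0.7:
                    frame.append(rect_det(f, 100 * k + rng.uniform(-1, 1),
                                          50 + rng.uniform(-1, 1), 20, 20))
            frames.append(frame)
        seq = bt.DetSequence(10, 640, 480, frames)
        cfg = bt.TrackerConfig(t_lost=1)
        trk = BeeTracker(cfg, frame_size=seq.frame_size)
        unmatched_seen = 0
        for f, frame in enumerate(seq.frames):
            before = {t.track_id for t in trk.tracks}
            trk.step(frame, f)
            after = {t.track_id for t in trk.tracks}
            unmatched_seen += len(after - before)
        assert trk.n_created == unmatched_seen
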