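import pytest

import beetrack as bt


@pytest.fixture(scope="session")
def separated_scene():
    """20 well-separated agents, 10 fps x 10 s; each agent confined to its
    own grid cell so identities are recoverable by construction."""
    cfg = bt.SceneConfig(n_agents=20, fps=10, duration=10, well_separated=True, seed=3)
    gt, agents, paths = bt.simulate_scene(cfg, return_agents=True)
    return cfg, gt, agents, paths


@pytest.fixture(scope="session")
def perfect_detections(separated_scene):
    """Ground truth of the separated scene re-issued as uncorrupted detections."""
    _cfg, gt, _agents, _paths = separated_scene
    return bt.corrupt_detections(gt, bt.CorruptionConfig(seed=0))


def rect_det(frame, x, y, w, h, score=1.0):
    box = bt.BBox(x, y, w, h)
    return bt.Detection(frame, box, bt.rect_mask(box), score)


def rect_gt(frame, inst, x, y, w, h):
    box = bt.BBox(x, y, w, h)
    return bt.GTInstance(frame, inst, box, bt.rect_mask(box))


def rect_tracked(frame, tid, x, y, w, h, score=1.0):
    box = bt.BBox(x, y, w, h)
    return bt.TrackedInstance(frame, tid, box, bt.rect_mask(box), score)


@pytest.fixture
def rect_builders():
    return rect_det, rect_gt, rect_tracked
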