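# Methods

## Coordinate and rasterization conventions

All coordinates are 0-based pixels, origin top-left. A box `(x, y, w, h)`
covers the half-open region `[x, x+w) × [y, y+h)`, so box area is exactly
`w·h` and abutting boxes do not intersect. A mask is a set of polygon
rings; pixel `(i, j)` belongs to the mask iff its center `(i+0.5, j+0.5)`
is inside under the even-odd rule evaluated over all rings together. This
rule decides every boundary pixel deterministically and makes the discrete
mask of an integer-aligned rectangle agree exactly with the box above —
which is what lets `mask_iou` and `bbox_iou` be cross-checked against each
other on rectangular masks. Mask IoU is computed on the rasterized pixel
sets (not on polygon areas), matching how segmentation benchmarks count.

Letterboxing to the square model resolution pads with zeros at the
bottom/right by default (`pad_top = pad_left = 0` for landscape frames),
so original coordinates are unchanged before the single scale factor
`model_size / max(src_w, src_h)`; the pad fields are stored so a centered
convention is equally expressible, and the transform round-trips to
within 1e-6 px.

## Tracking core

The motion model is a linear constant-velocity filter over
`(u, v, s, r, u̇, v̇, ṡ)` — box center, area, aspect ratio, and their
velocities (aspect ratio carries no velocity). The observation picks
`(u, v, s, r)` from the matched detection's box. Noise covariances follow
the convention of the simple-online-realtime-tracking family, which this
design deliberately mirrors: measurement variances (1, 1, 10, 10),
initial variances (10, 10, 10, 10) on observed components and 1e4 on
velocities, process noise (1, 1, 1, 1, 0.01, 0.01, 1e-4). All are exposed
in `KalmanParams`. Updates use the Joseph-form covariance recursion and
symmetrization, keeping `P` positive semidefinite through long runs
(property-tested). If a predicted area would become non-positive, the area
velocity is clamped to zero before the transition.

Association maximizes total box IoU via `scipy.optimize.linear_sum_assignment`
on cost `1 − IoU`; assigned pairs below `iou_min` are demoted to unmatched
on both sides. The gate defaults to 0.5. Among equal-cost optima the
solver's deterministic choice is accepted as the tie-break; the assignment
total is verified against an exhaustive-permutation oracle. A mask-IoU
association mode exists for experiments but the default is box IoU — it
is faster and the masks ride along with the matched detections anyway.

Lifecycle: every unmatched detection opens a track; a track undetected
for more than `t_lost` frames (default 1) is deleted, and a reappearing
object becomes a new identity — identities are never reused. Output rows
are emitted only for tracks matched in the current frame, once a track has
`min_hits` matches (default 1) or during the sequence's first `min_hits`
frames. Coasting (predicted-but-unmatched) tracks emit nothing, because a
reported mask must originate from a detection.

## Evaluation

* **AP / mAP** — detections ranked by score, greedily matched to the
  best-IoU unmatched ground truth in their frame at IoU ≥ 0.5
  (inclusive boundary). AP integrates the precision envelope over the
  exact recall step curve (all-point interpolation); an 11-point option is
  available. With one class, mAP = AP. The empty-vs-empty case is
  reported as AP 1.0 with a `degenerate` flag; ground truth with no
  detections is AP 0.
* **CLEAR MOT** — per frame, correspondences carried over from the
  previous frame survive while their box IoU stays ≥ `iou_min`; the
  remainder is matched by the Hungarian assignment. An identity switch is
  counted when a ground-truth object's matched id differs from its last
  known match, gaps included. `MOTA = 100·(1 − (FN+FP+IDSW)/GT)`. MOTP is
  reported as mean matched IoU × 100 — the benchmark-server convention in
  which 100 is perfect localization — rather than as a distance error.
* **MOTS** — mask-level counts under the strict `IoU > 0.5` rule, which
  guarantees a unique per-frame matching when result masks are pairwise
  disjoint. Overlapping result masks are a validation error by default;
  `overlap="resolve"` instead awards each disputed pixel to the lowest
  track id, which is needed when evaluating tracker output built from
  jittered (hence occasionally overlapping) detection masks. `MOTSA =
  100·(TP − FP − IDS)/GT`, `MOTSP = 100·(Σ IoU)/TP`, and soft sMOTSA is
  reported as an extra field. Recall is `100·TP/GT` for both MOT and MOTS.

The two evaluators agree count-for-count when every mask is its own
bounding box and no IoU sits exactly on the (differing) 0.5 boundary;
this cross-consistency is part of the test suite.

## Synthetic scenes

The generator reproduces the statistical structure the tracker faces, not
hive imagery. Defaults mirror the reference recording conditions: a
1920 × 1080 frame, ≈370 agents, 10 s duration, 30 fps capture thinned to
5/10/15 fps by frame dropping (never interpolation). Each agent is an
oriented ellipse with half-axes 33 × 12 px — a ~14 mm bee on a ~0.21 mm/px
field of view. Agents split into *active* walkers (per-agent base speed
drawn from N(1.6, 0.6²) px/frame, floored at 0.4, with a heading random
walk of sd 0.06 rad/frame — roughly 1 cm/s and 1 rad/s at 30 fps) and
*inactive* resters (home-anchored jitter, sd 0.05 px clamped to ±1 px, no
rotation). These motion constants are order-of-magnitude choices, not
calibrated measurements; the tracker's feasibility boundary is the
inter-frame box IoU they induce, and at these settings a thin ellipse's
rotation keeps consecutive-frame IoU well above the 0.5 gate at every
supported frame rate.

Boundaries reflect (position and heading component flip), so identities
persist for whole sequences. The `well_separated` layout instead confines
each agent to its own grid cell, guaranteeing zero occlusion forever —
this is the construction behind the perfect-recovery tests, where the
pipeline must return MOTA = MOTSA = 100 % exactly.

Annotation mimics the labeling rule of keeping only bodies more than 80 %
visible: an agent whose body is less than `visibility_min` (default 0.8)
visible — after clipping to the frame and subtracting agents above it in
depth order (later index occludes earlier) — is omitted from that frame's
ground truth. Annotated masks are the full (frame-clipped) bodies, the way
a human annotator estimates an occluded body, so two annotated masks can
overlap by at most the hidden fraction of a body (asserted in tests).

Detector corruption applies, per object: an independent miss with
probability `miss_rate`; center jitter N(0, jitter_sd²) applied to box and
mask together; an optional signed morphological offset (shapely buffer) of
sd `mask_erode_dilate` px; and a confidence score N(score_mean,
score_sd²) clipped to [0, 1] (defaults 0.9 ± 0.05, so the 0.7 acceptance
threshold passes nearly all true detections). Spurious detections arrive
as Poisson(`fp_rate`) random ellipses per frame shaped like the median
annotated body. Random draws are consumed at fixed positions per object,
so with a fixed seed the set of missed objects at a lower miss rate is a
subset of those missed at a higher rate — detection recall then degrades
monotonically in `miss_rate` by construction, which is what the
degradation test asserts.

The generator does not emulate: appearance (no pixels), comb background,
bees entering/leaving the field of view (reflecting walls), body flexing
(rigid ellipse; the three-lobed posture of real bees is not modeled), or
correlated detector failures in crowded regions (misses are independent).
Passing tests therefore demonstrate the correctness of the tracking and
scoring machinery under the stated motion/noise model — not detector
quality or tracking accuracy on real hive video.

## Problem sizes and numerical choices

The stress configuration used by the acceptance script and the heaviest
test is the full-density scene: 370 agents at 1920 × 1080, 30 fps × 10 s
(300 frames) thinned to 100 frames at 10 fps, corrupted at miss 0.05,
jitter 1 px, 0.5 false positives/frame. It runs end to end (simulate →
corrupt → track → evaluate) in about two minutes on one CPU. The 70 %
MOTA floor asserted there is a designed regression floor for this
synthetic setting, not an empirical claim about hive video. Unit-level
scenes use 5–60 agents at reduced frame sizes.

Tolerances: letterbox round-trips at 1e-6 px; covariance PSD checked at
eigenvalue ≥ −1e-9; metric identities (MOTA 70 %, AP 1.0, …) asserted
exactly up to floating-point epsilon since their inputs are constructed
integer-pixel cases. Scores tie-break by input order; detection ranking is
invariant to monotone score transforms. Frame-rate thinning requires an
integer rate ratio and refuses anything else.

## Known limitations

* MOTP/MOTSP follow the IoU-percent convention; tools that define MOTP as
  a distance error will not match numerically.
* The CLEAR MOT evaluator matches on box IoU and MOTS on mask IoU; with
  heavily overlapping bodies the two can legitimately disagree.
* Track association uses geometry only (no appearance), so two bodies
  crossing at high speed can swap identities — the known failure mode of
  the underlying online-tracking design.
* Compressed RLE segmentations are not parsed (uncompressed RLE and
  polygons are).
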