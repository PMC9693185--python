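# Methods

This note records the models behind `skelsuite`, the conventions and
numerical choices that are not forced by the mathematics, and what the
synthetic studies do and do not demonstrate.

## Data model and conventions

A pose sequence is a `T × J × D` array (`D` ∈ {2, 3}) with a `T × J`
visibility mask. Invisible joints are stored as NaN on disk; in memory
the mask is authoritative and every operation consults it (smoothing, for
example, fills hidden entries with model predictions while leaving them
flagged hidden). 3D pose coordinates are right-handed with y up; 2D box
coordinates follow the image convention, y down. Track files use the
MOTChallenge CSV dialect with 1-based frames; frames stay 1-based
throughout the tracking code, so no index conversion can be forgotten.

The default skeleton is the common 18-keypoint layout (nose, neck, eyes,
ears, shoulders, elbows, wrists, hips, knees, ankles) arranged as a
kinematic tree rooted at the neck. Whole-body metrics default to the
13-joint `eval13` subset — nose plus the 12 major limb joints — since
eyes/ears carry little postural information and the neck is the tree
root. Both are overridable via a YAML skeleton config.

## Standardization

**h-norm.** The subject's height in a frame is the distance from the
nose to whichever visible foot is farther from it. The frame maximizing
this height is the "stretched" frame; the whole sequence is multiplied
by the single scale that makes that height exactly 1. A single global
scale — rather than per-frame scaling — preserves within-sequence motion
amplitude: a crouching frame stays smaller than a standing one.

**Procrustes alignment.** The similarity transform (R, s, t) minimizing
Σ‖s·R·xᵢ + t − yᵢ‖² over jointly visible joints is computed in closed
form from the SVD of the centred cross-covariance. Reflections are
excluded by default (det R = +1): allowing them would let the evaluator
silently "repair" a left/right side-swapped pose, which is precisely a
failure mode the metrics should expose. A flag restores the classical
full-Procrustes behaviour. PA- metrics align per frame on the evaluation
subset, because the scores they feed are frame-wise aggregates.

**Retargeting.** Walking the kinematic tree from the root (whose
position is preserved, keeping the global trajectory), each child joint
is placed at its parent's already-retargeted position plus the *input*
bone's unit direction times the *target* bone length. Every output bone
length equals the target exactly, and every joint angle (cosine between
adjacent bones) is preserved. A bone with an invisible endpoint is
skipped and its whole subtree marked invisible — no direction
information exists for it. When comparing prediction against ground
truth, the default target lengths are the ground-truth sequence's mean
bone lengths, recomputed per evaluation run; any fixed skeleton can be
supplied instead.

## Kalman smoothing (KSM)

Each keypoint's coordinate series is smoothed independently per axis
with a Kalman filter followed by an RTS backward pass. The default state
model is constant-velocity (position + velocity per axis) with a
discretized white-noise-acceleration process covariance: human keypoints
have strong velocity continuity, and a position-only model (or a causal
filter alone, available via `mode="filter"`) visibly lags fast motions
such as a jump shot. Defaults q = 1e-3, r = 1e-2 are expressed in
h-normalized units (person height = 1) and encode that detector jitter
(~0.1 of height std) is large against true inter-frame acceleration; the
smoothing-benefit study below is the empirical check that this operating
point helps across noise levels. Initial state: first observed value,
zero velocity, covariance p0·I with p0 = 1. Missing samples get the time
update only; the backward pass then interpolates through gaps.

Two exact invariances are tested: shift equivariance, and scale
equivariance when q, r, p0 are scaled by c².

## Pose metrics

All threshold metrics use the strict inequality d < factor · reference.
PCK on h-normalized poses uses the unit person height as reference — the
only scale that is 1 by construction there — so PA-PCK@0.15 reads
"fraction of joints within 15% of body height after alignment". PCKh
defaults to the ground-truth head-to-neck distance as head height
(configurable to a supplied head-box height); PDJ uses the diagonal of
the min/max box of the visible ground-truth joints. PCP is limb-wise by
default (a limb scored by the mean of its two endpoint errors against
half its ground-truth length), with a per-keypoint mode available, since
both readings exist in the literature. AP/AR over OKS use the COCO-style
threshold grid 0.50:0.05:0.95 and report the *mean* of per-threshold
precision/recall — a bare sum would be unbounded. Joints invisible in
either sequence are excluded from the denominator rather than scored as
failures.

The pipeline evaluator (`evaluate_pose_run`) height-normalizes both
sequences, then reports PA-PCK@τ and PA-MPJPE in three columns: base,
+KSM (prediction smoothed), +KSM+RET (both sequences additionally
retargeted onto the ground truth's mean bone lengths).

## Tracking metrics

Frame-level matching follows the CLEAR convention: IoU threshold 0.5,
previous-frame match persistence (a surviving pair is never re-opened
for competition), then Hungarian assignment on cost 1 − IoU among the
rest. Identity switches are counted against each ground-truth identity's
*most recent* previous match: a gap re-acquired with the same id costs
nothing; a changed id after a gap costs one. MOTP is reported as mean
matched-box IoU (higher is better). Recall and Precision are
detection-level (matched pairs over total GT / total hypothesis boxes).
IDF1 uses an exhaustively-tested optimal global id-to-id assignment
(Hungarian on the per-pair overlap-frame counts). MT/ML boundaries are
inclusive: coverage ≥ 0.8 is mostly-tracked, ≤ 0.2 mostly-lost.

`aggregate_reports` averages rows across datasets (unweighted macro
mean) and *truncates toward zero* at the printed precision — 2 decimals
for percentage metrics, 3 for MOTP, integers for IDsw/MT/ML — because
that is how the bundled cross-dataset summary table was evidently
produced (e.g. an IDF1 mean of 20.525 prints as 20.52, an IDsw mean of
2772.75 as 2772). A handful of published summary cells are inconsistent
with *any* simple averaging rule and are treated as transcription
errors; tests assert only the self-consistent cells.

## Baseline tracker

State per track: (cx, cy, vx, vy, w, h) — constant-velocity center,
static size. The assignment cost is ‖Δcenter‖ + λ(|Δw| + |Δh|) with
λ = 0.5, gate 100 px, detection-confidence threshold 0.4, max_age 3,
min_hits 1, q = 1e-2, r = 1 (pixel units). These gates are engineering
defaults fixed for reproducibility, not tuned values; all are exposed in
`TrackerConfig`. Assignment ties break deterministically by (track id,
detection order). Retired ids are never reused.

## Synthetic data

The pose generator animates unit bone directions with per-bone
sinusoidal angle trajectories (random orthogonal swing axes and phases,
amplitude 0.5 rad at 0.8 Hz for limb bones) over a fixed kinematic tree
with adult bone lengths, plus a ballistic vertical root arc — a smooth,
bone-length-preserving stand-in for a handball jump shot at 200 frames /
30 fps. Corruption reproduces pose-estimator failure modes: isotropic
Gaussian keypoint noise, Bernoulli per-joint occlusions, and whole-frame
left/right swaps. It does **not** emulate structured detector error
(confusion of nearby joints, heatmap quantization, correlated drift), so
passing the smoothing and metric studies shows correctness of the
pipeline and its behaviour under white noise — not performance on real
video.

The tracking generator moves non-overlapping objects on parallel lanes
(pairwise IoU 0 throughout), which makes matching unambiguous, so
planted misses, far-away false positives (placed several box diagonals
from every lane) and scripted persistent id swaps translate into exact
expected FN/FP/IDsw counts; the planted IDsw is derived by applying the
switch-counting rule to the generator's own identity bookkeeping, which
keeps it exact even when misses interact with swaps.

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` use 120–200-frame pose
sequences, 60 smoothing runs (3 noise levels × 20 seeds), 50 tracking
scenario configurations, and 30 small scenarios (≤ 4 identities, ≤ 12
frames) for brute-force oracle comparison — sizes at which the
exhaustive oracles (all per-frame pairings; all id-to-id mappings) are
cheap and the Monte-Carlo checks are stable across seeds.

## Known limitations

- The Procrustes solution assumes a non-degenerate point set; collinear
  configurations fall back to an arbitrary optimal rotation.
- The smoother treats axes independently; correlated noise between axes
  is not modelled.
- `match_frames` persistence is greedy per frame, as in the CLEAR
  protocol; it is not a global (multi-frame) optimum by design.
- The baseline tracker has no appearance model and will swap identities
  of objects that cross at similar sizes and speeds.
- 2D pose support is structural (D = 2 works throughout) but the
  synthetic generator only produces 3D sequences.
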