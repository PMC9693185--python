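"""Synthetic fixtures: articulated pose sequences and tracking scenarios.

Real benchmark recordings (mocap sessions, annotated sports video) are not
redistributable, so every test and example in this toolkit runs on
generated data with known ground truth.

Pose sequences
    A kinematically consistent "truth" is built by animating unit bone
    directions on the default 18-joint skeleton with sinusoidal joint-angle
    trajectories (plus an optional ballistic vertical arc of the root,
    emulating a jump shot); positions are recomputed from the tree with
    fixed bone lengths each frame, so bone lengths are constant by
    construction.  A "corrupted" copy adds the failure modes of per-frame
    pose estimators: isotropic Gaussian keypoint noise, random per-joint
    occlusion dropouts, and whole-frame left/right side swaps.

Tracking scenarios
    Non-overlapping objects move on linear (or gently curved) paths; the
    hypothesis stream is the ground truth with exactly the planted
    corruptions applied — missed boxes, far-away false positives, and
    scripted persistent identity swaps — so the expected FN/FP/IDsw counts
    are known exactly and an evaluator can be checked against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .pose import PoseSequence
from .skeleton import SkeletonDefinition, default_skeleton
from .tracks import BoxRecord, TrackDataset

# rest-pose unit direction of each tree bone (y up, subject facing +z),
# keyed by (parent, child) joint names of the default skeleton
_REST_DIRECTIONS = {
    ("neck", "nose"): (0.0, 1.0, 0.1),
    ("nose", "right_eye"): (-0.3, 0.6, 0.5),
    ("nose", "left_eye"): (0.3, 0.6, 0.5),
    ("right_eye", "right_ear"): (-1.0, 0.0, -0.3),
    ("left_eye", "left_ear"): (1.0, 0.0, -0.3),
    ("neck", "right_shoulder"): (-1.0, 0.0, 0.0),
    ("right_shoulder", "right_elbow"): (-0.3, -1.0, 0.0),
    ("right_elbow", "right_wrist"): (-0.1, -1.0, 0.2),
    ("neck", "left_shoulder"): (1.0, 0.0, 0.0),
    ("left_shoulder", "left_elbow"): (0.3, -1.0, 0.0),
    ("left_elbow", "left_wrist"): (0.1, -1.0, 0.2),
    ("neck", "right_hip"): (-0.35, -1.0, 0.0),
    ("right_hip", "right_knee"): (0.0, -1.0, 0.1),
    ("right_knee", "right_ankle"): (0.0, -1.0, -0.1),
    ("neck", "left_hip"): (0.35, -1.0, 0.0),
    ("left_hip", "left_knee"): (0.0, -1.0, 0.1),
    ("left_knee", "left_ankle"): (0.0, -1.0, -0.1),
}

# bone lengths (meters) for an ~1.8 m adult
_BONE_LENGTH_BY_CHILD = {
    "nose": 0.25, "right_eye": 0.08, "left_eye": 0.08,
    "right_ear": 0.1, "left_ear": 0.1,
    "right_shoulder": 0.2, "left_shoulder": 0.2,
    "right_elbow": 0.3, "left_elbow": 0.3,
    "right_wrist": 0.27, "left_wrist": 0.27,
    "right_hip": 0.55, "left_hip": 0.55,
    "right_knee": 0.45, "left_knee": 0.45,
    "right_ankle": 0.43, "left_ankle": 0.43,
}


@dataclass(frozen=True)
class SyntheticPoseConfig:
    """Controls for the articulated pose generator.

    ``noise_sigma`` is the per-coordinate Gaussian noise (meters) of the
    corrupted copy; ``occlusion_rate`` the per-joint-per-frame dropout
    probability; ``side_swap_frames`` frames whose left/right joints are
    exchanged wholesale (the characteristic pose-estimator side-swap
    failure).  Defaults emulate a short single-person sports clip: 200
    frames at 30 fps of fast periodic whole-body motion with a jump arc.
    """

    n_frames: int = 200
    fps: float = 30.0
    skeleton: SkeletonDefinition = field(default_factory=default_skeleton)
    motion_amplitude: float = 0.5   # radians of joint-angle swing
    motion_frequency: float = 0.8   # Hz
    jump: bool = True               # ballistic vertical arc of the root
    jump_height: float = 0.5        # meters
    noise_sigma: float = 0.0
    occlusion_rate: float = 0.0
    side_swap_frames: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.occlusion_rate <= 1.0):
            raise ValidationError("occlusion_rate must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValidationError("need at least one frame")


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def gen_pose_sequence(
    cfg: SyntheticPoseConfig,
) -> tuple[PoseSequence, PoseSequence]:
    """Generate (truth, corrupted) pose sequences; seeded and deterministic."""
    skel = cfg.skeleton
    rng = np.random.default_rng(cfg.seed)
    bones = skel.tree_bones()
    names = skel.joint_names
    rest = {}
    lengths = {}
    for p, c in bones:
        key = (names[p], names[c])
        if key not in _REST_DIRECTIONS:
            raise ValidationError(f"no rest direction for bone {key}")
        v = np.asarray(_REST_DIRECTIONS[key], dtype=float)
        rest[(p, c)] = v / np.linalg.norm(v)
        lengths[(p, c)] = _BONE_LENGTH_BY_CHILD[names[c]]

    # one swing axis + phase per bone, fixed for the sequence
    axes = {}
    phases = {}
    for p, c in bones:
        a = rng.normal(size=3)
        # axis orthogonal to the rest direction gives a pendulum-like swing
        a -= a.dot(rest[(p, c)]) * rest[(p, c)]
        n = np.linalg.norm(a)
        axes[(p, c)] = a / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
        phases[(p, c)] = rng.uniform(0, 2 * np.pi)

    # limb bones swing with the full amplitude; head/torso bones barely move
    limb_children = {
        "right_elbow", "right_wrist", "left_elbow", "left_wrist",
        "right_knee", "right_ankle", "left_knee", "left_ankle",
        "right_shoulder", "left_shoulder",
    }

    T = cfg.n_frames
    coords = np.zeros((T, skel.n_joints, 3))
    t_axis = np.arange(T) / cfg.fps
    root = skel.root
    # root trajectory: slow forward drift plus optional ballistic jump
    root_pos = np.zeros((T, 3))
    root_pos[:, 2] = 0.3 * t_axis
    root_pos[:, 1] = 1.3
    if cfg.jump:
        # parabolic arc over the middle half of the clip
        t0, t1 = T // 4, 3 * T // 4
        tj = np.arange(t0, t1)
        u = (tj - t0) / max(t1 - t0 - 1, 1)
        root_pos[tj, 1] += cfg.jump_height * 4.0 * u * (1.0 - u)

    for f in range(T):
        coords[f, root] = root_pos[f]
        for p, c in bones:
            amp = cfg.motion_amplitude if names[c] in limb_children else 0.05
            angle = amp * np.sin(
                2 * np.pi * cfg.motion_frequency * t_axis[f] + phases[(p, c)]
            )
            direction = _rotation(axes[(p, c)], angle) @ rest[(p, c)]
            coords[f, c] = coords[f, p] + lengths[(p, c)] * direction

    visible = np.ones((T, skel.n_joints), dtype=bool)
    truth = PoseSequence(coords=coords, visible=visible, skeleton=skel,
                         units="meters", fps=cfg.fps)

    corrupted = coords.copy()
    if cfg.noise_sigma > 0:
        corrupted = corrupted + rng.normal(0.0, cfg.noise_sigma, corrupted.shape)
    for f in cfg.side_swap_frames:
        for j, side in enumerate(skel.side_of):
            if side != "left":
                continue
            partner = _side_partner(skel, j)
            corrupted[f, [j, partner]] = corrupted[f, [partner, j]]
    vis_c = visible.copy()
    if cfg.occlusion_rate > 0:
        vis_c &= rng.random((T, skel.n_joints)) >= cfg.occlusion_rate
        corrupted = corrupted.copy()
        corrupted[~vis_c] = np.nan
    corrupted_seq = PoseSequence(coords=corrupted, visible=vis_c, skeleton=skel,
                                 units="meters", fps=cfg.fps)
    return truth, corrupted_seq


def _side_partner(skel: SkeletonDefinition, joint: int) -> int:
    """Index of the mirror joint (left_x <-> right_x) by name."""
    name = skel.joint_names[joint]
    if name.startswith("left_"):
        return skel.index_of("right_" + name[5:])
    if name.startswith("right_"):
        return skel.index_of("left_" + name[6:])
    raise ValidationError(f"joint {name!r} has no side partner")


# --------------------------------------------------------------------------
# tracking scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTrackConfig:
    """Controls for the tracking-scenario generator.

    Objects move left-to-right on parallel, well-separated lanes so that
    frame-level matching is unambiguous (pairwise IoU is 0 throughout) and
    every planted corruption maps to exactly one metric count.  Defaults
    emulate a still camera watching a handful of players: 4 objects,
    100 frames, 60×120 px boxes.
    """

    n_objects: int = 4
    n_frames: int = 100
    box_size: tuple[float, float] = (60.0, 120.0)
    lane_gap: float = 400.0        # vertical gap between lanes (px)
    speed: float = 6.0             # px / frame
    curved: bool = False           # gentle sinusoidal lane wobble
    miss_rate: float = 0.0
    fp_rate: float = 0.0
    scripted_swaps: tuple[tuple[int, int, int], ...] = ()  # (frame, id_a, id_b)
    detection_sigma: float = 0.0   # box-corner jitter (px)
    seed: int = 0

    def __post_init__(self):
        for rate in (self.miss_rate, self.fp_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValidationError("rates must be in [0, 1]")
        ids = set(range(1, self.n_objects + 1))
        for frame, a, b in self.scripted_swaps:
            if a not in ids or b not in ids or a == b:
                raise ValidationError(f"swap ({frame}, {a}, {b}) references bad ids")
            if not (1 <= frame <= self.n_frames):
                raise ValidationError(f"swap frame {frame} out of range")


def gen_track_scenario(
    cfg: SyntheticTrackConfig,
) -> tuple[TrackDataset, TrackDataset, dict[str, int]]:
    """Generate (ground truth, hypothesis, planted counts).

    The hypothesis equals the ground truth except for the planted
    corruptions; the returned counts are exact by construction:

    * ``FN`` — boxes deleted by ``miss_rate``;
    * ``FP`` — injected boxes placed several box-diagonals away from every
      lane, so they can never match;
    * ``IDsw`` — computed by applying the most-recent-previous-match
      switch-counting rule to the known identity correspondence.
    """
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.box_size
    gt_records: list[BoxRecord] = []
    for obj in range(1, cfg.n_objects + 1):
        y0 = obj * cfg.lane_gap
        for frame in range(1, cfg.n_frames + 1):
            x = 10.0 + cfg.speed * (frame - 1)
            y = y0 + (30.0 * np.sin(frame / 15.0 + obj) if cfg.curved else 0.0)
            gt_records.append(BoxRecord(frame, obj, x, y, w, h, 1.0))
    gt = TrackDataset(records=gt_records, n_frames=cfg.n_frames, name="gt")

    # persistent id relabeling per frame from the scripted swaps
    mapping = {i: i for i in range(1, cfg.n_objects + 1)}
    frame_maps: dict[int, dict[int, int]] = {}
    swaps_by_frame: dict[int, list[tuple[int, int]]] = {}
    for frame, a, b in cfg.scripted_swaps:
        swaps_by_frame.setdefault(frame, []).append((a, b))
    for frame in range(1, cfg.n_frames + 1):
        for a, b in swaps_by_frame.get(frame, []):
            mapping[a], mapping[b] = mapping[b], mapping[a]
        frame_maps[frame] = dict(mapping)

    hyp_records: list[BoxRecord] = []
    observed: dict[int, list[tuple[int, int]]] = {}  # gt id -> (frame, hyp id)
    fn = 0
    for r in gt_records:
        if rng.random() < cfg.miss_rate:
            fn += 1
            continue
        hid = frame_maps[r.frame][r.track_id]
        jitter = rng.normal(0.0, cfg.detection_sigma, 2) if cfg.detection_sigma else (0, 0)
        hyp_records.append(
            BoxRecord(r.frame, hid, r.left + jitter[0], r.top + jitter[1],
                      w, h, 1.0)
        )
        observed.setdefault(r.track_id, []).append((r.frame, hid))

    fp = 0
    fp_zone = (cfg.n_objects + 3) * cfg.lane_gap  # far below every lane
    next_fp_id = 1000
    for frame in range(1, cfg.n_frames + 1):
        if rng.random() < cfg.fp_rate:
            hyp_records.append(
                BoxRecord(frame, next_fp_id, 10.0 + cfg.speed * frame,
                          fp_zone, w, h, 1.0)
            )
            next_fp_id += 1
            fp += 1

    idsw = 0
    for gid, pairs in observed.items():
        last = None
        for _, hid in sorted(pairs):
            if last is not None and hid != last:
                idsw += 1
            last = hid

    hyp = TrackDataset(records=hyp_records, n_frames=cfg.n_frames, name="hyp")
    planted = {"FN": fn, "FP": fp, "IDsw": idsw,
               "GT": len(gt_records)}
    return gt, hyp, planted
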