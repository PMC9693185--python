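"""Spatial standardization of pose sequences.

Pose estimates from different images, cameras or sensors live at arbitrary
positions and scales.  Before any error metric is meaningful the poses must
be brought into a common frame.  This module provides the four tools used
throughout the toolkit:

* :func:`l2_normalize` — each frame's visible coordinates scaled to unit
  Euclidean norm;
* :func:`root_align` — each frame translated so the hip midpoint sits at
  the origin;
* :func:`h_norm` — one global scale chosen so the subject's height (nose to
  the farther foot) equals 1 in the most "stretched" frame of the sequence;
* :func:`procrustes_align` — least-squares similarity alignment (rotation,
  scale, translation) of one pose onto another, the "PA-" in PA-MPJPE;
* :func:`retarget_pose` / :func:`retarget_sequence` — rebuild a pose on a
  standardized skeleton, keeping each bone's direction but replacing its
  length with the target length.

Reflections are excluded from the Procrustes rotation by default
(det(R) = +1): a reflection would silently repair the left/right side-swap
failure mode that evaluation is supposed to expose.  Pass
``allow_reflection=True`` for the classical full Procrustes solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .pose import PoseSequence
from .skeleton import TargetSkeleton


@dataclass(frozen=True)
class SimilarityTransform:
    """x ↦ scale · rotation @ x + translation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))
        d = R.shape[0]
        if not np.allclose(R.T @ R, np.eye(d), atol=1e-9):
            raise DegenerateInputError("rotation is not orthonormal")
        if self.scale <= 0:
            raise DegenerateInputError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation


def l2_normalize(seq: PoseSequence) -> PoseSequence:
    """Scale each frame so its flattened visible coordinates have norm 1."""
    coords = seq.coords.copy()
    for f in range(seq.n_frames):
        vis = seq.visible[f]
        if not vis.any():
            raise DegenerateInputError(f"frame {f}: all joints invisible")
        norm = np.linalg.norm(coords[f][vis])
        if norm == 0:
            raise DegenerateInputError(f"frame {f}: zero-norm frame")
        coords[f][vis] /= norm
    return seq.with_coords(coords, units="normalized")


def root_align(seq: PoseSequence) -> PoseSequence:
    """Translate each frame so the midpoint of the two hips is the origin."""
    lh = seq.skeleton.special("left_hip")
    rh = seq.skeleton.special("right_hip")
    coords = seq.coords.copy()
    for f in range(seq.n_frames):
        if not (seq.visible[f, lh] and seq.visible[f, rh]):
            raise DegenerateInputError(f"frame {f}: hip joint invisible")
        mid = 0.5 * (coords[f, lh] + coords[f, rh])
        vis = seq.visible[f]
        coords[f][vis] -= mid
    return seq.with_coords(coords)


def frame_heights(seq: PoseSequence) -> np.ndarray:
    """Per-frame nose-to-farther-foot distance (NaN where unavailable)."""
    nose = seq.skeleton.special("nose")
    feet = [seq.skeleton.special("left_foot"), seq.skeleton.special("right_foot")]
    heights = np.full(seq.n_frames, np.nan)
    for f in range(seq.n_frames):
        if not seq.visible[f, nose]:
            continue
        dists = [
            np.linalg.norm(seq.coords[f, nose] - seq.coords[f, foot])
            for foot in feet
            if seq.visible[f, foot]
        ]
        if dists:
            heights[f] = max(dists)
    return heights


def h_norm(seq: PoseSequence) -> tuple[PoseSequence, int, float]:
    """Height-normalize a sequence with one global scale.

    The subject's height in a frame is the distance from the nose to the
    foot farther from it.  The frame with the greatest height is taken as
    the "stretched" frame (the subject fully extended); the whole sequence
    is multiplied by one scale making that height exactly 1, so relative
    motion amplitude within the sequence is preserved.

    Returns ``(normalized sequence, stretched frame index, scale)``.
    """
    heights = frame_heights(seq)
    if np.all(np.isnan(heights)):
        raise DegenerateInputError("no frame with nose and a foot visible")
    stretched = int(np.nanargmax(heights))
    scale = 1.0 / heights[stretched]
    out = seq.with_coords(seq.coords * scale, units="normalized")
    return out, stretched, float(scale)


def procrustes_align(
    source: np.ndarray,
    target: np.ndarray,
    visible: np.ndarray | None = None,
    allow_reflection: bool = False,
) -> tuple[SimilarityTransform, np.ndarray]:
    """Least-squares similarity alignment of one pose frame onto another.

    Finds rotation R (det +1 unless ``allow_reflection``), scale s > 0 and
    translation t minimizing  Σᵢ ‖s·R·sourceᵢ + t − targetᵢ‖²  over the
    jointly visible points, by SVD of the cross-covariance of the centred
    point sets.  Returns the transform and the aligned source (all points
    transformed, including hidden ones).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape:
        raise DegenerateInputError("source and target shapes differ")
    d = src.shape[1]
    if visible is None:
        visible = np.all(np.isfinite(src), axis=1) & np.all(np.isfinite(tgt), axis=1)
    visible = np.asarray(visible, dtype=bool)
    x = src[visible]
    y = tgt[visible]
    if len(x) < d:
        raise DegenerateInputError(
            f"need at least {d} jointly visible joints, have {len(x)}"
        )
    mu_x, mu_y = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mu_x, y - mu_y
    var_x = (xc ** 2).sum() / len(x)
    if var_x < 1e-24:
        raise DegenerateInputError("all source joints coincident")
    cov = yc.T @ xc / len(x)
    U, S, Vt = np.linalg.svd(cov)
    sgn = np.ones(d)
    if not allow_reflection and np.linalg.det(U) * np.linalg.det(Vt) < 0:
        sgn[-1] = -1.0
    R = U @ np.diag(sgn) @ Vt
    scale = float((S * sgn).sum() / var_x)
    if scale <= 0:
        raise DegenerateInputError("degenerate configuration: non-positive scale")
    t = mu_y - scale * R @ mu_x
    transform = SimilarityTransform(rotation=R, scale=scale, translation=t)
    return transform, transform.apply(src)


def _retarget_frame(
    coords: np.ndarray,
    visible: np.ndarray,
    target: TargetSkeleton,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild one frame on the target bone lengths; returns (coords, mask)."""
    skel = target.skeleton
    out = np.full_like(coords, np.nan)
    out_vis = np.zeros_like(visible)
    root = skel.root
    if visible[root]:
        out[root] = coords[root]
        out_vis[root] = True
    for parent, child in skel.tree_bones():
        if not (out_vis[parent] and visible[child]):
            continue  # invisibility propagates down the subtree
        vec = coords[child] - coords[parent]
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            a, b = skel.joint_names[parent], skel.joint_names[child]
            raise DegenerateInputError(f"zero-length bone {a!r}->{b!r}")
        out[child] = out[parent] + target.length_of(parent, child) * vec / norm
        out_vis[child] = True
    return out, out_vis


def retarget_pose(
    coords: np.ndarray,
    target: TargetSkeleton,
    visible: np.ndarray | None = None,
) -> np.ndarray:
    """Retarget a single pose frame (J×D array) onto target bone lengths.

    The root keypoint keeps its input position.  Walking the kinematic tree
    from the root, each child is placed at its parent's (already
    retargeted) position plus the input bone's unit direction times the
    target bone length, so every output bone has exactly the target length
    while all bone directions — and hence joint angles — are preserved.
    """
    coords = np.asarray(coords, dtype=float)
    if visible is None:
        visible = np.all(np.isfinite(coords), axis=1)
    out, _ = _retarget_frame(coords, np.asarray(visible, dtype=bool), target)
    return out


def retarget_sequence(seq: PoseSequence, target: TargetSkeleton) -> PoseSequence:
    """Apply :func:`retarget_pose` to every frame of a sequence."""
    coords = np.empty_like(seq.coords)
    vis = np.zeros_like(seq.visible)
    for f in range(seq.n_frames):
        try:
            coords[f], vis[f] = _retarget_frame(
                seq.coords[f], seq.visible[f], target
            )
        except DegenerateInputError as e:
            raise DegenerateInputError(f"frame {f}: {e}") from e
    return seq.with_coords(coords, visible=vis)


def mean_bone_lengths(seq: PoseSequence) -> np.ndarray:
    """Per-bone mean length over frames where both endpoints are visible."""
    lengths = np.array([seq.bone_lengths(f) for f in range(seq.n_frames)])
    return np.nanmean(lengths, axis=0)


def target_from_sequence(seq: PoseSequence) -> TargetSkeleton:
    """A TargetSkeleton carrying the sequence's mean bone lengths.

    This is the default retargeting target when comparing a predicted
    sequence against ground truth: both are rebuilt on the ground truth's
    mean bone lengths so limb-length errors cannot dominate the metric.
    """
    return TargetSkeleton(skeleton=seq.skeleton, bone_lengths=mean_bone_lengths(seq))
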