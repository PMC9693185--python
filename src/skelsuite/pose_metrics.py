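"""Pose-estimation accuracy metrics.

Given a predicted and a ground-truth sequence, all metrics start from the
per-frame per-joint Euclidean distances d[f, i] and differ only in how they
aggregate them:

* MPJPE — mean per-joint position error: the per-frame mean of d over the
  evaluated joints, averaged over frames.
* PCP / PCKh / PDJ / PCK@τ — the fraction of joints with d strictly below
  a factor times a reference length (limb length, head height, bounding-box
  diagonal, or — on height-normalized poses — the unit person height).
* OKS — object keypoint similarity exp(−d²/(2 s² k²)), averaged per frame;
  AP/AR threshold the per-frame OKS at a set of cut-offs (COCO-style
  0.50:0.05:0.95 by default) and average precision/recall over them.
* PA- variants — the same metrics after per-frame Procrustes alignment of
  the prediction onto the ground truth on the evaluation joint subset.

Joints with either endpoint invisible are excluded from the joint count
rather than scored as failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .pose import PoseSequence
from .skeleton import SkeletonDefinition
from .smoothing import KalmanConfig, smooth_sequence
from .standardize import h_norm, procrustes_align, retarget_sequence, target_from_sequence
from .tracks import MetricReport

COCO_OKS_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.99, 0.05), 2))


@dataclass(frozen=True)
class OKSParams:
    """Scale and per-keypoint fall-off constants for OKS.

    ``s`` is the square root of the subject's segment area; ``k`` holds one
    positive fall-off constant per joint (larger k = more forgiving).
    """

    s: float
    k: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "k", np.asarray(self.k, dtype=float))
        if self.s <= 0:
            raise ValidationError("scale s must be positive")
        if not np.all(self.k > 0):
            raise ValidationError("all k must be positive")


@dataclass
class PoseErrorTable:
    """T×J Euclidean distances with a validity mask."""

    d: np.ndarray
    valid: np.ndarray
    joints: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def joint_distances(
    pred: PoseSequence,
    gt: PoseSequence,
    subset: tuple[int, ...] | str | None = None,
) -> PoseErrorTable:
    """Per-frame per-joint distances between two sequences.

    ``subset`` selects joints by indices or by a named skeleton subset;
    default is all joints.  Entries are valid only where the joint is
    visible in both sequences.
    """
    if pred.coords.shape != gt.coords.shape:
        raise ValidationError(
            f"shape mismatch: pred {pred.coords.shape} vs gt {gt.coords.shape}"
        )
    joints = _resolve_subset(pred.skeleton, subset)
    idx = list(joints)
    diff = pred.coords[:, idx, :] - gt.coords[:, idx, :]
    valid = pred.visible[:, idx] & gt.visible[:, idx]
    d = np.where(valid, np.linalg.norm(np.nan_to_num(diff), axis=2), np.nan)
    return PoseErrorTable(d=d, valid=valid, joints=joints)


def _resolve_subset(
    skeleton: SkeletonDefinition, subset: tuple[int, ...] | str | None
) -> tuple[int, ...]:
    if subset is None:
        return tuple(range(skeleton.n_joints))
    if isinstance(subset, str):
        return skeleton.subset(subset)
    return tuple(subset)


def threshold_accuracy(
    err: PoseErrorTable,
    reference: np.ndarray | float,
    factor: float,
) -> float:
    """Fraction of valid joints with d strictly below factor × reference.

    ``reference`` may be a scalar (e.g. 1.0 for PCK on height-normalized
    poses, or a head height for PCKh) or an array broadcastable against the
    distance table (e.g. per-joint limb lengths for PCP).  The comparison is
    strict (<): a distance exactly at the threshold does not count.
    """
    if err.n_valid == 0:
        raise DegenerateInputError("no valid joint pairs")
    ref = np.broadcast_to(np.asarray(reference, dtype=float), err.d.shape)
    if not np.all(ref[err.valid] > 0):
        raise ValidationError("reference lengths must be positive")
    hits = (err.d < factor * ref) & err.valid
    return float(hits.sum() / err.n_valid)


def oks(err: PoseErrorTable, params: OKSParams) -> np.ndarray:
    """Per-frame object keypoint similarity in (0, 1].

    Per keypoint, exp(−d²/(2 s² k²)); per frame, the mean over valid
    keypoints.
    """
    k = params.k[list(err.joints)] if len(params.k) > err.d.shape[1] else params.k
    if k.shape[0] != err.d.shape[1]:
        raise ValidationError("need one k per evaluated joint")
    per_kp = np.exp(-(err.d ** 2) / (2.0 * params.s ** 2 * k[None, :] ** 2))
    out = np.empty(err.d.shape[0])
    for f in range(err.d.shape[0]):
        v = err.valid[f]
        if not v.any():
            raise DegenerateInputError(f"frame {f}: no valid keypoints")
        out[f] = per_kp[f, v].mean()
    return out


def oks_ap_ar(
    per_frame_oks: np.ndarray,
    thresholds: tuple[float, ...] = COCO_OKS_THRESHOLDS,
    n_unmatched_predictions: int = 0,
) -> tuple[float, float]:
    """Average precision and recall from thresholded per-frame OKS.

    In the single-instance setting each frame's pose is a TP at a threshold
    when its OKS reaches it, otherwise an FN; unmatched spurious predictions
    (no ground truth available) count as FP at every threshold.  AP and AR
    are the means of the per-threshold precision and recall.
    """
    s = np.asarray(per_frame_oks, dtype=float)
    if len(s) == 0 or len(thresholds) == 0:
        raise DegenerateInputError("empty OKS list or threshold set")
    precisions, recalls = [], []
    for thr in thresholds:
        tp = int((s >= thr).sum())
        fn = len(s) - tp
        fp = n_unmatched_predictions
        precisions.append(tp / (tp + fp) if (tp + fp) else 0.0)
        recalls.append(tp / (tp + fn) if (tp + fn) else 0.0)
    return float(np.mean(precisions)), float(np.mean(recalls))


def mpjpe(err: PoseErrorTable) -> float:
    """Mean per-joint position error: per-frame mean, then mean over frames."""
    if err.n_valid == 0:
        raise DegenerateInputError("no valid joint pairs")
    frame_means = []
    for f in range(err.d.shape[0]):
        v = err.valid[f]
        if v.any():
            frame_means.append(err.d[f, v].mean())
    return float(np.mean(frame_means))


def pcp(
    pred: PoseSequence,
    gt: PoseSequence,
    factor: float = 0.5,
    mode: str = "limb",
    subset: tuple[int, ...] | str | None = None,
) -> float:
    """Percentage of correct parts against ground-truth limb lengths.

    ``mode="limb"`` (classical): a limb is correct when the mean of its two
    endpoint errors is below factor × the ground-truth bone length.
    ``mode="keypoint"``: each keypoint is scored against the length of the
    bone connecting it to its parent (the literal per-keypoint reading).
    """
    err = joint_distances(pred, gt, subset)
    jpos = {j: i for i, j in enumerate(err.joints)}
    hits, total = 0, 0
    for a, b in gt.skeleton.bones:
        if a not in jpos or b not in jpos:
            continue
        ia, ib = jpos[a], jpos[b]
        for f in range(err.d.shape[0]):
            if not (err.valid[f, ia] and err.valid[f, ib]):
                continue
            limb = np.linalg.norm(gt.coords[f, b] - gt.coords[f, a])
            if limb <= 0:
                continue
            if mode == "limb":
                total += 1
                hits += int(0.5 * (err.d[f, ia] + err.d[f, ib]) < factor * limb)
            else:
                total += 2
                hits += int(err.d[f, ia] < factor * limb)
                hits += int(err.d[f, ib] < factor * limb)
    if total == 0:
        raise DegenerateInputError("no scorable limbs")
    return hits / total


def pckh(
    pred: PoseSequence,
    gt: PoseSequence,
    factor: float = 0.5,
    head_height: float | None = None,
    subset: tuple[int, ...] | str | None = None,
) -> float:
    """PCK with the head segment as reference length.

    The default head height is the per-frame ground-truth head-to-neck
    distance; pass ``head_height`` to use a supplied head-box height.
    """
    err = joint_distances(pred, gt, subset)
    if head_height is not None:
        return threshold_accuracy(err, head_height, factor)
    head = gt.skeleton.special("head")
    neck = gt.skeleton.special("neck")
    heights = np.linalg.norm(gt.coords[:, head] - gt.coords[:, neck], axis=1)
    ref = np.repeat(heights[:, None], err.d.shape[1], axis=1)
    err.valid &= np.isfinite(ref) & (ref > 0)
    ref = np.where(err.valid, ref, 1.0)
    return threshold_accuracy(err, ref, factor)


def pdj(
    pred: PoseSequence,
    gt: PoseSequence,
    factor: float = 0.05,
    subset: tuple[int, ...] | str | None = None,
) -> float:
    """PCK with the ground-truth bounding-box diagonal as reference.

    The box is the min/max extent of the visible ground-truth joints per
    frame; the diagonal comes from the Pythagorean theorem.
    """
    err = joint_distances(pred, gt, subset)
    T = err.d.shape[0]
    diag = np.empty(T)
    for f in range(T):
        pts = gt.coords[f][gt.visible[f]]
        span = pts.max(axis=0) - pts.min(axis=0)
        diag[f] = np.sqrt((span ** 2).sum())
    ref = np.repeat(diag[:, None], err.d.shape[1], axis=1)
    err.valid &= ref > 0
    ref = np.where(err.valid, ref, 1.0)
    return threshold_accuracy(err, ref, factor)


def pa_align_pair(
    pred: PoseSequence,
    gt: PoseSequence,
    subset: tuple[int, ...] | str | None = None,
) -> PoseSequence:
    """Per-frame Procrustes alignment of pred onto gt on a joint subset."""
    joints = _resolve_subset(pred.skeleton, subset)
    idx = list(joints)
    coords = pred.coords.copy()
    for f in range(pred.n_frames):
        vis = pred.visible[f, idx] & gt.visible[f, idx]
        transform, _ = procrustes_align(
            pred.coords[f][idx], gt.coords[f][idx], visible=vis
        )
        coords[f][pred.visible[f]] = transform.apply(
            pred.coords[f][pred.visible[f]]
        )
    return pred.with_coords(coords)


def pa_metric(
    pred: PoseSequence,
    gt: PoseSequence,
    metric: str = "mpjpe",
    subset: tuple[int, ...] | str | None = None,
    tau: float = 0.15,
) -> float:
    """A metric computed after per-frame Procrustes alignment (PA- prefix).

    ``metric`` is ``"mpjpe"`` or ``"pck"``; for PCK the reference is the
    unit person height of height-normalized poses and ``tau`` the factor
    (PA-PCK@0.15 by default).
    """
    aligned = pa_align_pair(pred, gt, subset)
    err = joint_distances(aligned, gt, subset)
    if metric == "mpjpe":
        return mpjpe(err)
    if metric == "pck":
        return threshold_accuracy(err, 1.0, tau)
    raise ValidationError(f"unknown PA metric {metric!r}")


def evaluate_pose_run(
    pred: PoseSequence,
    gt: PoseSequence,
    subset: str = "eval13",
    tau: float = 0.15,
    ksm: KalmanConfig | None = None,
) -> MetricReport:
    """Full evaluation pipeline with base, +KSM and +KSM+RET columns.

    Both sequences are height-normalized; the base column reports
    PA-PCK@tau (×100) and PA-MPJPE on the evaluation subset.  The +KSM
    column Kalman-smooths the prediction first; the +KSM+RET column
    additionally retargets both sequences onto the ground truth's mean
    bone lengths so limb-length errors are removed from the comparison.
    """
    cfg = ksm or KalmanConfig()
    pred_n, _, _ = h_norm(pred)
    gt_n, _, _ = h_norm(gt)

    def cols(p, g):
        return (
            100.0 * pa_metric(p, g, "pck", subset, tau),
            pa_metric(p, g, "mpjpe", subset),
        )

    base_pck, base_mpjpe = cols(pred_n, gt_n)
    pred_s = smooth_sequence(pred_n, cfg)
    ksm_pck, ksm_mpjpe = cols(pred_s, gt_n)
    target = target_from_sequence(gt_n)
    pred_r = retarget_sequence(pred_s, target)
    gt_r = retarget_sequence(gt_n, target)
    ret_pck, ret_mpjpe = cols(pred_r, gt_r)

    report = MetricReport(
        values={
            "PA-PCK": base_pck,
            "PA-PCK+KSM": ksm_pck,
            "PA-PCK+KSM+RET": ret_pck,
            "PA-MPJPE": base_mpjpe,
            "PA-MPJPE+KSM": ksm_mpjpe,
            "PA-MPJPE+KSM+RET": ret_mpjpe,
        },
        details={"tau": tau, "subset": subset},
    )
    return report
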