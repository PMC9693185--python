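"""Multi-object tracking evaluation: CLEAR metrics, identity metrics, MT/ML.

The evaluation follows the CLEAR-MOT protocol.  Per frame, ground-truth
boxes are put in one-to-one correspondence with hypothesis boxes: matches
surviving from the previous frame are kept while their IoU stays at or
above the threshold (match persistence), then the remaining boxes are
assigned by minimum total cost 1 − IoU (Hungarian algorithm), discarding
pairs below the threshold.  From the per-frame correspondences:

* FN — unmatched ground-truth boxes; FP — unmatched hypothesis boxes;
* IDsw — for each ground-truth identity, +1 whenever its matched hypothesis
  id differs from the id of its most recent previous match (a gap with the
  same id on re-match is not a switch);
* MOTA = 1 − (ΣFN + ΣFP + ΣIDsw) / ΣGT, reported ×100;
* MOTP — the mean IoU overlap over all matches (higher is better);
* MT / ML — identities covered for ≥80% / ≤20% of their lifetime.

IDF1 is computed independently of the frame-level matching: a single
global bipartite assignment between ground-truth identities and hypothesis
identities maximizes the number of correctly identified detections (IDTP);
IDF1 = 2·IDTP / (2·IDTP + IDFP + IDFN), reported ×100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import DegenerateInputError, ValidationError
from .tracks import BoxRecord, MetricReport, TrackDataset

TABLE_COLUMNS = ("MOTA", "MOTP", "IDF1", "IDsw", "Recall", "Precision", "MT", "ML")

#: printed precision per metric used when averaging report rows
_AGG_DECIMALS = {
    "MOTA": 2, "IDF1": 2, "Recall": 2, "Precision": 2,
    "MOTP": 3, "IDsw": 0, "MT": 0, "ML": 0,
}


def iou(a, b) -> float:
    """Intersection-over-union of two (left, top, width, height) boxes."""
    ax, ay, aw, ah = (a.left, a.top, a.width, a.height) if isinstance(a, BoxRecord) else a
    bx, by, bw, bh = (b.left, b.top, b.width, b.height) if isinstance(b, BoxRecord) else b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


@dataclass
class FrameAssignment:
    """Per-frame one-to-one GT↔hypothesis correspondences."""

    matches: dict[int, list[tuple[int, int, float]]] = field(default_factory=dict)
    unmatched_gt: dict[int, list[int]] = field(default_factory=dict)
    unmatched_hyp: dict[int, list[int]] = field(default_factory=dict)
    frames: list[int] = field(default_factory=list)

    @property
    def n_matches(self) -> int:
        return sum(len(m) for m in self.matches.values())


def match_frames(
    gt: TrackDataset, hyp: TrackDataset, iou_threshold: float = 0.5
) -> FrameAssignment:
    """CLEAR-style frame-by-frame matching with match persistence."""
    out = FrameAssignment()
    gt_frames = gt.frames()
    hyp_frames = hyp.frames()
    all_frames = sorted(set(gt_frames) | set(hyp_frames))
    prev: dict[int, int] = {}  # gt_id -> hyp_id carried over
    for t in all_frames:
        g_recs = {r.track_id: r for r in gt_frames.get(t, [])}
        h_recs = {r.track_id: r for r in hyp_frames.get(t, [])}
        matches: list[tuple[int, int, float]] = []
        used_h: set[int] = set()
        # persistence: keep last frame's pairs that still overlap enough
        for gid, hid in prev.items():
            if gid in g_recs and hid in h_recs and hid not in used_h:
                o = iou(g_recs[gid], h_recs[hid])
                if o >= iou_threshold:
                    matches.append((gid, hid, o))
                    used_h.add(hid)
        matched_g = {m[0] for m in matches}
        free_g = [gid for gid in sorted(g_recs) if gid not in matched_g]
        free_h = [hid for hid in sorted(h_recs) if hid not in used_h]
        if free_g and free_h:
            cost = np.ones((len(free_g), len(free_h)))
            for i, gid in enumerate(free_g):
                for j, hid in enumerate(free_h):
                    cost[i, j] = 1.0 - iou(g_recs[gid], h_recs[hid])
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                o = 1.0 - cost[i, j]
                if o >= iou_threshold:
                    matches.append((free_g[i], free_h[j], o))
        matched_g = {m[0] for m in matches}
        matched_h = {m[1] for m in matches}
        out.matches[t] = sorted(matches)
        out.unmatched_gt[t] = [g for g in sorted(g_recs) if g not in matched_g]
        out.unmatched_hyp[t] = [h for h in sorted(h_recs) if h not in matched_h]
        out.frames.append(t)
        prev = {gid: hid for gid, hid, _ in matches}
    return out


def id_switches(assign: FrameAssignment) -> int:
    """Total identity switches under the most-recent-previous-match rule."""
    last: dict[int, int] = {}
    switches = 0
    for t in assign.frames:
        for gid, hid, _ in assign.matches[t]:
            if gid in last and last[gid] != hid:
                switches += 1
            last[gid] = hid
    return switches


def mota(gt: TrackDataset, hyp: TrackDataset,
         assign: FrameAssignment) -> tuple[float, dict[str, int]]:
    """MOTA (×100) and its constituent counts."""
    total_gt = sum(1 for r in gt.records if r.track_id >= 0)
    if total_gt == 0:
        raise DegenerateInputError("no ground-truth objects")
    fn = sum(len(v) for v in assign.unmatched_gt.values())
    fp = sum(len(v) for v in assign.unmatched_hyp.values())
    idsw = id_switches(assign)
    value = 100.0 * (1.0 - (fn + fp + idsw) / total_gt)
    return value, {"FN": fn, "FP": fp, "IDsw": idsw, "GT": total_gt}


def motp(assign: FrameAssignment) -> float:
    """Mean bounding-box overlap over all matches (in [0, 1])."""
    overlaps = [o for t in assign.frames for _, _, o in assign.matches[t]]
    if not overlaps:
        raise DegenerateInputError("no matches")
    return float(np.mean(overlaps))


def idf1(
    gt: TrackDataset, hyp: TrackDataset, iou_threshold: float = 0.5
) -> tuple[float, dict[str, int]]:
    """Identity F1 (×100) under the optimal global id-to-id mapping."""
    gt_ids = gt.track_ids()
    hyp_ids = hyp.track_ids()
    n_gt = sum(1 for r in gt.records if r.track_id >= 0)
    n_hyp = sum(1 for r in hyp.records if r.track_id >= 0)
    if not gt_ids or not hyp_ids:
        return 0.0, {"IDTP": 0, "IDFP": n_hyp, "IDFN": n_gt}
    # potential IDTP per (gt id, hyp id): frames where their boxes overlap
    gain = np.zeros((len(gt_ids), len(hyp_ids)), dtype=int)
    hyp_frames = hyp.frames()
    gt_by_frame = gt.frames()
    for t, g_recs in gt_by_frame.items():
        h_recs = hyp_frames.get(t, [])
        for g in g_recs:
            for h in h_recs:
                if iou(g, h) >= iou_threshold:
                    gain[gt_ids.index(g.track_id), hyp_ids.index(h.track_id)] += 1
    rows, cols = linear_sum_assignment(gain, maximize=True)
    idtp = int(gain[rows, cols].sum())
    idfn = n_gt - idtp
    idfp = n_hyp - idtp
    denom = 2 * idtp + idfp + idfn
    value = 100.0 * (2 * idtp / denom) if denom else 0.0
    return value, {"IDTP": idtp, "IDFP": idfp, "IDFN": idfn}


def mt_ml(
    gt: TrackDataset, assign: FrameAssignment
) -> tuple[int, int, dict[int, float]]:
    """Mostly-tracked / mostly-lost counts and per-identity coverage.

    Coverage is matched frames over lifetime frames; MT counts identities
    with coverage ≥ 0.8 (inclusive), ML those with coverage ≤ 0.2.
    """
    lifetime: dict[int, int] = {}
    for r in gt.records:
        if r.track_id >= 0:
            lifetime[r.track_id] = lifetime.get(r.track_id, 0) + 1
    covered: dict[int, int] = {gid: 0 for gid in lifetime}
    for t in assign.frames:
        for gid, _, _ in assign.matches[t]:
            covered[gid] = covered.get(gid, 0) + 1
    coverage = {gid: covered[gid] / n for gid, n in lifetime.items()}
    mt = sum(1 for c in coverage.values() if c >= 0.8)
    ml = sum(1 for c in coverage.values() if c <= 0.2)
    return mt, ml, coverage


def evaluate_tracking(
    gt: TrackDataset, hyp: TrackDataset, iou_threshold: float = 0.5
) -> MetricReport:
    """One benchmark-style report row for a (ground truth, hypothesis) pair."""
    assign = match_frames(gt, hyp, iou_threshold)
    mota_val, counts = mota(gt, hyp, assign)
    n_matches = assign.n_matches
    total_gt = counts["GT"]
    total_hyp = sum(1 for r in hyp.records if r.track_id >= 0)
    idf1_val, id_counts = idf1(gt, hyp, iou_threshold)
    mt, ml, coverage = mt_ml(gt, assign)
    report = MetricReport(
        values={
            "MOTA": mota_val,
            "MOTP": motp(assign) if n_matches else 0.0,
            "IDF1": idf1_val,
            "IDsw": float(counts["IDsw"]),
            "Recall": 100.0 * n_matches / total_gt,
            "Precision": 100.0 * n_matches / total_hyp if total_hyp else 0.0,
            "MT": float(mt),
            "ML": float(ml),
        },
        counts={**counts, **id_counts, "matches": n_matches, "HYP": total_hyp},
        details={"coverage": coverage},
    )
    return report


def _truncate(x: float, decimals: int) -> float:
    """Truncate toward zero at a decimal position, robust to binary noise."""
    scaled = round(x * 10 ** decimals, 6)
    return np.trunc(scaled) / 10 ** decimals


def aggregate_reports(rows: list[MetricReport | dict]) -> MetricReport:
    """Unweighted mean of report rows, truncated at the printed precision.

    Ratio metrics keep 2 decimals (MOTP 3); count metrics (IDsw, MT, ML)
    are truncated to integers.  Truncation — not rounding — toward zero
    matches how averaged benchmark tables are conventionally printed.
    """
    if not rows:
        raise DegenerateInputError("no rows to aggregate")
    dicts = [r.values if isinstance(r, MetricReport) else r for r in rows]
    keys = dicts[0].keys()
    if any(d.keys() != keys for d in dicts):
        raise ValidationError("rows carry different metric sets")
    out = {}
    for k in keys:
        mean = float(np.mean([d[k] for d in dicts]))
        out[k] = _truncate(mean, _AGG_DECIMALS.get(k, 2))
    return MetricReport(values=out)
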