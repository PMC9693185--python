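"""A SORT-style tracking-by-detection baseline.

Each track keeps a Kalman filter over the state (cx, cy, vx, vy, w, h):
constant-velocity box center, static box size.  Per frame:

1. every active track predicts its box one step ahead;
2. detections with confidence at or below the threshold are discarded;
3. surviving detections are assigned to predicted tracks by the Hungarian
   algorithm on the cost ‖center_det − center_pred‖ + λ·(|Δw| + |Δh|),
   with pairs costing more than the gate rejected;
4. matched tracks are measurement-updated, unmatched detections spawn new
   tracks with fresh ids, and tracks unmatched for more than ``max_age``
   frames are retired (their ids are never reused).

The tracker is purely positional — no appearance features — and fully
deterministic for a given detection stream and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tracks import BoxRecord, TrackDataset, UNASSIGNED


@dataclass(frozen=True)
class TrackerConfig:
    """Gates and noise levels of the baseline tracker.

    ``lam`` weighs a pixel of box-size difference against a pixel of
    center distance in the assignment cost; ``gate`` is the maximum
    admissible cost; ``conf_threshold`` drops weak detections before
    assignment; ``max_age`` is how many frames a track survives without a
    detection; ``min_hits`` how many assignments before a track's boxes
    are emitted.
    """

    conf_threshold: float = 0.4
    gate: float = 100.0
    lam: float = 0.5
    max_age: int = 3
    min_hits: int = 1
    q: float = 1e-2  # process noise (pixels²)
    r: float = 1.0   # measurement noise (pixels²)


# constant-velocity center + static size, measurement (cx, cy, w, h)
_F = np.eye(6)
_F[0, 2] = _F[1, 3] = 1.0
_H = np.zeros((4, 6))
_H[0, 0] = _H[1, 1] = _H[2, 4] = _H[3, 5] = 1.0


@dataclass
class TrackState:
    """One tracked object: filter state plus lifecycle counters."""

    track_id: int
    x: np.ndarray                 # (cx, cy, vx, vy, w, h)
    P: np.ndarray
    age: int = 0
    hits: int = 1
    time_since_update: int = 0
    predicted: np.ndarray = field(default=None)  # last predicted measurement

    @classmethod
    def from_detection(cls, det: BoxRecord, track_id: int, cfg: TrackerConfig):
        cx, cy = det.center
        x = np.array([cx, cy, 0.0, 0.0, det.width, det.height])
        P = np.diag([cfg.r, cfg.r, 10.0 * cfg.r, 10.0 * cfg.r, cfg.r, cfg.r])
        return cls(track_id=track_id, x=x, P=P, predicted=_H @ x)

    def predict(self, cfg: TrackerConfig) -> np.ndarray:
        """Time update; returns the predicted (cx, cy, w, h)."""
        Q = cfg.q * np.diag([1.0, 1.0, 1.0, 1.0, 0.1, 0.1])
        self.x = _F @ self.x
        self.P = _F @ self.P @ _F.T + Q
        self.age += 1
        self.time_since_update += 1
        self.predicted = _H @ self.x
        return self.predicted

    def update(self, det: BoxRecord, cfg: TrackerConfig) -> None:
        z = np.array([*det.center, det.width, det.height])
        S = _H @ self.P @ _H.T + cfg.r * np.eye(4)
        K = self.P @ _H.T @ np.linalg.inv(S)
        self.x = self.x + K @ (z - _H @ self.x)
        self.P = (np.eye(6) - K @ _H) @ self.P
        self.x[4] = max(self.x[4], 1e-6)
        self.x[5] = max(self.x[5], 1e-6)
        self.hits += 1
        self.time_since_update = 0

    def to_box(self, frame: int) -> BoxRecord:
        cx, cy, _, _, w, h = self.x
        return BoxRecord(frame, self.track_id, cx - w / 2, cy - h / 2, w, h, 1.0)


def associate(
    tracks: list[TrackState],
    detections: list[BoxRecord],
    cfg: TrackerConfig,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match predicted tracks to one frame's detections.

    Returns (pairs of (track index, detection index), unmatched track
    indices, unmatched detection indices).  Detections with confidence at
    or below the threshold are dropped entirely (they appear in neither
    list).  Ties are broken deterministically by (track id, detection
    order) since the cost matrix is traversed in that order.
    """
    usable = [i for i, d in enumerate(detections) if d.confidence > cfg.conf_threshold]
    if not tracks or not usable:
        return [], list(range(len(tracks))), usable
    cost = np.zeros((len(tracks), len(usable)))
    for ti, trk in enumerate(tracks):
        pcx, pcy, pw, ph = trk.predicted
        for dj, di in enumerate(usable):
            det = detections[di]
            dcx, dcy = det.center
            dist = np.hypot(dcx - pcx, dcy - pcy)
            size = abs(det.width - pw) + abs(det.height - ph)
            cost[ti, dj] = dist + cfg.lam * size
    rows, cols = linear_sum_assignment(cost)
    pairs, matched_t, matched_d = [], set(), set()
    for i, j in zip(rows, cols):
        if cost[i, j] <= cfg.gate:
            pairs.append((i, usable[j]))
            matched_t.add(i)
            matched_d.add(usable[j])
    un_t = [i for i in range(len(tracks)) if i not in matched_t]
    un_d = [i for i in usable if i not in matched_d]
    return pairs, un_t, un_d


class SortTracker:
    """Stateful frame-by-frame tracker; see module docstring."""

    def __init__(self, cfg: TrackerConfig | None = None):
        self.cfg = cfg or TrackerConfig()
        self.tracks: list[TrackState] = []
        self._next_id = 1

    def step(self, frame: int, detections: list[BoxRecord]) -> list[BoxRecord]:
        """Advance one frame; returns the boxes emitted for this frame."""
        for trk in self.tracks:
            trk.predict(self.cfg)
        pairs, un_t, un_d = associate(self.tracks, detections, self.cfg)
        for ti, di in pairs:
            self.tracks[ti].update(detections[di], self.cfg)
        for di in un_d:
            self.tracks.append(
                TrackState.from_detection(detections[di], self._next_id, self.cfg)
            )
            self._next_id += 1
        self.tracks = [
            t for t in self.tracks if t.time_since_update <= self.cfg.max_age
        ]
        return [
            t.to_box(frame)
            for t in sorted(self.tracks, key=lambda t: t.track_id)
            if t.time_since_update == 0 and t.hits >= self.cfg.min_hits
        ]


def run_tracker(
    detections: TrackDataset, cfg: TrackerConfig | None = None
) -> TrackDataset:
    """Run the baseline tracker over a detection dataset.

    Detections are consumed frame by frame (ids on the input are ignored);
    the output is a hypothesis dataset with stable track ids.
    """
    tracker = SortTracker(cfg)
    out: list[BoxRecord] = []
    by_frame = detections.frames()
    for frame in range(1, detections.n_frames + 1):
        out.extend(tracker.step(frame, by_frame.get(frame, [])))
    return TrackDataset(records=out, n_frames=detections.n_frames,
                        name=f"{detections.name}-sort")


__all__ = [
    "TrackerConfig", "TrackState", "SortTracker", "associate", "run_tracker",
    "UNASSIGNED",
]
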