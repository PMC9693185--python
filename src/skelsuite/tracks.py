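"""Bounding-box track containers for multi-object tracking evaluation.

Boxes are axis-aligned ``(left, top, width, height)`` in pixels with y
increasing downward, the image convention.  Frames are 1-based on disk
(MOTChallenge convention) and stay 1-based in :class:`BoxRecord`; nothing
internal ever re-indexes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

UNASSIGNED = -1  # track_id of a raw detection


@dataclass(frozen=True)
class BoxRecord:
    """One identified (or raw, id = -1) bounding box in one frame."""

    frame: int
    track_id: int
    left: float
    top: float
    width: float
    height: float
    confidence: float = 1.0

    def __post_init__(self):
        if self.frame < 1:
            raise ValidationError(f"frame must be >= 1, got {self.frame}")
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"box width/height must be positive, got "
                f"({self.width}, {self.height}) at frame {self.frame}"
            )

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.left, self.top, self.width, self.height)

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)


@dataclass
class TrackDataset:
    """A named collection of box records covering ``n_frames`` frames."""

    records: list[BoxRecord]
    n_frames: int = 0
    name: str = ""

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r.frame, r.track_id))
        max_frame = max((r.frame for r in self.records), default=0)
        if self.n_frames == 0:
            self.n_frames = max_frame
        elif max_frame > self.n_frames:
            raise ValidationError(
                f"record at frame {max_frame} exceeds n_frames={self.n_frames}"
            )
        seen = set()
        for r in self.records:
            if r.track_id == UNASSIGNED:
                continue
            key = (r.frame, r.track_id)
            if key in seen:
                raise ValidationError(f"duplicate (frame, id) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def by_frame(self, frame: int) -> list[BoxRecord]:
        return [r for r in self.records if r.frame == frame]

    def frames(self) -> dict[int, list[BoxRecord]]:
        """Records grouped by frame (only frames that have records)."""
        out: dict[int, list[BoxRecord]] = {}
        for r in self.records:
            out.setdefault(r.frame, []).append(r)
        return out

    def track_ids(self) -> list[int]:
        return sorted({r.track_id for r in self.records if r.track_id != UNASSIGNED})

    def as_detections(self) -> "TrackDataset":
        """Copy with all identities erased (id = -1), for feeding a tracker."""
        return TrackDataset(
            records=[
                BoxRecord(r.frame, UNASSIGNED, r.left, r.top, r.width, r.height,
                          r.confidence)
                for r in self.records
            ],
            n_frames=self.n_frames,
            name=self.name,
        )

    def equals(self, other: "TrackDataset", atol: float = 1e-9) -> bool:
        if len(self.records) != len(other.records) or self.n_frames != other.n_frames:
            return False
        for a, b in zip(self.records, other.records):
            if (a.frame, a.track_id) != (b.frame, b.track_id):
                return False
            if not np.allclose(
                [a.left, a.top, a.width, a.height, a.confidence],
                [b.left, b.top, b.width, b.height, b.confidence],
                atol=atol, rtol=0.0,
            ):
                return False
        return True


@dataclass
class MetricReport:
    """Computed metric values plus the counts they were built from.

    ``values`` holds the headline numbers (percentages on the 0–100 scale
    where that is the printed convention); ``counts`` the integer
    constituents (TP/FP/FN, IDTP/IDFP/IDFN, Σc_t, ΣGT_t); ``details``
    anything table-like (per-joint distances, per-identity coverage).
    """

    values: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    details: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def row(self, order: list[str]) -> list[float]:
        return [self.values[k] for k in order]
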