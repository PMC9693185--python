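"""The PoseSequence container: frames × joints × coordinates with visibility.

Invisible joints are stored as NaN with ``visible[f, j] = False``.  Every
operation in the toolkit consults the visibility mask, never NaN-ness.
Pose coordinates are right-handed with y up for 3D data; 2D image-plane
data uses y increasing downward (the units tag records which world the
numbers live in).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ValidationError
from .skeleton import SkeletonDefinition

UNITS = ("pixels", "normalized", "meters")


@dataclass
class PoseSequence:
    """A tracked person's pose over time.

    Attributes
    ----------
    coords
        ``(T, J, D)`` float array, ``D`` in {2, 3}; NaN where invisible.
    visible
        ``(T, J)`` boolean mask.
    skeleton
        The layout the joint axis follows.
    units
        One of ``pixels``, ``normalized``, ``meters``.
    fps
        Optional capture rate (frames per second).
    """

    coords: np.ndarray
    visible: np.ndarray
    skeleton: SkeletonDefinition
    units: str = "normalized"
    fps: Optional[float] = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] not in (2, 3):
            raise ValidationError(f"coords must be (T, J, D<=3), got {coords.shape}")
        if coords.shape[1] != self.skeleton.n_joints:
            raise ValidationError(
                f"sequence has {coords.shape[1]} joints, skeleton defines "
                f"{self.skeleton.n_joints}"
            )
        if self.visible is None:
            visible = np.all(np.isfinite(coords), axis=2)
        else:
            visible = np.asarray(self.visible, dtype=bool)
        if visible.shape != coords.shape[:2]:
            raise ValidationError("visible mask shape must be (T, J)")
        if not np.all(np.isfinite(coords[visible])):
            bad = np.argwhere(visible & ~np.all(np.isfinite(coords), axis=2))
            f, j = bad[0]
            raise ValidationError(
                f"non-finite coordinate at visible joint "
                f"{self.skeleton.joint_names[j]!r}, frame {f}"
            )
        if self.units not in UNITS:
            raise ValidationError(f"unknown units {self.units!r}")
        # invisible entries are typically NaN, but may hold model-filled
        # values (e.g. after smoothing); the mask is authoritative either way
        self.coords = coords.copy()
        self.visible = visible

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[2]

    def with_coords(self, coords: np.ndarray, units: Optional[str] = None,
                    visible: Optional[np.ndarray] = None) -> "PoseSequence":
        """Copy of this sequence with new coordinates (and optional mask)."""
        return replace(
            self,
            coords=coords,
            visible=self.visible.copy() if visible is None else visible,
            units=self.units if units is None else units,
        )

    def frame(self, f: int) -> np.ndarray:
        return self.coords[f]

    def bone_lengths(self, f: int) -> np.ndarray:
        """Per-bone lengths in frame ``f`` (NaN where an endpoint hidden)."""
        return self.skeleton.bone_lengths_from(self.coords[f])

    def allclose(self, other: "PoseSequence", atol: float = 1e-9) -> bool:
        if self.coords.shape != other.coords.shape:
            return False
        if not np.array_equal(self.visible, other.visible):
            return False
        a, b = self.coords[self.visible], other.coords[other.visible]
        return bool(np.allclose(a, b, atol=atol, rtol=0.0))
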