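"""Skeleton definitions: joints, kinematic tree, bones, evaluation subsets.

A :class:`SkeletonDefinition` is the shared vocabulary of every other
module: pose files are validated against it, the h-norm needs to know which
joints are the nose and the feet, root alignment needs the hips, and
retargeting walks its kinematic tree.

The built-in default is the common 18-keypoint convention used by 2D pose
estimators (nose, neck, eyes, ears, shoulders, elbows, wrists, hips, knees,
ankles) together with a 13-joint evaluation subset (head plus the 12 major
limb joints) that is standard for whole-body error metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import SkeletonError

ROOT_PARENT = -1

#: roles that named operations rely on
SPECIAL_ROLES = ("nose", "neck", "left_foot", "right_foot", "left_hip", "right_hip")


@dataclass(frozen=True)
class SkeletonDefinition:
    """Joint names, kinematic tree and metadata for one skeleton layout.

    Parameters
    ----------
    joint_names
        Ordered joint labels; index order is the storage order of every
        pose array.
    parent_index
        Per-joint index of the kinematic parent; the single root carries
        ``ROOT_PARENT`` (-1).
    bones
        ``(a, b)`` joint-index pairs.  If omitted, the tree edges
        ``(parent, child)`` are used.
    side_of
        Per-joint label in ``{"left", "right", "center"}``.
    subsets
        Named joint-index subsets, e.g. ``"eval13"``.
    special_joints
        Mapping of the roles in :data:`SPECIAL_ROLES` to joint indices.
    """

    joint_names: tuple[str, ...]
    parent_index: tuple[int, ...]
    bones: tuple[tuple[int, int], ...] = ()
    side_of: tuple[str, ...] = ()
    subsets: dict[str, tuple[int, ...]] = field(default_factory=dict)
    special_joints: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.joint_names)
        if len(set(self.joint_names)) != n:
            raise SkeletonError("duplicate joint names")
        if len(self.parent_index) != n:
            raise SkeletonError("parent_index length != joint count")
        self._validate_tree(n)
        if not self.bones:
            object.__setattr__(
                self,
                "bones",
                tuple(
                    (p, c) for c, p in enumerate(self.parent_index) if p != ROOT_PARENT
                ),
            )
        for a, b in self.bones:
            if a == b or not (0 <= a < n and 0 <= b < n):
                raise SkeletonError(f"bone ({a}, {b}) does not reference two distinct joints")
        if self.side_of and len(self.side_of) != n:
            raise SkeletonError("side_of length != joint count")
        for label in self.side_of:
            if label not in ("left", "right", "center"):
                raise SkeletonError(f"invalid side label {label!r}")
        for name, subset in self.subsets.items():
            if len(subset) == 0:
                raise SkeletonError(f"subset {name!r} is empty")
            if not all(0 <= j < n for j in subset):
                raise SkeletonError(f"subset {name!r} references unknown joints")
        for role, j in self.special_joints.items():
            if not (0 <= j < n):
                raise SkeletonError(f"special joint {role!r} -> {j} out of range")

    def _validate_tree(self, n: int) -> None:
        roots = [j for j, p in enumerate(self.parent_index) if p == ROOT_PARENT]
        if len(roots) != 1:
            raise SkeletonError(f"tree must have exactly one root, found {len(roots)}")
        for j, p in enumerate(self.parent_index):
            if p != ROOT_PARENT and not (0 <= p < n):
                raise SkeletonError(f"joint {j} has out-of-range parent {p}")
        # ascend from every joint; a cycle never reaches the root
        for j in range(n):
            seen = set()
            k = j
            while k != roots[0]:
                if k in seen:
                    raise SkeletonError(f"cycle through joint {j}")
                seen.add(k)
                k = self.parent_index[k]
                if k == ROOT_PARENT:  # pragma: no cover - only one root exists
                    break

    # -- convenience -------------------------------------------------------

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def root(self) -> int:
        return self.parent_index.index(ROOT_PARENT)

    def index_of(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise SkeletonError(f"unknown joint name {name!r}") from None

    def special(self, role: str) -> int:
        if role not in self.special_joints:
            raise SkeletonError(f"skeleton defines no {role!r} joint")
        return self.special_joints[role]

    def subset(self, name: str) -> tuple[int, ...]:
        if name not in self.subsets:
            raise SkeletonError(f"unknown subset {name!r}")
        return self.subsets[name]

    def children(self, joint: int) -> list[int]:
        return [c for c, p in enumerate(self.parent_index) if p == joint]

    def topological_order(self) -> list[int]:
        """Joints ordered root-first so each parent precedes its children."""
        order, stack = [], [self.root]
        while stack:
            j = stack.pop()
            order.append(j)
            stack.extend(self.children(j))
        return order

    def tree_bones(self) -> list[tuple[int, int]]:
        """(parent, child) edges of the kinematic tree, root-first."""
        return [
            (self.parent_index[c], c)
            for c in self.topological_order()
            if self.parent_index[c] != ROOT_PARENT
        ]

    def bone_lengths_from(self, coords: np.ndarray) -> np.ndarray:
        """Per-bone Euclidean length measured on one pose (J×D array)."""
        coords = np.asarray(coords, dtype=float)
        return np.array(
            [np.linalg.norm(coords[b] - coords[a]) for a, b in self.bones]
        )

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "joint_names": list(self.joint_names),
            "parent_index": list(self.parent_index),
            "bones": [list(b) for b in self.bones],
            "side_of": list(self.side_of),
            "subsets": {k: list(v) for k, v in self.subsets.items()},
            "special_joints": dict(self.special_joints),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SkeletonDefinition":
        return cls(
            joint_names=tuple(d["joint_names"]),
            parent_index=tuple(d["parent_index"]),
            bones=tuple(tuple(b) for b in d.get("bones", [])),
            side_of=tuple(d.get("side_of", ())),
            subsets={k: tuple(v) for k, v in d.get("subsets", {}).items()},
            special_joints=dict(d.get("special_joints", {})),
        )

    @classmethod
    def from_file(cls, path) -> "SkeletonDefinition":
        """Load a skeleton from a YAML or JSON config file."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TargetSkeleton:
    """A skeleton together with the bone lengths a pose is retargeted onto."""

    skeleton: SkeletonDefinition
    bone_lengths: np.ndarray

    def __post_init__(self):
        lengths = np.asarray(self.bone_lengths, dtype=float)
        object.__setattr__(self, "bone_lengths", lengths)
        if lengths.shape != (len(self.skeleton.bones),):
            raise SkeletonError("need exactly one bone length per bone")
        if not np.all(lengths > 0):
            raise SkeletonError("all target bone lengths must be positive")

    def length_of(self, parent: int, child: int) -> float:
        bones = self.skeleton.bones
        for i, (a, b) in enumerate(bones):
            if (a, b) == (parent, child) or (a, b) == (child, parent):
                return float(self.bone_lengths[i])
        raise SkeletonError(f"no bone between joints {parent} and {child}")


_DEFAULT_JOINTS = (
    "nose", "neck",
    "right_shoulder", "right_elbow", "right_wrist",
    "left_shoulder", "left_elbow", "left_wrist",
    "right_hip", "right_knee", "right_ankle",
    "left_hip", "left_knee", "left_ankle",
    "right_eye", "left_eye", "right_ear", "left_ear",
)

_DEFAULT_PARENTS = (
    1, ROOT_PARENT,
    1, 2, 3,
    1, 5, 6,
    1, 8, 9,
    1, 11, 12,
    0, 0, 14, 15,
)

_DEFAULT_SIDES = (
    "center", "center",
    "right", "right", "right",
    "left", "left", "left",
    "right", "right", "right",
    "left", "left", "left",
    "right", "left", "right", "left",
)

_EVAL13 = (0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13)


def default_skeleton() -> SkeletonDefinition:
    """The common 18-keypoint human skeleton with an ``eval13`` subset.

    The evaluation subset keeps the head (nose) plus shoulders, elbows,
    wrists, hips, knees and ankles — the 13 joints whole-body metrics are
    typically computed on — and drops eyes/ears/neck.
    """
    return SkeletonDefinition(
        joint_names=_DEFAULT_JOINTS,
        parent_index=_DEFAULT_PARENTS,
        side_of=_DEFAULT_SIDES,
        subsets={"full18": tuple(range(18)), "eval13": _EVAL13},
        special_joints={
            "nose": 0,
            "neck": 1,
            "head": 0,
            "right_foot": 10,
            "left_foot": 13,
            "right_hip": 8,
            "left_hip": 11,
        },
    )
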