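"""Readers and writers for pose sequences and MOTChallenge track files.

Pose JSON schema::

    {"units": "meters", "fps": 30.0, "joints": ["nose", ...],
     "frames": [[[x, y, z], ...], ...],          # T × J × D
     "visible": [[true, ...], ...]}              # T × J, optional

Pose CSV schema: one row per frame × joint with columns
``frame,joint,x,y[,z],visible`` (frame 0-based, joint by name).

Track files are the MOTChallenge CSV dialect
``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z`` with 1-based
frames; the world columns are ignored on read and written as -1.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PoseParseError, TrackParseError, ValidationError
from .pose import PoseSequence
from .skeleton import SkeletonDefinition
from .tracks import BoxRecord, TrackDataset


# --------------------------------------------------------------------------
# pose sequences
# --------------------------------------------------------------------------

def _map_joint_order(names: list[str], skeleton: SkeletonDefinition) -> list[int]:
    """Position of each skeleton joint within the file's joint list."""
    unknown = [n for n in names if n not in skeleton.joint_names]
    if unknown:
        raise PoseParseError(f"unknown joint name(s) {unknown} not in skeleton")
    missing = [n for n in skeleton.joint_names if n not in names]
    if missing:
        raise PoseParseError(f"file is missing skeleton joint(s) {missing}")
    return [names.index(n) for n in skeleton.joint_names]


def read_pose_sequence(path, skeleton: SkeletonDefinition) -> PoseSequence:
    """Read a pose sequence from the JSON or CSV schema above.

    Joint order in the file is mapped onto the skeleton's order by name.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_pose_csv(path, skeleton)
    return _read_pose_json(path, skeleton)


def _read_pose_json(path: Path, skeleton: SkeletonDefinition) -> PoseSequence:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise PoseParseError(f"{path}: invalid JSON ({e})") from e
    for key in ("joints", "frames"):
        if key not in doc:
            raise PoseParseError(f"{path}: missing required key {key!r}")
    order = _map_joint_order(list(doc["joints"]), skeleton)
    frames = doc["frames"]
    if not frames:
        raise PoseParseError(f"{path}: no frames")
    widths = {len(f) for f in frames}
    if widths != {len(doc["joints"])}:
        bad = next(i for i, f in enumerate(frames) if len(f) != len(doc["joints"]))
        raise PoseParseError(
            f"{path}: frame {bad} has {len(frames[bad])} joints, "
            f"expected {len(doc['joints'])}"
        )
    coords = np.array(
        [[[np.nan if v is None else float(v) for v in joint] for joint in f]
         for f in frames],
        dtype=float,
    )
    coords = coords[:, order, :]
    if "visible" in doc and doc["visible"] is not None:
        visible = np.asarray(doc["visible"], dtype=bool)[:, order]
    else:
        visible = np.all(np.isfinite(coords), axis=2)
    try:
        return PoseSequence(
            coords=coords,
            visible=visible,
            skeleton=skeleton,
            units=doc.get("units", "normalized"),
            fps=doc.get("fps"),
        )
    except ValidationError as e:
        raise PoseParseError(f"{path}: {e}") from e


def _read_pose_csv(path: Path, skeleton: SkeletonDefinition) -> PoseSequence:
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise PoseParseError(f"{path}: unreadable CSV ({e})") from e
    required = {"frame", "joint", "x", "y"}
    if not required.issubset(df.columns):
        raise PoseParseError(f"{path}: CSV needs columns {sorted(required)}")
    names = sorted(df["joint"].unique().tolist())
    _map_joint_order(names, skeleton)
    dims = 3 if "z" in df.columns else 2
    n_frames = int(df["frame"].max()) + 1
    coords = np.full((n_frames, skeleton.n_joints, dims), np.nan)
    visible = np.zeros((n_frames, skeleton.n_joints), dtype=bool)
    axes = ["x", "y", "z"][:dims]
    for _, row in df.iterrows():
        j = skeleton.index_of(str(row["joint"]))
        f = int(row["frame"])
        coords[f, j] = [row[a] for a in axes]
        visible[f, j] = bool(row["visible"]) if "visible" in df.columns else True
    coords[~visible] = np.nan
    try:
        return PoseSequence(coords=coords, visible=visible, skeleton=skeleton)
    except ValidationError as e:
        raise PoseParseError(f"{path}: {e}") from e


def write_pose_sequence(seq: PoseSequence, path) -> None:
    """Write the JSON schema; re-readable by :func:`read_pose_sequence`."""
    coords = seq.coords.copy()
    frames = [
        [[None if not math.isfinite(v) else v for v in joint] for joint in frame]
        for frame in coords.tolist()
    ]
    doc = {
        "units": seq.units,
        "fps": seq.fps,
        "joints": list(seq.skeleton.joint_names),
        "frames": frames,
        "visible": seq.visible.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# --------------------------------------------------------------------------
# MOTChallenge track files
# --------------------------------------------------------------------------

def read_track_file(path, n_frames: int = 0, name: str = "") -> TrackDataset:
    """Read a MOTChallenge CSV file into a :class:`TrackDataset`.

    ``n_frames`` defaults to the maximum frame index present.
    """
    records = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 6:
                raise TrackParseError(
                    f"{path}:{lineno}: expected >= 6 comma-separated fields"
                )
            try:
                frame = int(float(parts[0]))
                track_id = int(float(parts[1]))
                left, top, w, h = (float(p) for p in parts[2:6])
                conf = float(parts[6]) if len(parts) > 6 else 1.0
            except ValueError as e:
                raise TrackParseError(f"{path}:{lineno}: non-numeric field ({e})") from e
            try:
                records.append(BoxRecord(frame, track_id, left, top, w, h, conf))
            except ValidationError as e:
                raise TrackParseError(f"{path}:{lineno}: {e}") from e
    try:
        return TrackDataset(records=records, n_frames=n_frames, name=name or path.stem)
    except ValidationError as e:
        raise TrackParseError(f"{path}: {e}") from e


def write_track_file(ds: TrackDataset, path) -> None:
    """Write MOTChallenge CSV, records sorted by (frame, id)."""
    with open(path, "w") as fh:
        for r in sorted(ds.records, key=lambda r: (r.frame, r.track_id)):
            # shortest round-tripping float repr keeps read∘write exact
            fields = [float(v) for v in (r.left, r.top, r.width, r.height,
                                         r.confidence)]
            fh.write(
                f"{r.frame},{r.track_id},"
                + ",".join(repr(v) for v in fields)
                + ",-1,-1,-1\n"
            )
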