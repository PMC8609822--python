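"""Readers and writers for the package's plain-text interchange formats.

Point clouds travel as ascii PLY (preferred), STL (surface vertices are used
as the cloud) or whitespace XYZ; landmark sets as JSON ({name: [x, y, z]}) or
CSV (name,x,y,z); rigid transforms as JSON (row-major 3x3 rotation plus
translation); marker trajectories as TRC (tab-separated, DataRate header) or
wide CSV. Malformed files raise :class:`~hipclear.errors.InputError` naming
the offending record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .frames import LandmarkSet
from .geometry import Axis, PointCloud, RigidTransform
from .mocap import MarkerTrajectories


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def read_point_cloud(path, label: str | None = None) -> PointCloud:
    """Read a PLY/STL/XYZ file as a point cloud (mesh vertices for STL)."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    suffix = p.suffix.lower()
    if suffix in (".ply", ".stl"):
        import trimesh

        obj = trimesh.load(str(p), process=False)
        pts = np.asarray(obj.vertices, dtype=float)
    elif suffix in (".xyz", ".txt"):
        try:
            pts = np.loadtxt(p, dtype=float, ndmin=2)
        except ValueError as e:
            raise InputError(f"malformed XYZ file {p}: {e}") from None
        if pts.shape[1] != 3:
            raise InputError(f"XYZ file {p} has {pts.shape[1]} columns, expected 3")
    else:
        raise InputError(f"unsupported point-cloud format: {p.suffix!r}")
    if len(pts) == 0:
        raise InputError(f"point-cloud file {p} contains no points")
    return PointCloud(pts, label=label if label is not None else p.stem)


def write_ply(path, cloud: PointCloud) -> None:
    """Write an ascii PLY point cloud (fixed %.6f precision, reproducible)."""
    p = Path(path)
    header = [
        "ply",
        "format ascii 1.0",
        f"comment label {cloud.label}" if cloud.label else "comment hipclear cloud",
        f"element vertex {len(cloud)}",
        "property float x",
        "property float y",
        "property float z",
        "end_header",
    ]
    body = "\n".join(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in cloud.points)
    p.write_text("\n".join(header) + "\n" + body + "\n")


def write_xyz(path, cloud: PointCloud) -> None:
    np.savetxt(path, cloud.points, fmt="%.6f")


# ---------------------------------------------------------------------------
# landmarks and axes
# ---------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    """Landmark JSON ({name: [x,y,z]}, keys starting with '_' are metadata) or
    CSV (columns name,x,y,z)."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    if p.suffix.lower() == ".json":
        data = json.loads(p.read_text())
        return LandmarkSet({k: v for k, v in data.items() if not k.startswith("_")})
    if p.suffix.lower() == ".csv":
        df = pd.read_csv(p)
        required = {"name", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise InputError(f"landmark CSV {p} must have columns name,x,y,z")
        return LandmarkSet(
            {str(r["name"]): [r["x"], r["y"], r["z"]] for _, r in df.iterrows()}
        )
    raise InputError(f"unsupported landmark format: {p.suffix!r}")


def write_landmarks(path, landmarks: LandmarkSet, extra: dict | None = None) -> None:
    payload = {n: v.tolist() for n, v in landmarks.landmarks.items()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_axes(path) -> tuple[Axis, Axis]:
    """Neck and shaft axes from a landmark JSON's _neck_axis/_shaft_axis keys."""
    data = json.loads(Path(path).read_text())
    axes = []
    for key in ("_neck_axis", "_shaft_axis"):
        if key not in data:
            raise InputError(f"{path} is missing the {key!r} record")
        axes.append(Axis(np.asarray(data[key]["point"]), np.asarray(data[key]["direction"])))
    return axes[0], axes[1]


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

def read_transform(path) -> RigidTransform:
    data = json.loads(Path(path).read_text())
    try:
        return RigidTransform.from_dict(data)
    except (KeyError, InputError) as e:
        raise InputError(f"malformed transform file {path}: {e}") from None


def write_transform(path, transform: RigidTransform) -> None:
    Path(path).write_text(json.dumps(transform.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# marker trajectories
# ---------------------------------------------------------------------------

def read_trc(path) -> MarkerTrajectories:
    """Read a TRC marker file (tab-separated, standard two header blocks)."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    lines = p.read_text().splitlines()
    if len(lines) < 6:
        raise InputError(f"TRC file {p} is truncated ({len(lines)} lines)")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    try:
        rate = float(meta["DataRate"])
        n_markers = int(meta["NumMarkers"])
    except (KeyError, ValueError) as e:
        raise InputError(f"TRC header of {p} is malformed: {e}") from None
    header = lines[3].split("\t")
    labels = [h for h in header[2:] if h.strip()]
    if len(labels) != n_markers:
        raise InputError(
            f"TRC {p}: header lists {len(labels)} markers but NumMarkers={n_markers}"
        )
    rows = []
    for ln_no, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        cells = line.split("\t")
        vals = cells[2 : 2 + 3 * n_markers]
        if len(vals) != 3 * n_markers:
            raise InputError(f"TRC {p}: line {ln_no} has {len(vals)} coordinate cells")
        try:
            rows.append([float(v) if v.strip() else np.nan for v in vals])
        except ValueError:
            raise InputError(f"TRC {p}: line {ln_no} has a non-numeric cell") from None
    data = np.asarray(rows, dtype=float).reshape(len(rows), n_markers, 3)
    visible = ~np.isnan(data).any(axis=2)
    data = np.nan_to_num(data)
    return MarkerTrajectories(tuple(labels), data, rate=rate, visible=visible)


def write_trc(path, motion: MarkerTrajectories) -> None:
    """Write a TRC file with fixed %.5f precision (byte-reproducible)."""
    p = Path(path)
    n_frames, n_markers = motion.positions.shape[:2]
    rate = motion.rate
    out = [
        f"PathFileType\t4\t(X/Y/Z)\t{p.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n_frames}\t{n_markers}\tmm\t{rate:g}\t1\t{n_frames}",
        "Frame#\tTime\t" + "\t\t\t".join(motion.labels) + "\t\t",
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(n_markers)),
    ]
    for f in range(n_frames):
        cells = [str(f + 1), f"{f / rate:.5f}"]
        for m in range(n_markers):
            if motion.visible[f, m]:
                cells.extend(f"{c:.5f}" for c in motion.positions[f, m])
            else:
                cells.extend(["", "", ""])
        out.append("\t".join(cells))
    p.write_text("\n".join(out) + "\n")


def read_marker_csv(path) -> MarkerTrajectories:
    """Wide CSV: frame column plus <label>_x,<label>_y,<label>_z triplets."""
    df = pd.read_csv(path)
    rate_col = [c for c in df.columns if c.lower() == "rate"]
    rate = float(df[rate_col[0]].iloc[0]) if rate_col else 120.0
    labels = []
    for c in df.columns:
        if c.endswith("_x"):
            base = c[:-2]
            if f"{base}_y" in df.columns and f"{base}_z" in df.columns:
                labels.append(base)
    if not labels:
        raise InputError(f"{path}: no <label>_x/_y/_z column triplets found")
    data = np.stack(
        [df[[f"{l}_x", f"{l}_y", f"{l}_z"]].to_numpy(dtype=float) for l in labels],
        axis=1,
    )
    visible = ~np.isnan(data).any(axis=2)
    return MarkerTrajectories(tuple(labels), np.nan_to_num(data), rate=rate, visible=visible)


def write_angles_csv(path, angles, decimals: int | None = None) -> None:
    """Angle rows as CSV (frame_index, flexion, adduction, internal_rotation);
    full precision unless `decimals` is given (human-readable reports)."""
    rows = ["frame_index,flexion,adduction,internal_rotation"]
    for i, a in enumerate(angles):
        if a is None:
            rows.append(f"{i},,,")
        elif decimals is None:
            rows.append(f"{i},{a.flexion!r},{a.adduction!r},{a.internal_rotation!r}")
        else:
            rows.append(
                f"{i},{a.flexion:.{decimals}f},{a.adduction:.{decimals}f},"
                f"{a.internal_rotation:.{decimals}f}"
            )
    Path(path).write_text("\n".join(rows) + "\n")
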