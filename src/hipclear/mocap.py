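"""Marker trajectories, standing calibration, per-frame hip angles, frame matching.

The standing calibration records, for the pelvis and the thigh marker
cluster, the marker configuration in a reference standing posture together
with the anatomical frames (built from imaging landmarks) in that same
posture. For any later motion frame the cluster's rigid pose relative to the
calibration is recovered by a least-squares (Kabsch) fit over all cluster
markers, the anatomical frames are propagated rigidly, and Grood-Suntay
angles are evaluated. Frames with insufficient visible markers yield gap
records -- never interpolated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, InputError, NoMeasurementError
from .frames import AnatomicalFrame, HipJointAngles, frame_pose, grood_suntay_angles
from .geometry import RigidTransform
from .registration import kabsch
from .stats import lsqe


@dataclass(frozen=True)
class MarkerTrajectories:
    """Labelled marker positions over time at a fixed sample rate (mm, Hz)."""

    labels: tuple
    positions: np.ndarray  # (n_frames, n_markers, 3)
    rate: float
    visible: np.ndarray | None = None  # (n_frames, n_markers) bool

    def __post_init__(self):
        labels = tuple(self.labels)
        if len(set(labels)) != len(labels):
            raise InputError("marker labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[1] != len(labels) or pos.shape[2] != 3:
            raise InputError("positions must have shape (n_frames, n_markers, 3)")
        if not self.rate > 0:
            raise InputError("sample rate must be positive")
        vis = self.visible
        if vis is None:
            vis = np.ones(pos.shape[:2], dtype=bool)
        else:
            vis = np.asarray(vis, dtype=bool)
            if vis.shape != pos.shape[:2]:
                raise InputError("visible mask must have shape (n_frames, n_markers)")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "visible", vis)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"marker {label!r} not present") from None

    def frame_markers(self, frame: int, labels: Sequence[str]):
        """(positions, visibility) of the given labels at one frame."""
        idx = [self.index(l) for l in labels]
        return self.positions[frame, idx], self.visible[frame, idx]


def _check_cluster(points: np.ndarray, name: str) -> None:
    if len(points) < 3:
        raise DegenerateGeometryError(f"{name} cluster needs at least 3 markers")
    centred = points - points.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals[1] < 1e-6 * max(svals[0], 1.0):
        raise DegenerateGeometryError(f"{name} cluster markers are collinear")


@dataclass(frozen=True)
class BodyCalibration:
    """One body's marker cluster configuration + anatomical frame at standing."""

    body: str
    marker_labels: tuple
    reference_markers: np.ndarray  # (k, 3) standing positions
    anatomical_frame: AnatomicalFrame


@dataclass(frozen=True)
class CalibrationResult:
    pelvis: BodyCalibration
    femur: BodyCalibration
    reference_distance: float

    def __post_init__(self):
        if not self.reference_distance > 0:
            raise InputError("reference centre-to-centre distance must be positive")


def calibrate_standing(
    standing_markers: dict,
    pelvis_frame: AnatomicalFrame,
    femur_frame: AnatomicalFrame,
    pelvis_markers: Sequence[str],
    thigh_markers: Sequence[str],
) -> CalibrationResult:
    """Bind anatomical frames to marker clusters in the standing reference posture.

    `standing_markers` maps label -> 3-vector for the standing frame. The
    reference centre-to-centre distance is the distance between the two frame
    origins (acetabular centre and femoral head centre).
    """
    def grab(labels, name):
        try:
            pts = np.array([standing_markers[l] for l in labels], dtype=float)
        except KeyError as e:
            raise InputError(f"standing posture is missing marker {e.args[0]!r}") from None
        _check_cluster(pts, name)
        return pts

    pel = grab(pelvis_markers, "pelvis")
    thi = grab(thigh_markers, "thigh")
    ref_dist = float(np.linalg.norm(pelvis_frame.origin - femur_frame.origin))
    return CalibrationResult(
        pelvis=BodyCalibration("pelvis", tuple(pelvis_markers), pel, pelvis_frame),
        femur=BodyCalibration("thigh", tuple(thigh_markers), thi, femur_frame),
        reference_distance=ref_dist,
    )


@dataclass(frozen=True)
class FrameResult:
    """Angles and body poses at one motion frame; `gap` marks frames where a
    cluster had fewer than 3 visible markers (no value is interpolated)."""

    frame_index: int
    angles: HipJointAngles | None
    pelvis_transform: RigidTransform | None
    femur_transform: RigidTransform | None
    gap: bool


def track_motion(
    motion: MarkerTrajectories, calib: CalibrationResult, side: str = "right"
) -> list[FrameResult]:
    """Per-frame cluster poses (relative to standing) and Grood-Suntay angles."""
    for body in (calib.pelvis, calib.femur):
        for label in body.marker_labels:
            motion.index(label)  # raises on mismatch

    results: list[FrameResult] = []
    for f in range(motion.n_frames):
        transforms = {}
        gap = False
        for body in (calib.pelvis, calib.femur):
            pts, vis = motion.frame_markers(f, body.marker_labels)
            if vis.sum() < 3:
                gap = True
                break
            transforms[body.body] = kabsch(body.reference_markers[vis], pts[vis])
        if gap:
            results.append(FrameResult(f, None, None, None, True))
            continue
        t_p, t_f = transforms["pelvis"], transforms["thigh"]
        pelvis = frame_pose(calib.pelvis.anatomical_frame, t_p)
        femur = frame_pose(calib.femur.anatomical_frame, t_f)
        angles = grood_suntay_angles(pelvis, femur, side=side)
        results.append(FrameResult(f, angles, t_p, t_f, False))
    return results


def angles_per_frame(
    motion: MarkerTrajectories, calib: CalibrationResult, side: str = "right"
) -> list[HipJointAngles | None]:
    """Hip angle triple per frame (None for gap frames)."""
    return [r.angles for r in track_motion(motion, calib, side=side)]


def match_frame(
    motion_angles: Sequence[HipJointAngles | None], target: HipJointAngles
) -> tuple[int, float]:
    """Frame whose angles minimise the LSQE to `target`.

    Ties break to the earliest frame index; gap frames (None) never match.
    """
    best: tuple[int, float] | None = None
    for i, ang in enumerate(motion_angles):
        if ang is None:
            continue
        err = lsqe(ang, target)
        if best is None or err < best[1]:
            best = (i, err)
    if best is None:
        raise NoMeasurementError("no valid frame available for matching")
    return best
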