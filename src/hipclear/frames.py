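"""ISB pelvis/femur anatomical frames and Grood-Suntay hip angles.

The pelvis frame follows the ISB recommendation: Z along the inter-ASIS line
toward the subject's right, X anterior in the ASIS/PSIS-midpoint plane,
Y = Z x X superior; origin at the acetabular centre (best-fit sphere to the
lunate surface). The femur frame: y from the epicondyle midpoint to the
femoral head centre (superior), z perpendicular to y in the plane of the head
centre and epicondyles pointing toward the subject's right (the lateral
epicondyle on the right side, the medial one on the left -- this mirrored
construction makes positive flexion/adduction/internal rotation mean the same
clinically on both sides), x = y x z anterior; origin at the head centre.

Hip angles use the Grood-Suntay convention: e1 = pelvis Z (flexion axis,
body-fixed), e2 = femur y (rotation axis, body-fixed), e3 = e1 x e2 the
floating ab/adduction axis, equivalent to an intrinsic Z-X-Y factorisation of
the pelvis-to-femur rotation. Angle extraction uses atan2 on direction
cosines throughout (never acos of clamped dots) so signs are correct near 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DegenerateGeometryError, InputError
from .geometry import RigidTransform, SphereFit, _unit

PELVIS_LANDMARKS = ("RASIS", "LASIS", "RPSIS", "LPSIS")
FEMUR_LANDMARKS = ("medial_epicondyle", "lateral_epicondyle")

_GIMBAL_COS = 0.999


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical landmark coordinates (mm)."""

    landmarks: Mapping[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for name, p in dict(self.landmarks).items():
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise InputError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = arr
        object.__setattr__(self, "landmarks", clean)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.landmarks[name]
        except KeyError:
            raise InputError(f"missing landmark {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.landmarks

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.landmarks]
        if missing:
            raise InputError(f"missing required landmarks: {missing}")

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({n: transform.apply(p) for n, p in self.landmarks.items()})


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal body frame: columns of `axes` are x, y, z."""

    origin: np.ndarray
    axes: np.ndarray
    body: str = ""

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-8):
            raise InputError("frame axes are not orthonormal")
        if np.linalg.det(axes) < 0:
            raise InputError("frame axes are not right-handed")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "z": self.z.tolist(),
            "body": self.body,
        }


@dataclass(frozen=True)
class HipJointAngles:
    """Clinical hip angles in degrees; positive = flexion / adduction /
    internal rotation on either side."""

    flexion: float
    adduction: float
    internal_rotation: float
    side: str = "right"
    gimbal_warning: bool = False

    def __post_init__(self):
        if self.side not in ("right", "left"):
            raise InputError("side must be 'right' or 'left'")

    def as_array(self) -> np.ndarray:
        return np.array([self.flexion, self.adduction, self.internal_rotation], dtype=float)


def _orthogonalise(v: np.ndarray, against: np.ndarray, what: str) -> np.ndarray:
    w = v - (v @ against) * against
    if np.linalg.norm(w) < 1e-9:
        raise DegenerateGeometryError(f"degenerate frame: {what}")
    return w / np.linalg.norm(w)


def build_pelvis_frame(landmarks: LandmarkSet, origin_name: str = "acetabulum_center") -> AnatomicalFrame:
    """ISB pelvis frame from ASIS/PSIS landmarks, origin at the acetabular centre."""
    landmarks.require(*PELVIS_LANDMARKS, origin_name)
    rasis, lasis = landmarks["RASIS"], landmarks["LASIS"]
    if np.linalg.norm(rasis - lasis) < 1e-9:
        raise DegenerateGeometryError("degenerate frame: ASIS landmarks coincide")
    z = _unit(rasis - lasis, "inter-ASIS direction")
    mid_psis = 0.5 * (landmarks["RPSIS"] + landmarks["LPSIS"])
    mid_asis = 0.5 * (rasis + lasis)
    anterior_ref = mid_asis - mid_psis
    x = _orthogonalise(anterior_ref, z, "ASIS/PSIS landmarks are collinear")
    y = np.cross(z, x)
    return AnatomicalFrame(landmarks[origin_name], np.column_stack([x, y, z]), body="pelvis")


def build_femur_frame(
    landmarks: LandmarkSet, head_fit: SphereFit | None = None, side: str = "right"
) -> AnatomicalFrame:
    """Femur frame from the epicondyles and the femoral head centre.

    The head centre comes from `head_fit` when given, otherwise from the
    'femoral_head_center' landmark. `side` selects the mirrored lateral
    direction for left femora (see module docstring).
    """
    if side not in ("right", "left"):
        raise InputError("side must be 'right' or 'left'")
    landmarks.require(*FEMUR_LANDMARKS)
    head = head_fit.center if head_fit is not None else landmarks["femoral_head_center"]
    med, lat = landmarks["medial_epicondyle"], landmarks["lateral_epicondyle"]
    if np.linalg.norm(med - lat) < 1e-9:
        raise DegenerateGeometryError("degenerate frame: epicondyles coincide")
    mid = 0.5 * (med + lat)
    if np.linalg.norm(head - mid) < 1e-9:
        raise DegenerateGeometryError("degenerate frame: head centre at epicondyle midpoint")
    y = _unit(head - mid, "mechanical axis")
    toward_right = (lat - med) if side == "right" else (med - lat)
    z = _orthogonalise(toward_right, y, "head centre lies on the epicondyle line")
    x = np.cross(y, z)
    return AnatomicalFrame(head, np.column_stack([x, y, z]), body="femur")


def _decompose_zxy(R: np.ndarray) -> tuple[float, float, float]:
    """Intrinsic Z-X-Y Euler factorisation R = Rz(a) Rx(b) Ry(c), radians."""
    b = np.arcsin(np.clip(R[2, 1], -1.0, 1.0))
    a = np.arctan2(-R[0, 1], R[1, 1])
    c = np.arctan2(-R[2, 0], R[2, 2])
    return a, b, c


def _compose_zxy(a: float, b: float, c: float) -> np.ndarray:
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    Rx = np.array([[1.0, 0, 0], [0, cb, -sb], [0, sb, cb]])
    Ry = np.array([[cc, 0, sc], [0, 1.0, 0], [-sc, 0, cc]])
    return Rz @ Rx @ Ry


def grood_suntay_angles(
    pelvis: AnatomicalFrame, femur: AnatomicalFrame, side: str = "right"
) -> HipJointAngles:
    """Grood-Suntay hip angles of `femur` relative to `pelvis`.

    Near-gimbal poses (|e1 . e2| > 0.999, ab/adduction near +-90 deg) set
    `gimbal_warning` on the result; angles are still returned.
    """
    if side not in ("right", "left"):
        raise InputError("side must be 'right' or 'left'")
    R = pelvis.axes.T @ femur.axes
    a, b, c = _decompose_zxy(R)
    gimbal = abs(R[2, 1]) > _GIMBAL_COS
    if gimbal:
        warnings.warn("hip pose near gimbal lock (ab/adduction near +-90 deg)", stacklevel=2)
    if side == "right":
        flex, add, rot = a, -b, c
    else:
        flex, add, rot = a, b, -c
    return HipJointAngles(
        flexion=float(np.degrees(flex)),
        adduction=float(np.degrees(add)),
        internal_rotation=float(np.degrees(rot)),
        side=side,
        gimbal_warning=bool(gimbal),
    )


def hip_rotation_matrix(angles: HipJointAngles) -> np.ndarray:
    """Forward Grood-Suntay construction: the pelvis-to-femur rotation whose
    decomposition is `angles` (inverse of :func:`grood_suntay_angles`)."""
    flex = np.radians(angles.flexion)
    add = np.radians(angles.adduction)
    rot = np.radians(angles.internal_rotation)
    if angles.side == "right":
        a, b, c = flex, -add, rot
    else:
        a, b, c = flex, add, -rot
    return _compose_zxy(a, b, c)


def frame_pose(reference: AnatomicalFrame, transform: RigidTransform) -> AnatomicalFrame:
    """Rigidly move an anatomical frame: axes rotate, origin maps."""
    return AnatomicalFrame(
        transform.apply(reference.origin),
        transform.rotation @ reference.axes,
        body=reference.body,
    )
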