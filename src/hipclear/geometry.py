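"""Foundational 3D types and fitting primitives.

Conventions used throughout the package:

* all coordinates are in millimetres,
* angles cross API boundaries in degrees (radians are used internally),
* a :class:`PointCloud` is an unordered set of bone-surface points,
* a :class:`RigidTransform` is a proper rotation plus translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import AmbiguousAxisError, DegenerateGeometryError, InputError

_ORTHO_TOL = 1e-6


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"expected an (n, 3) array of points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InputError("point coordinates must be finite")
    return pts


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"cannot normalise near-zero {what}")
    return v / n


@dataclass(frozen=True)
class PointCloud:
    """Unordered 3D bone-surface points (mm)."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "points", _as_points(self.points))

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        return PointCloud(transform.apply(self.points), label=self.label)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R @ p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise InputError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
            raise InputError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other, i.e. apply `other` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass(frozen=True)
class Plane:
    """Plane through `point` with unit `normal`."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        object.__setattr__(self, "normal", _unit(self.normal, "plane normal"))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal

    def offset(self, distance: float) -> "Plane":
        """Parallel plane shifted by `distance` along the normal."""
        return Plane(self.point + distance * self.normal, self.normal)


@dataclass(frozen=True)
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if not self.radius > 0:
            raise InputError("sphere radius must be positive")
        if self.rms_residual < 0:
            raise InputError("rms residual must be non-negative")


@dataclass(frozen=True)
class Axis:
    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        object.__setattr__(self, "direction", _unit(self.direction, "axis direction"))

    def transformed(self, transform: RigidTransform) -> "Axis":
        return Axis(transform.apply(self.point), transform.rotation @ self.direction)


@dataclass(frozen=True)
class PlaneBasis:
    """Orthonormal in-plane coordinate frame (origin, u, v) on a plane.

    2D coordinates are (p - origin) . u and (p - origin) . v; the triple
    (u, v, normal) is right-handed so in-plane angle sense is well defined.
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    normal: np.ndarray

    def to_2d(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return np.column_stack([pts @ self.u, pts @ self.v])

    def to_3d(self, coords: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(np.asarray(coords, dtype=float))
        return self.origin + np.outer(c[:, 0], self.u) + np.outer(c[:, 1], self.v)


# ---------------------------------------------------------------------------
# fitting primitives
# ---------------------------------------------------------------------------

def fit_sphere(cloud: PointCloud, refine: bool = True) -> SphereFit:
    """Least-squares sphere through a point cloud.

    Solves the linear (algebraic) formulation first -- writing
    ``|p|^2 = 2 c.p + (r^2 - |c|^2)`` turns the fit into an ordinary linear
    least-squares problem with no initialisation -- then optionally refines
    by minimising the geometric residual sum((|p - c| - r)^2).
    """
    pts = cloud.points
    if len(pts) < 4:
        raise DegenerateGeometryError("sphere fit needs at least 4 points")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError(
            "sphere fit is degenerate: points are coplanar or otherwise rank-deficient"
        )
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))

    if refine:
        def residual(params):
            c, r = params[:3], params[3]
            return np.linalg.norm(pts - c, axis=1) - r

        out = least_squares(residual, np.append(center, radius), method="lm")
        center, radius = out.x[:3], float(abs(out.x[3]))

    res = np.linalg.norm(pts - center, axis=1) - radius
    return SphereFit(center, radius, float(np.sqrt(np.mean(res**2))))


def slice_by_plane(cloud: PointCloud, plane: Plane, half_thickness: float) -> PointCloud:
    """Points with |signed distance to plane| <= half_thickness (closed slab)."""
    if not half_thickness > 0:
        raise InputError("half_thickness must be positive")
    mask = np.abs(plane.signed_distance(cloud.points)) <= half_thickness
    return PointCloud(cloud.points[mask].reshape(-1, 3), label=cloud.label)


def plane_basis(plane: Plane, u_hint: np.ndarray | None = None) -> PlaneBasis:
    """Deterministic right-handed in-plane basis.

    If `u_hint` is given its in-plane component defines u; otherwise the world
    axis least aligned with the normal is projected into the plane.
    """
    n = plane.normal
    if u_hint is None:
        e = np.zeros(3)
        e[int(np.argmin(np.abs(n)))] = 1.0
    else:
        e = np.asarray(u_hint, dtype=float)
    u_raw = e - (e @ n) * n
    if np.linalg.norm(u_raw) < 1e-9:
        raise DegenerateGeometryError("u_hint is parallel to the plane normal")
    u = _unit(u_raw)
    v = np.cross(n, u)
    return PlaneBasis(plane.point.copy(), u, v, n.copy())


def project_to_plane(
    cloud: PointCloud, plane: Plane, u_hint: np.ndarray | None = None
) -> tuple[np.ndarray, PlaneBasis]:
    """Orthogonal projection to in-plane 2D coordinates.

    Returns the (n, 2) coordinates and the basis so angles/distances measured
    in 2D are independent of the ambient frame. Distances between in-plane
    points are preserved exactly (orthonormal basis).
    """
    basis = plane_basis(plane, u_hint)
    return basis.to_2d(cloud.points), basis


def fit_axis(
    cloud: PointCloud,
    hint: np.ndarray | None = None,
    anisotropy_ratio: float = 1.05,
) -> Axis:
    """Principal direction of a point set through its centroid.

    The direction of maximal variance is sign-resolved against `hint`
    (default +Y, the superior direction in the package's anatomical
    convention). Point sets whose top two variances differ by less than
    `anisotropy_ratio` have no dominant direction and raise
    :class:`AmbiguousAxisError`.
    """
    pts = cloud.points
    if len(pts) < 2:
        raise DegenerateGeometryError("axis fit needs at least 2 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] <= 0:
        raise AmbiguousAxisError("all points coincide; axis undefined")
    if evals[1] > 0 and evals[2] / evals[1] < anisotropy_ratio:
        raise AmbiguousAxisError(
            f"no dominant direction: top-two variance ratio "
            f"{evals[2] / evals[1]:.4f} < {anisotropy_ratio}"
        )
    direction = evecs[:, 2]
    ref = np.array([0.0, 1.0, 0.0]) if hint is None else np.asarray(hint, dtype=float)
    d = direction @ ref
    if abs(d) < 1e-12:
        # hint uninformative: canonical sign = largest-magnitude component positive
        k = int(np.argmax(np.abs(direction)))
        if direction[k] < 0:
            direction = -direction
    elif d < 0:
        direction = -direction
    return Axis(centroid, direction)


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (float(angle) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a
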