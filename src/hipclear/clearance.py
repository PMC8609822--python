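"""Beta-angle clearance model.

Given a posed femur and acetabulum point cloud, a fitted femoral head sphere
and the femoral neck/shaft axes, this module reslices the hip along a stack
of planes parallel to the alpha plane (the plane through the head centre
containing the neck and shaft axes, emulating the oblique imaging stack),
finds in each slice the onset of deviation from sphericity on the femoral
head-neck contour and the end of the acetabular rim, and reports the beta
angle -- the angle at the head centre between the rim ray and the onset ray.
Positive beta means clearance between onset and rim; negative beta means the
aspherical region sits under acetabular coverage (overlap / impingement).

Angular convention inside a section ("marching coordinate" phi): sections
are parameterised by the angle around the projected head centre, with phi = 0
at the direction opposite the projected neck axis (deepest inside the
acetabulum) and phi increasing toward the neck (phi = pi) through the +v half
plane of the section basis (v = normal x neck-direction). Fixing the basis to
the neck projection makes onset/rim/beta signs reproducible without manual
input and invariant under rigid motion of the whole scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InputError, NoMeasurementError
from .geometry import (
    Axis,
    Plane,
    PlaneBasis,
    PointCloud,
    RigidTransform,
    SphereFit,
    plane_basis,
    slice_by_plane,
    wrap_angle_deg,
    _unit,
)

DEFAULT_SPACING = 2.5       # mm between adjacent reslice planes
DEFAULT_HALF_THICKNESS = 0.5  # mm slab half-thickness ("within 0.5 mm" of a plane)
DEFAULT_TOLERANCE = 0.5     # mm above fitted radius counted as aspherical
DEFAULT_CONTOUR_BAND = 2.5  # mm radial band above the sphere treated as head-neck contour
MIN_AXIS_SEPARATION_DEG = 5.0

_RUN_GUARD = 3  # consecutive supra-threshold points required for an onset


def build_alpha_plane(head_fit: SphereFit, neck_axis: Axis, shaft_axis: Axis) -> Plane:
    """Alpha plane: through the head centre, normal = unit(neck x shaft).

    The plane contains the neck axis direction (and the shaft direction), as
    in standard alpha-angle imaging of the head-neck contour.
    """
    n = np.cross(neck_axis.direction, shaft_axis.direction)
    sin_sep = np.linalg.norm(n)
    if sin_sep < np.sin(np.radians(MIN_AXIS_SEPARATION_DEG)):
        raise DegenerateGeometryError(
            "neck and shaft axes are near-parallel (< 5 deg); alpha plane undefined"
        )
    return Plane(head_fit.center, n / sin_sep)


@dataclass(frozen=True)
class AlphaPlaneStack:
    """Planes parallel to the alpha plane at k * spacing, k in [-count, count]."""

    base_plane: Plane
    spacing: float = DEFAULT_SPACING
    half_thickness: float = DEFAULT_HALF_THICKNESS
    count_each_side: int = 0

    def __post_init__(self):
        if not self.spacing > 0:
            raise InputError("spacing must be positive")
        if not self.half_thickness > 0:
            raise InputError("half_thickness must be positive")
        if self.half_thickness > self.spacing / 2:
            raise InputError("half_thickness must not exceed spacing/2 (overlapping slabs)")
        if self.count_each_side < 0:
            raise InputError("count_each_side must be >= 0")

    def offsets(self) -> np.ndarray:
        k = np.arange(-self.count_each_side, self.count_each_side + 1)
        return k * self.spacing

    def planes(self) -> list[tuple[int, Plane]]:
        return [
            (int(k), self.base_plane.offset(float(k * self.spacing)))
            for k in range(-self.count_each_side, self.count_each_side + 1)
        ]


def build_plane_stack(
    base: Plane,
    spacing: float = DEFAULT_SPACING,
    count_each_side: int = 0,
    half_thickness: float = DEFAULT_HALF_THICKNESS,
) -> AlphaPlaneStack:
    return AlphaPlaneStack(base, spacing, half_thickness, count_each_side)


def default_count_each_side(head_radius: float, spacing: float = DEFAULT_SPACING) -> int:
    """Stack half-count spanning the fitted head diameter: ceil(radius/spacing)."""
    return int(np.ceil(head_radius / spacing))


@dataclass(frozen=True)
class SectionContour:
    """One reslice plane's worth of 2D contour data.

    `head_radius` is the radius of the fitted head sphere's circle in this
    plane, sqrt(R^2 - d^2) at offset d (equal to the fitted radius on the mid
    plane). `femur_r3d` holds each femur point's 3D distance from the fitted
    head centre, the quantity tested against R + tolerance for asphericity.
    """

    plane_index: int
    femur_points_2d: np.ndarray
    acetabulum_points_2d: np.ndarray
    head_center_2d: np.ndarray
    head_radius: float
    sphere_radius: float
    femur_r3d: np.ndarray
    basis: PlaneBasis
    usable: bool

    def phi(self, points_2d: np.ndarray) -> np.ndarray:
        """Marching angle of 2D points about the projected head centre, radians.

        0 opposite the neck, +pi at the neck through the marching half-plane;
        values in (-pi, pi]."""
        p = np.atleast_2d(np.asarray(points_2d, dtype=float)) - self.head_center_2d
        theta = np.arctan2(p[:, 1], p[:, 0])  # u = projected neck direction
        phi = np.pi - theta
        return np.where(phi > np.pi, phi - 2 * np.pi, phi)


MIN_FEMUR_POINTS = 10
MIN_ACETABULUM_POINTS = 3


def extract_section(
    femur: PointCloud,
    acetabulum: PointCloud,
    plane: Plane,
    half_thickness: float,
    head_fit: SphereFit,
    neck_axis: Axis,
    plane_index: int = 0,
) -> SectionContour:
    """Slice both bones by the slab around `plane` and project to 2D.

    The in-plane basis u is the projected neck direction so the marching
    coordinate is intrinsic to the anatomy. Sections with fewer than 10 femur
    or 3 acetabulum points, or whose plane misses the head sphere, are flagged
    unusable rather than raising.
    """
    fem = slice_by_plane(femur, plane, half_thickness)
    ace = slice_by_plane(acetabulum, plane, half_thickness)
    d = float(plane.signed_distance(head_fit.center)[0])
    r_eff_sq = head_fit.radius**2 - d**2

    neck_in_plane = neck_axis.direction - (neck_axis.direction @ plane.normal) * plane.normal
    if np.linalg.norm(neck_in_plane) < 1e-9:
        raise DegenerateGeometryError("neck axis is perpendicular to the section plane")
    basis = plane_basis(plane, u_hint=neck_in_plane)

    head_2d = basis.to_2d(head_fit.center)[0]
    fem_2d = basis.to_2d(fem.points) if len(fem) else np.empty((0, 2))
    ace_2d = basis.to_2d(ace.points) if len(ace) else np.empty((0, 2))
    fem_r3d = (
        np.linalg.norm(fem.points - head_fit.center, axis=1) if len(fem) else np.empty(0)
    )
    usable = (
        len(fem) >= MIN_FEMUR_POINTS
        and len(ace) >= MIN_ACETABULUM_POINTS
        and r_eff_sq > 0
    )
    return SectionContour(
        plane_index=plane_index,
        femur_points_2d=fem_2d,
        acetabulum_points_2d=ace_2d,
        head_center_2d=head_2d,
        head_radius=float(np.sqrt(max(r_eff_sq, 0.0))),
        sphere_radius=head_fit.radius,
        femur_r3d=fem_r3d,
        basis=basis,
        usable=bool(usable),
    )


def find_asphericity_onset(
    section: SectionContour,
    tolerance: float = DEFAULT_TOLERANCE,
    contour_band: float = DEFAULT_CONTOUR_BAND,
) -> np.ndarray | None:
    """First femoral contour point deviating from the fitted sphere.

    Femur points on the marching path (phi in [0, pi]) within `contour_band`
    millimetres of the fitted sphere surface -- the head-neck contour;
    structures farther out, such as the shaft or trochanter silhouette, are
    not part of the sphericity march -- are ordered angularly from
    deepest-in-cup toward the neck. The onset is the first point whose 3D
    distance from the head centre exceeds fitted radius + tolerance AND that
    starts a run of at least 3 consecutive supra-threshold points (noise
    guard). Returns the 2D point, or None when the contour stays spherical
    through the slab (no-onset: the plane is non-informative).
    """
    if not section.usable:
        raise InputError("section flagged unusable")
    if contour_band <= tolerance:
        raise InputError("contour_band must exceed tolerance")
    phi = section.phi(section.femur_points_2d)
    on_path = (phi >= 0.0) & (
        section.femur_r3d <= section.sphere_radius + contour_band
    )
    if not np.any(on_path):
        return None
    order = np.argsort(phi[on_path])
    pts = section.femur_points_2d[on_path][order]
    supra = (section.femur_r3d[on_path][order]) > (section.sphere_radius + tolerance)
    if len(supra) < _RUN_GUARD:
        return None
    run = 0
    for i, s in enumerate(supra):
        run = run + 1 if s else 0
        if run == _RUN_GUARD:
            return pts[i - _RUN_GUARD + 1]
    return None


def find_rim_point(section: SectionContour) -> np.ndarray:
    """Acetabular rim endpoint on the head-neck side: the acetabular section
    point with the largest marching angle about the head centre."""
    if not section.usable:
        raise InputError("section flagged unusable")
    if len(section.acetabulum_points_2d) == 0:
        raise NoMeasurementError("empty acetabular contour in section")
    phi = section.phi(section.acetabulum_points_2d)
    return section.acetabulum_points_2d[int(np.argmax(phi))]


def beta_angle_in_plane(section: SectionContour, onset: np.ndarray, rim: np.ndarray) -> float:
    """Signed beta angle (degrees) at the head centre from the rim ray to the
    onset ray; positive when the onset lies beyond the rim along the marching
    direction (clearance), negative under coverage (overlap)."""
    for name, p in (("onset", onset), ("rim", rim)):
        if np.linalg.norm(np.asarray(p, float) - section.head_center_2d) < 1e-9:
            raise DegenerateGeometryError(f"{name} point coincides with the head centre")
    phi_on = section.phi(np.asarray(onset, float))[0]
    phi_rim = section.phi(np.asarray(rim, float))[0]
    return wrap_angle_deg(np.degrees(phi_on - phi_rim))


@dataclass(frozen=True)
class BetaResult:
    """Per-plane beta angles and the overall minimum."""

    per_plane: tuple  # (plane_index, beta_deg, onset_2d, rim_2d)
    min_beta: float
    min_plane_index: int
    excluded_planes: tuple = ()  # (plane_index, reason)


def min_beta(
    femur: PointCloud,
    acetabulum: PointCloud,
    stack: AlphaPlaneStack,
    head_fit: SphereFit,
    neck_axis: Axis,
    tolerance: float = DEFAULT_TOLERANCE,
    contour_band: float = DEFAULT_CONTOUR_BAND,
) -> BetaResult:
    """Beta for every usable plane of the stack, plus the minimum.

    Planes flagged unusable (too few points / plane misses the head) or with
    no asphericity onset are excluded from the minimum and recorded with a
    reason. Raises :class:`NoMeasurementError` when no plane yields a beta.
    """
    per_plane = []
    excluded = []
    for idx, plane in stack.planes():
        section = extract_section(
            femur, acetabulum, plane, stack.half_thickness, head_fit, neck_axis, plane_index=idx
        )
        if not section.usable:
            excluded.append((idx, "unusable"))
            continue
        onset = find_asphericity_onset(section, tolerance, contour_band)
        if onset is None:
            excluded.append((idx, "no-onset"))
            continue
        try:
            rim = find_rim_point(section)
        except NoMeasurementError:
            excluded.append((idx, "no-rim"))
            continue
        beta = beta_angle_in_plane(section, onset, rim)
        per_plane.append((idx, beta, onset, rim))
    if not per_plane:
        raise NoMeasurementError("no usable plane produced a beta angle")
    betas = [b for _, b, _, _ in per_plane]
    k = int(np.argmin(betas))
    return BetaResult(
        per_plane=tuple(per_plane),
        min_beta=float(betas[k]),
        min_plane_index=int(per_plane[k][0]),
        excluded_planes=tuple(excluded),
    )


def adjust_center_distance(
    femur: PointCloud,
    head_fit: SphereFit,
    acetabulum_center: np.ndarray,
    reference_distance: float,
) -> PointCloud:
    """Translate the femur along the head-to-acetabulum line so the
    centre-to-centre distance equals `reference_distance` (rotation unchanged),
    matching the supine-scan joint spacing."""
    acet = np.asarray(acetabulum_center, dtype=float).reshape(3)
    offset = head_fit.center - acet
    dist = np.linalg.norm(offset)
    if dist < 1e-9:
        raise DegenerateGeometryError(
            "head and acetabulum centres coincide; adjustment direction undefined"
        )
    direction = offset / dist
    translation = (reference_distance - dist) * direction
    return PointCloud(femur.points + translation, label=femur.label)


def place_models_at_frame(
    femur: PointCloud,
    acetabulum: PointCloud,
    supine_to_frame_femur: RigidTransform,
    supine_to_frame_pelvis: RigidTransform,
    reference_distance: float,
    head_fit: SphereFit,
    acetabulum_center: np.ndarray,
) -> tuple[PointCloud, PointCloud]:
    """Pose the supine bone models at a motion frame.

    The pelvis transform moves the acetabulum, the femur transform moves the
    femur, then the femur is translated along the centre-to-centre line to
    restore `reference_distance`. `head_fit` and `acetabulum_center` are given
    in the supine frame and transformed internally.
    """
    fem = femur.transformed(supine_to_frame_femur)
    ace = acetabulum.transformed(supine_to_frame_pelvis)
    head_posed = SphereFit(
        supine_to_frame_femur.apply(head_fit.center), head_fit.radius, head_fit.rms_residual
    )
    acet_posed = supine_to_frame_pelvis.apply(np.asarray(acetabulum_center, float))
    fem = adjust_center_distance(fem, head_posed, acet_posed, reference_distance)
    return fem, ace
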