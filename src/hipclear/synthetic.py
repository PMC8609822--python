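"""Parametric hip phantom and simulated motion with analytic ground truth.

The phantom stands in for segmented subject anatomy: a spherical femoral
head, a neck cylinder meeting the sphere at the analytic sphere-cylinder
junction, a shaft stub, an optional Gaussian cam bump on the head-neck
contour, and an acetabular cup (spherical-cap shell) with a defined rim.
Landmarks (ASIS/PSIS, epicondyles) sit on rigid pelvis/femur bodies so the
whole measurement chain -- sphere fit, frames, calibration, tracking,
reslicing, beta -- can run end to end against closed-form expectations.

Geometry is laid out in a neutral standing pose for a RIGHT hip with the
femoral head centre at the origin and world axes equal to both anatomical
frames: x anterior, y superior, z lateral (subject's right). The femoral
neck points infero-laterally in the y-z plane, the shaft points inferiorly,
so the alpha plane (normal = neck x shaft) is the x = 0 plane and reslice
offsets sweep the anterior-posterior direction.

The analytic functions here are an independent oracle: they never touch the
point-cloud pipeline and compute onset/rim/beta from the surface equations
(sphere, cylinder, Gaussian bump, spherical cap) directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .clearance import DEFAULT_HALF_THICKNESS, DEFAULT_SPACING, DEFAULT_TOLERANCE
from .errors import InputError
from .frames import HipJointAngles, LandmarkSet, hip_rotation_matrix
from .geometry import Axis, PointCloud, RigidTransform, wrap_angle_deg
from .mocap import MarkerTrajectories

PELVIS_MARKER_LABELS = ("RASIS", "LASIS", "RPSIS", "LPSIS")
# thigh segment: 4-marker cluster plate plus greater trochanter and lateral
# epicondyle (the epicondyle marker stays on during trials; the long lever
# conditions axial rotation)
THIGH_MARKER_LABELS = ("THI1", "THI2", "THI3", "THI4", "GTRO", "LEPI")


@dataclass(frozen=True)
class HipPhantomSpec:
    """Parameters of the hip phantom (mm / degrees / points per mm^2)."""

    head_radius: float = 25.0
    neck_radius: float = 14.0
    neck_length: float = 55.0
    neck_shaft_angle: float = 130.0
    cam_amplitude: float = 0.0
    cam_center_angle: float = 45.0   # deg from the neck axis, marching side
    cam_width: float = 10.0          # Gaussian sigma, deg
    cup_coverage_angle: float = 65.0  # deg from the cup pole to the rim
    cup_clearance: float = 1.0       # mm joint-space between head and cup
    cup_center_offset: float = 1.5   # mm cup centre offset toward the pole
    point_density: float = 2.0       # points per mm^2
    seed: int = 0

    def __post_init__(self):
        if not (self.head_radius > self.neck_radius > 0):
            raise InputError("need head_radius > neck_radius > 0")
        if self.cam_amplitude < 0:
            raise InputError("cam_amplitude must be >= 0")
        if not (0 < self.cup_coverage_angle < 180):
            raise InputError("cup_coverage_angle must be in (0, 180)")
        if not self.point_density > 0:
            raise InputError("point_density must be positive")
        if not self.cup_center_offset > 0:
            raise InputError("cup_center_offset must be positive (centres may not coincide)")
        if not 0 < self.neck_shaft_angle < 180:
            raise InputError("neck_shaft_angle must be in (0, 180)")
        tj = np.degrees(np.arcsin(self.neck_radius / self.head_radius))
        if self.neck_length <= self.head_radius * np.cos(np.radians(tj)):
            raise InputError("neck_length must extend past the sphere-cylinder junction")


@dataclass(frozen=True)
class HipPhantom:
    """Generated phantom: clouds, landmarks, axes and analytic values."""

    spec: HipPhantomSpec
    femur: PointCloud
    head: PointCloud           # head-sphere subset away from the cam (for sphere fitting)
    acetabulum: PointCloud
    landmarks: LandmarkSet
    neck_axis: Axis
    shaft_axis: Axis
    analytic: dict             # junction_angle, cup_edge_angle, beta_true (deg)

    @property
    def head_center(self) -> np.ndarray:
        return np.zeros(3)

    @property
    def cup_center(self) -> np.ndarray:
        return self.landmarks["acetabulum_center"]


# ---------------------------------------------------------------------------
# phantom geometry helpers (femur frame, neutral pose)
# ---------------------------------------------------------------------------

def _directions(spec: HipPhantomSpec):
    g = np.radians(180.0 - spec.neck_shaft_angle)
    d_neck = np.array([0.0, -np.cos(g), np.sin(g)])   # head centre -> neck, infero-lateral
    d_shaft = np.array([0.0, -1.0, 0.0])
    n0 = np.cross(d_neck, d_shaft)
    n0 /= np.linalg.norm(n0)                           # = +x
    v_march = np.cross(n0, d_neck)                     # marching half-plane direction
    pole = -d_neck                                     # cup pole, supero-medial
    return d_neck, d_shaft, n0, v_march, pole


def _cam_direction(spec: HipPhantomSpec) -> np.ndarray:
    d_neck, _, _, v_march, _ = _directions(spec)
    tc = np.radians(spec.cam_center_angle)
    return np.cos(tc) * d_neck + np.sin(tc) * v_march


_JITTER_FRAC = 0.25  # tangential jitter as a fraction of the lattice spacing


def _fibonacci_directions(n: int, rng) -> np.ndarray:
    """Quasi-regular unit directions (golden-spiral lattice) with a small
    tangential jitter.

    Segmented bone surfaces from gridded images are near-regularly sampled;
    a regular lattice keeps the largest angular gap close to the mean spacing
    (i.i.d. uniform sampling would leave Poisson gaps several times larger).
    """
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    th = golden * i
    dirs = np.column_stack([r * np.cos(th), r * np.sin(th), z])
    # jitter: random tangent displacement of ~_JITTER_FRAC lattice spacings
    spacing = np.sqrt(4.0 * np.pi / n)
    t = rng.normal(0.0, _JITTER_FRAC * spacing, (n, 3))
    t -= dirs * np.einsum("ij,ij->i", t, dirs)[:, None]
    dirs = dirs + t
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def _cylinder_grid(radius: float, t_min: float, t_max: float, density: float, rng):
    """Jittered regular grid on a cylinder lateral surface; returns (t, alpha)."""
    delta = 1.0 / np.sqrt(density)
    n_a = max(8, int(round(2 * np.pi * radius / delta)))
    n_t = max(4, int(round((t_max - t_min) / delta)))
    a = (np.arange(n_a) + 0.5) * 2 * np.pi / n_a
    t = t_min + (np.arange(n_t) + 0.5) * (t_max - t_min) / n_t
    tt, aa = np.meshgrid(t, a, indexing="ij")
    tt = tt + rng.uniform(-0.4, 0.4, tt.shape) * (t_max - t_min) / n_t
    aa = aa + rng.uniform(-0.4, 0.4, aa.shape) * 2 * np.pi / n_a
    return tt.ravel(), aa.ravel()


def generate_phantom(spec: HipPhantomSpec) -> HipPhantom:
    """Sample the phantom surfaces at `spec.point_density`, deterministically
    in `spec.seed`; analytic values are independent of the seed."""
    rng = np.random.default_rng(spec.seed)
    R, rn = spec.head_radius, spec.neck_radius
    d_neck, d_shaft, n0, v_march, pole = _directions(spec)
    theta_j = np.arcsin(rn / R)
    t_j = R * np.cos(theta_j)

    # femoral head: sphere minus the neck cap, with optional cam bump
    sphere_area = 4 * np.pi * R**2
    n_full = max(400, int(spec.point_density * sphere_area))
    w = _fibonacci_directions(n_full, rng)
    w = w[w @ d_neck < np.cos(theta_j)]  # drop the neck cap
    radial = np.full(len(w), float(R))
    u_cam = _cam_direction(spec)
    if spec.cam_amplitude > 0:
        sig = np.radians(spec.cam_width)
        delta = np.arccos(np.clip(w @ u_cam, -1, 1))
        radial = radial + spec.cam_amplitude * np.exp(-(delta**2) / (2 * sig**2))
    head_pts = w * radial[:, None]

    # clean head subset for sphere fitting: sphere samples well away from cam
    if spec.cam_amplitude > 0:
        delta = np.arccos(np.clip(w @ u_cam, -1, 1))
        clean = head_pts[delta > 3 * np.radians(spec.cam_width)]
    else:
        clean = head_pts
    head_cloud = PointCloud(clean, label="femoral_head")

    # neck cylinder from the junction to neck_length
    t, alpha = _cylinder_grid(rn, t_j, spec.neck_length, spec.point_density, rng)
    neck_pts = (
        np.outer(t, d_neck)
        + np.outer(rn * np.cos(alpha), v_march)
        + np.outer(rn * np.sin(alpha), n0)
    )

    # shaft stub
    r_shaft = 1.6 * rn
    shaft_len = 80.0
    shaft_origin = spec.neck_length * d_neck
    s, alpha = _cylinder_grid(r_shaft, 0.0, shaft_len, spec.point_density, rng)
    w1 = np.cross(d_shaft, n0)
    shaft_pts = (
        shaft_origin
        + np.outer(s, d_shaft)
        + np.outer(r_shaft * np.cos(alpha), w1)
        + np.outer(r_shaft * np.sin(alpha), n0)
    )

    femur_cloud = PointCloud(np.vstack([head_pts, neck_pts, shaft_pts]), label="femur")

    # acetabular cup: spherical-cap shell around the pole
    R_cup = R + spec.cup_clearance
    cov = np.radians(spec.cup_coverage_angle)
    c_cup = spec.cup_center_offset * pole
    n_cup_full = max(400, int(spec.point_density * 4 * np.pi * R_cup**2))
    wc = _fibonacci_directions(n_cup_full, rng)
    wc = wc[wc @ pole >= np.cos(cov)]
    cup_cloud = PointCloud(c_cup + R_cup * wc, label="acetabulum")

    landmarks = LandmarkSet(
        {
            "RASIS": np.array([65.0, 75.0, 30.0]),
            "LASIS": np.array([65.0, 75.0, -210.0]),
            "RPSIS": np.array([-80.0, 75.0, -40.0]),
            "LPSIS": np.array([-80.0, 75.0, -140.0]),
            "medial_epicondyle": np.array([0.0, -400.0, -45.0]),
            "lateral_epicondyle": np.array([0.0, -400.0, 45.0]),
            "acetabulum_center": c_cup,
            "femoral_head_center": np.zeros(3),
        }
    )
    neck_axis = Axis(np.zeros(3), d_neck)
    shaft_axis = Axis(shaft_origin, d_shaft)

    analytic = {
        "junction_angle": float(np.degrees(theta_j)),
        "cup_edge_angle": float(np.degrees(np.pi - _rim_phi(spec, pose=None, d=0.0))),
        "beta_true": None,  # filled below
    }
    onset_ideal = np.degrees(_ideal_onset_angle(spec, DEFAULT_TOLERANCE))
    analytic["beta_true"] = float(analytic["cup_edge_angle"] - onset_ideal)

    return HipPhantom(
        spec=spec,
        femur=femur_cloud,
        head=head_cloud,
        acetabulum=cup_cloud,
        landmarks=landmarks,
        neck_axis=neck_axis,
        shaft_axis=shaft_axis,
        analytic=analytic,
    )


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------

def _cam_tolerance_halfwidth(spec: HipPhantomSpec, tolerance: float) -> float | None:
    """Angular half-width (rad) of the cam region exceeding `tolerance` above
    the sphere, from the Gaussian bump crossing the tolerance level."""
    if spec.cam_amplitude <= tolerance:
        return None
    sig = np.radians(spec.cam_width)
    return float(sig * np.sqrt(2 * np.log(spec.cam_amplitude / tolerance)))


def _ideal_onset_angle(spec: HipPhantomSpec, tolerance: float) -> float:
    """Spec-level onset angle from the neck axis (rad): the sphere-cylinder
    junction, or the cam's tolerance-crossing rising edge if it reaches
    farther toward the cup."""
    theta_j = np.arcsin(spec.neck_radius / spec.head_radius)
    half = _cam_tolerance_halfwidth(spec, tolerance)
    if half is None:
        return float(theta_j)
    return float(max(theta_j, np.radians(spec.cam_center_angle) + half))


def _pose_cup(spec: HipPhantomSpec, pose: RigidTransform | None):
    """Cup centre and pole expressed in the femur frame for a relative pose
    (pose maps pelvis-fixed geometry into femur coordinates)."""
    _, _, _, _, pole = _directions(spec)
    c_cup = spec.cup_center_offset * pole
    if pose is None:
        return c_cup, pole
    return pose.apply(c_cup), pose.rotation @ pole


def _phi_of_2d(x, y):
    phi = np.pi - np.arctan2(y, x)
    return np.where(phi > np.pi, phi - 2 * np.pi, phi)


def _rim_phi(
    spec: HipPhantomSpec,
    pose: RigidTransform | None,
    d: float,
    half_thickness: float = 0.0,
    n_grid: int = 2048,
) -> float:
    """Largest marching angle of the cup surface within the slab at offset d.

    Enumerates the cap boundary condition on the sphere/plane intersection
    circle for several sub-offsets across the slab (projection onto the
    section plane does not depend on the sub-offset). Returns NaN when the
    slab misses the cup.
    """
    d_neck, _, n0, v_march, _ = _directions(spec)
    u, v = d_neck, v_march
    R_cup = spec.head_radius + spec.cup_clearance
    cov = np.radians(spec.cup_coverage_angle)
    c_cup, pole = _pose_cup(spec, pose)

    if half_thickness > 0:
        sub = np.linspace(d - half_thickness, d + half_thickness, 9)
    else:
        sub = np.array([d])
    psi = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    best = np.nan
    for dp in sub:
        h_c = dp - float(c_cup @ n0)
        rho_sq = R_cup**2 - h_c**2
        if rho_sq <= 0:
            continue
        rho = np.sqrt(rho_sq)
        q0 = c_cup + h_c * n0
        qx = q0 @ u + rho * np.cos(psi)
        qy = q0 @ v + rho * np.sin(psi)
        cap = (
            h_c * (n0 @ pole)
            + rho * np.cos(psi) * (u @ pole)
            + rho * np.sin(psi) * (v @ pole)
        ) >= R_cup * np.cos(cov)
        if not np.any(cap):
            continue
        phi = _phi_of_2d(qx[cap], qy[cap])
        m = float(np.max(phi))
        if np.isnan(best) or m > best:
            best = m
    return best


def _onset_phi(spec: HipPhantomSpec, d: float, half_thickness: float, tolerance: float) -> float:
    """Marching angle of the asphericity onset in the slab at offset d (NaN if
    the contour stays spherical through the slab).

    Two candidate onsets exist: the sphere-cylinder junction region (points on
    the neck cylinder whose 3D distance from the head centre first exceeds
    R + tolerance) and the cam bump's tolerance-crossing boundary. The onset
    is whichever lies farther from the neck (first along the march)."""
    R, rn = spec.head_radius, spec.neck_radius
    h = half_thickness
    s_m = max(abs(d - h), abs(d + h))  # worst (deepest) out-of-plane slab coordinate
    candidates = []

    # neck cylinder: out-of-plane coordinate of a cylinder point is rn*sin(a).
    # A detected run needs the contour supra-threshold across the whole slab
    # depth, so the binding depth is the slab edge farthest from the axis plane.
    if s_m <= rn:
        w_perp = np.sqrt(rn**2 - s_m**2)
        t_star = np.sqrt((R + tolerance) ** 2 - rn**2)
        if t_star <= spec.neck_length and w_perp > 1e-12:
            candidates.append(np.arctan2(w_perp, t_star))

    # cam bump: boundary circle at radius R + tolerance, same worst-depth rule
    half_cam = _cam_tolerance_halfwidth(spec, tolerance)
    if half_cam is not None:
        rb = R + tolerance
        s_cam = s_m / rb
        if s_cam < 1.0:
            sin_part = np.sqrt(1 - s_cam**2)
            if np.cos(half_cam) <= sin_part:
                eta = np.arccos(np.cos(half_cam) / sin_part)
                candidates.append(np.radians(spec.cam_center_angle) + eta)

    if not candidates:
        return np.nan
    theta_on = max(candidates)  # largest angle from the neck = first along march
    return float(np.pi - theta_on)


def analytic_beta_in_plane(
    spec: HipPhantomSpec,
    pose: RigidTransform | None = None,
    d: float = 0.0,
    half_thickness: float = DEFAULT_HALF_THICKNESS,
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Closed-form beta (deg) for the slab at offset d and relative pose
    (pose = femur-frame coordinates of pelvis-fixed geometry)."""
    phi_on = _onset_phi(spec, d, half_thickness, tolerance)
    phi_rim = _rim_phi(spec, pose, d, half_thickness)
    if np.isnan(phi_on) or np.isnan(phi_rim):
        return np.nan
    return wrap_angle_deg(np.degrees(phi_on - phi_rim))


def analytic_min_beta(
    spec: HipPhantomSpec,
    pose: RigidTransform | None = None,
    spacing: float = DEFAULT_SPACING,
    count_each_side: int | None = None,
    half_thickness: float = DEFAULT_HALF_THICKNESS,
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Analytic minimum beta (deg) over the reslice stack; NaN if no plane is
    informative. Independent oracle for the point-cloud pipeline."""
    if count_each_side is None:
        count_each_side = int(np.ceil(spec.head_radius / spacing))
    betas = [
        analytic_beta_in_plane(spec, pose, k * spacing, half_thickness, tolerance)
        for k in range(-count_each_side, count_each_side + 1)
    ]
    betas = [b for b in betas if not np.isnan(b)]
    return float(min(betas)) if betas else float("nan")


# ---------------------------------------------------------------------------
# simulated motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionScenario:
    """A squat or FADIR trial: half-cosine ramp from standing to peak angles."""

    kind: str = "squat"
    peak_angles: HipJointAngles = field(
        default_factory=lambda: HipJointAngles(85.0, 5.0, 5.0, side="right")
    )
    duration: float = 2.0
    rate: float = 60.0
    marker_noise_sd: float = 0.0
    seed: int = 0
    pelvis_drop: float = 250.0  # mm vertical pelvis descent at peak (squat only)
    pelvis_tilt: float = -8.0   # deg posterior pelvic rotation at peak

    def __post_init__(self):
        if self.kind not in ("squat", "fadir"):
            raise InputError("scenario kind must be 'squat' or 'fadir'")
        if not self.rate > 0:
            raise InputError("rate must be positive")
        if self.duration < 0:
            raise InputError("duration must be >= 0")


@dataclass(frozen=True)
class MotionGroundTruth:
    angles: tuple            # HipJointAngles per frame
    pelvis_transforms: tuple  # RigidTransform per frame (standing -> frame)
    femur_transforms: tuple
    beta_midplane: np.ndarray  # analytic mid-plane beta per frame (deg)


def _thigh_cluster_points() -> np.ndarray:
    return np.array(
        [
            [15.0, -140.0, 65.0],   # THI1..THI4: anterolateral cluster plate
            [48.0, -165.0, 12.0],
            [10.0, -235.0, 55.0],
            [45.0, -255.0, 15.0],
            [-8.0, -15.0, 62.0],    # GTRO: greater trochanter
            [0.0, -400.0, 48.0],    # LEPI: lateral femoral epicondyle (skin)
        ]
    )


def simulate_motion(
    scenario: MotionScenario, phantom: HipPhantom
) -> tuple[MarkerTrajectories, MotionGroundTruth]:
    """Marker trajectories plus rigid-body ground truth for a scenario.

    Frame 0 is the standing reference (zero hip angles). The femur rotates
    about the head centre by the Grood-Suntay forward construction of the
    ramped angle triple; the pelvis translates/tilts slightly (squat) so the
    tracking problem is non-trivial. Marker noise is isotropic Gaussian,
    independent per frame and marker.
    """
    rng = np.random.default_rng(scenario.seed)
    n_frames = max(1, int(round(scenario.duration * scenario.rate)) + 1)
    ramp = (
        0.5 * (1 - np.cos(np.pi * np.linspace(0, 1, n_frames)))
        if n_frames > 1
        else np.zeros(1)
    )
    side = scenario.peak_angles.side
    peak = scenario.peak_angles.as_array()

    pelvis_pts = np.array([phantom.landmarks[l] for l in PELVIS_MARKER_LABELS])
    thigh_pts = _thigh_cluster_points()
    labels = PELVIS_MARKER_LABELS + THIGH_MARKER_LABELS

    angles_list, t_p_list, t_f_list = [], [], []
    positions = np.empty((n_frames, len(labels), 3))
    drop = scenario.pelvis_drop if scenario.kind == "squat" else 0.0

    for f, r in enumerate(ramp):
        tri = peak * r
        ang = HipJointAngles(tri[0], tri[1], tri[2], side=side)
        R_joint = hip_rotation_matrix(ang)
        tilt = np.radians(scenario.pelvis_tilt * r)
        ct, st = np.cos(tilt), np.sin(tilt)
        R_p = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
        t_p = np.array([0.0, -drop * r, 0.0])
        T_p = RigidTransform(R_p, t_p)
        T_f = RigidTransform(R_p @ R_joint, t_p)  # head centre rides with the pelvis
        angles_list.append(ang)
        t_p_list.append(T_p)
        t_f_list.append(T_f)
        positions[f, : len(pelvis_pts)] = T_p.apply(pelvis_pts)
        positions[f, len(pelvis_pts):] = T_f.apply(thigh_pts)

    if scenario.marker_noise_sd > 0:
        positions = positions + rng.normal(0, scenario.marker_noise_sd, positions.shape)

    beta_mid = np.array(
        [
            analytic_beta_in_plane(
                phantom.spec, pose=t_f.inverse() @ t_p, d=0.0
            )
            for t_p, t_f in zip(t_p_list, t_f_list)
        ]
    )
    motion = MarkerTrajectories(labels, positions, rate=scenario.rate)
    truth = MotionGroundTruth(
        angles=tuple(angles_list),
        pelvis_transforms=tuple(t_p_list),
        femur_transforms=tuple(t_f_list),
        beta_midplane=beta_mid,
    )
    return motion, truth


PRESETS = {
    "control": HipPhantomSpec(cam_amplitude=0.0),
    "cam-mild": HipPhantomSpec(cam_amplitude=1.5),
    "cam-moderate": HipPhantomSpec(cam_amplitude=3.0),
    "pincer": HipPhantomSpec(cam_amplitude=0.0, cup_coverage_angle=85.0),
}


def sampling_step_deg(spec: HipPhantomSpec) -> float:
    """Mean angular spacing of surface samples seen from the head centre
    (degrees): inter-point distance 1/sqrt(density) at the head radius."""
    return float(np.degrees(1.0 / (np.sqrt(spec.point_density) * spec.head_radius)))


def sample_validation_case(seed: int):
    """One random phantom + trial of the synthetic validation study.

    Anatomy spans adult hip ranges (head radius 22-28 mm, neck 52-60 % of the
    head, neck-shaft 125-135 deg, cup coverage 60-75 deg); half the draws
    carry a cam of 1.5-4 mm. Trials alternate squatting and sitting FADIR
    with peak angles in the ranges the two maneuvers reach, ramped over 1.5 s
    at 40 Hz with noise-free markers. Returns (spec, scenario, target_frame)
    where target_frame plays the role of the statically imaged posture.
    """
    rng = np.random.default_rng(seed)
    head_r = rng.uniform(22.0, 28.0)
    has_cam = rng.random() < 0.5
    spec = HipPhantomSpec(
        head_radius=head_r,
        neck_radius=head_r * rng.uniform(0.52, 0.60),
        neck_shaft_angle=rng.uniform(125.0, 135.0),
        cam_amplitude=rng.uniform(1.5, 4.0) if has_cam else 0.0,
        cam_center_angle=rng.uniform(42.0, 55.0),
        cam_width=rng.uniform(8.0, 14.0),
        cup_coverage_angle=rng.uniform(60.0, 75.0),
        cup_clearance=rng.uniform(0.6, 1.4),
        seed=int(rng.integers(2**31)),
    )
    if seed % 2 == 0:
        kind = "squat"
        peak = HipJointAngles(
            rng.uniform(65.0, 85.0), rng.uniform(-4.0, 8.0), rng.uniform(-4.0, 12.0)
        )
    else:
        kind = "fadir"
        peak = HipJointAngles(
            rng.uniform(80.0, 90.0), rng.uniform(4.0, 14.0), rng.uniform(10.0, 22.0)
        )
    scenario = MotionScenario(
        kind=kind, peak_angles=peak, duration=1.5, rate=40.0,
        marker_noise_sd=0.0, seed=int(rng.integers(2**31)),
    )
    target_frame = int(rng.integers(40, 61))
    return spec, scenario, target_frame


# ---------------------------------------------------------------------------
# fixture bundle I/O
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    path, phantom: HipPhantom, scenario: MotionScenario | None = None
) -> dict:
    """Write a phantom (and optionally a simulated trial) as plain-text files.

    Produces ascii PLY clouds, a landmark JSON (including the neck and shaft
    axes), a TRC marker file and a ground-truth CSV; re-reading reproduces the
    inputs at the written precision. Returns the file map."""
    from . import io as _io

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, cloud in (
        ("femur", phantom.femur),
        ("head", phantom.head),
        ("acetabulum", phantom.acetabulum),
    ):
        p = out / f"{name}.ply"
        _io.write_ply(p, cloud)
        files[name] = p
    lm_path = out / "landmarks.json"
    payload = {n: p.tolist() for n, p in phantom.landmarks.landmarks.items()}
    payload["_neck_axis"] = {
        "point": phantom.neck_axis.point.tolist(),
        "direction": phantom.neck_axis.direction.tolist(),
    }
    payload["_shaft_axis"] = {
        "point": phantom.shaft_axis.point.tolist(),
        "direction": phantom.shaft_axis.direction.tolist(),
    }
    payload["_analytic"] = phantom.analytic
    payload["_spec"] = asdict(phantom.spec)
    lm_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    files["landmarks"] = lm_path

    if scenario is not None:
        motion, truth = simulate_motion(scenario, phantom)
        trc = out / "motion.trc"
        _io.write_trc(trc, motion)
        files["motion"] = trc
        gt = out / "ground_truth.csv"
        rows = ["frame,flexion,adduction,internal_rotation,beta_midplane"]
        for i, (a, b) in enumerate(zip(truth.angles, truth.beta_midplane)):
            rows.append(
                f"{i},{a.flexion:.9f},{a.adduction:.9f},{a.internal_rotation:.9f},{b:.9f}"
            )
        gt.write_text("\n".join(rows) + "\n")
        files["ground_truth"] = gt
    return files
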