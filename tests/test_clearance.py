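"""Beta-angle clearance model against the phantom's analytic geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hipclear import (
    AlphaPlaneStack,
    Axis,
    DegenerateGeometryError,
    HipPhantomSpec,
    NoMeasurementError,
    Plane,
    PointCloud,
    RigidTransform,
    SphereFit,
    adjust_center_distance,
    analytic_beta_in_plane,
    beta_angle_in_plane,
    build_alpha_plane,
    build_plane_stack,
    extract_section,
    find_asphericity_onset,
    find_rim_point,
    generate_phantom,
    min_beta,
    place_models_at_frame,
)
from hipclear.clearance import default_count_each_side
from hipclear.errors import InputError


def sampling_step_deg(spec):
    """Mean angular spacing of surface samples seen from the head centre."""
    return np.degrees(1.0 / (np.sqrt(spec.point_density) * spec.head_radius))


HEAD = SphereFit([0.0, 0.0, 0.0], 25.0, 0.0)


class TestAlphaPlane:
    def test_orthogonal_axes(self):
        plane = build_alpha_plane(
            HEAD, Axis([0, 0, 0], [1, 0, 0]), Axis([0, 0, 0], [0, 1, 0])
        )
        assert np.allclose(plane.normal, [0, 0, 1])
        assert np.allclose(plane.point, HEAD.center)

    def test_five_degree_threshold(self):
        ok = Axis([0, 0, 0], [np.cos(np.radians(5.5)), np.sin(np.radians(5.5)), 0])
        build_alpha_plane(HEAD, Axis([0, 0, 0], [1, 0, 0]), ok)
        bad = Axis([0, 0, 0], [np.cos(np.radians(4.0)), np.sin(np.radians(4.0)), 0])
        with pytest.raises(DegenerateGeometryError):
            build_alpha_plane(HEAD, Axis([0, 0, 0], [1, 0, 0]), bad)

    def test_neck_direction_lies_in_plane(self, rng):
        for _ in range(20):
            neck = rng.normal(size=3)
            neck /= np.linalg.norm(neck)
            shaft = rng.normal(size=3)
            shaft /= np.linalg.norm(shaft)
            if abs(np.cross(neck, shaft) @ np.ones(3)) < 1e-3:
                continue
            if np.degrees(np.arcsin(np.linalg.norm(np.cross(neck, shaft)))) < 6:
                continue
            plane = build_alpha_plane(HEAD, Axis([0, 0, 0], neck), Axis([0, 0, 0], shaft))
            assert abs(plane.normal @ neck) < 1e-9


class TestPlaneStack:
    def test_offsets_count_two(self):
        stack = build_plane_stack(Plane([0, 0, 0], [0, 0, 1]), spacing=2.5, count_each_side=2)
        assert np.allclose(stack.offsets(), [-5.0, -2.5, 0.0, 2.5, 5.0])

    def test_count_zero_base_only(self):
        stack = build_plane_stack(Plane([0, 0, 0], [0, 0, 1]), count_each_side=0)
        assert len(stack.planes()) == 1

    def test_offsets_match_plane_positions(self):
        base = Plane([1.0, 2.0, 3.0], [0, 1, 0])
        stack = build_plane_stack(base, spacing=3.0, count_each_side=3, half_thickness=1.0)
        for (k, plane), off in zip(stack.planes(), stack.offsets()):
            assert plane.signed_distance(base.point + off * base.normal)[0] == pytest.approx(0, abs=1e-12)

    def test_overlapping_slabs_rejected(self):
        with pytest.raises(InputError):
            AlphaPlaneStack(Plane([0, 0, 0], [0, 0, 1]), spacing=2.5, half_thickness=1.5)


@pytest.fixture(scope="module")
def nocam_setup(phantom_nocam, head_fit_nocam):
    ph = phantom_nocam
    plane = build_alpha_plane(head_fit_nocam, ph.neck_axis, ph.shaft_axis)
    return ph, head_fit_nocam, plane


class TestExtractSection:
    def test_far_plane_unusable(self, nocam_setup):
        ph, fit, plane = nocam_setup
        far = Plane(plane.point + 500.0 * plane.normal, plane.normal)
        sec = extract_section(ph.femur, ph.acetabulum, far, 0.5, fit, ph.neck_axis)
        assert not sec.usable

    def test_midplane_head_circle_radius(self, nocam_setup):
        ph, fit, plane = nocam_setup
        sec = extract_section(ph.femur, ph.acetabulum, plane, 0.5, fit, ph.neck_axis)
        assert sec.usable
        assert sec.head_radius == pytest.approx(fit.radius, abs=1e-6)
        # on-sphere section points sit at the head radius within slab tolerance
        r2d = np.linalg.norm(sec.femur_points_2d - sec.head_center_2d, axis=1)
        on_sphere = np.abs(sec.femur_r3d - fit.radius) < 1e-6
        assert on_sphere.sum() > 50
        assert np.all(np.abs(r2d[on_sphere] - fit.radius) < 0.01)

    def test_slicing_matches_brute_force(self, nocam_setup, rng):
        ph, fit, plane = nocam_setup
        sec = extract_section(ph.femur, ph.acetabulum, plane, 0.5, fit, ph.neck_axis)
        expected = np.abs(plane.signed_distance(ph.femur.points)) <= 0.5
        assert len(sec.femur_points_2d) == expected.sum()


class TestOnset:
    def test_exact_circle_has_no_onset(self, nocam_setup):
        ph, fit, plane = nocam_setup
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        circle = np.column_stack(
            [np.zeros_like(th), fit.radius * np.cos(th), fit.radius * np.sin(th)]
        )
        sec = extract_section(
            PointCloud(circle), ph.acetabulum, plane, 0.5, fit, ph.neck_axis
        )
        assert find_asphericity_onset(sec) is None

    def test_junction_onset_angle(self, nocam_setup):
        """Onset on the no-cam phantom sits at the analytic crossing where the
        neck cylinder first exceeds radius + tolerance."""
        ph, fit, plane = nocam_setup
        spec = ph.spec
        sec = extract_section(ph.femur, ph.acetabulum, plane, 0.5, fit, ph.neck_axis)
        onset = find_asphericity_onset(sec)
        phi = np.degrees(sec.phi(onset))[0]
        w = np.sqrt(spec.neck_radius**2 - 0.5**2)
        t_star = np.sqrt((spec.head_radius + 0.5) ** 2 - spec.neck_radius**2)
        expected = 180.0 - np.degrees(np.arctan2(w, t_star))
        assert abs(phi - expected) < 2 * sampling_step_deg(spec)

    def test_cam_rising_edge_onset(self, phantom_cam, head_fit_cam):
        ph, fit = phantom_cam, head_fit_cam
        spec = ph.spec
        plane = build_alpha_plane(fit, ph.neck_axis, ph.shaft_axis)
        sec = extract_section(ph.femur, ph.acetabulum, plane, 0.5, fit, ph.neck_axis)
        onset = find_asphericity_onset(sec)
        phi = np.degrees(sec.phi(onset))[0]
        half = np.degrees(np.radians(spec.cam_width) * np.sqrt(2 * np.log(spec.cam_amplitude / 0.5)))
        expected = 180.0 - (spec.cam_center_angle + half)
        assert abs(phi - expected) < 2 * sampling_step_deg(spec)

    def test_single_spike_ignored(self, nocam_setup):
        ph, fit, plane = nocam_setup
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r = np.full_like(th, fit.radius)
        r[100] = fit.radius + 1.0  # lone supra-threshold spike
        circle = np.column_stack([np.zeros_like(th), r * np.cos(th), r * np.sin(th)])
        sec = extract_section(PointCloud(circle), ph.acetabulum, plane, 0.5, fit, ph.neck_axis)
        assert find_asphericity_onset(sec) is None


class TestRim:
    def test_cup_edge_angle(self, nocam_setup):
        ph, fit, plane = nocam_setup
        spec = ph.spec
        sec = extract_section(ph.femur, ph.acetabulum, plane, 0.5, fit, ph.neck_axis)
        rim = find_rim_point(sec)
        phi = np.degrees(sec.phi(rim))[0]
        from hipclear.synthetic import _rim_phi

        expected = np.degrees(_rim_phi(spec, None, 0.0, 0.5))
        assert abs(phi - expected) < 2 * sampling_step_deg(spec)

    def test_single_acetabular_point(self, nocam_setup):
        ph, fit, plane = nocam_setup
        lone = PointCloud(np.array([[0.0, 20.0, -10.0]]))
        sec = extract_section(ph.femur, lone, plane, 0.5, fit, ph.neck_axis)
        sec = type(sec)(**{**sec.__dict__, "usable": True})
        assert np.allclose(find_rim_point(sec), sec.basis.to_2d([[0.0, 20.0, -10.0]])[0])

    def test_invariant_under_scene_rotation(self, nocam_setup, rng):
        """Rim (and beta) are intrinsic: rotating bones, axes and plane
        together leaves the marching angle unchanged."""
        ph, fit, plane = nocam_setup
        sec0 = extract_section(ph.femur, ph.acetabulum, plane, 0.5, fit, ph.neck_axis)
        phi0 = sec0.phi(find_rim_point(sec0))[0]
        R = Rotation.random(random_state=np.random.RandomState(2)).as_matrix()
        T = RigidTransform(R, rng.uniform(-20, 20, 3))
        fit_t = SphereFit(T.apply(fit.center), fit.radius, fit.rms_residual)
        plane_t = Plane(T.apply(plane.point), R @ plane.normal)
        sec1 = extract_section(
            ph.femur.transformed(T),
            ph.acetabulum.transformed(T),
            plane_t,
            0.5,
            fit_t,
            ph.neck_axis.transformed(T),
        )
        phi1 = sec1.phi(find_rim_point(sec1))[0]
        assert phi1 == pytest.approx(phi0, abs=1e-6)


class TestBetaAngle:
    def _section(self, nocam_setup):
        ph, fit, plane = nocam_setup
        return extract_section(ph.femur, ph.acetabulum, plane, 0.5, fit, ph.neck_axis)

    def test_collinear_rays_zero(self, nocam_setup):
        sec = self._section(nocam_setup)
        p = sec.head_center_2d + np.array([3.0, 4.0])
        assert beta_angle_in_plane(sec, p, p) == pytest.approx(0.0)

    def test_plus_ten_degrees(self, nocam_setup):
        sec = self._section(nocam_setup)

        def at_phi(phi_deg):
            th = np.pi - np.radians(phi_deg)
            return sec.head_center_2d + 30.0 * np.array([np.cos(th), np.sin(th)])

        assert beta_angle_in_plane(sec, at_phi(100.0), at_phi(90.0)) == pytest.approx(10.0, abs=1e-9)

    def test_head_centre_ray_degenerate(self, nocam_setup):
        sec = self._section(nocam_setup)
        with pytest.raises(DegenerateGeometryError):
            beta_angle_in_plane(sec, sec.head_center_2d, sec.head_center_2d + 1.0)

    def test_cam_inside_cup_is_negative(self):
        """A cam engineered to sit under the acetabular rim gives negative beta."""
        spec = HipPhantomSpec(
            seed=5, cam_amplitude=3.0, cam_center_angle=95.0, cam_width=8.0,
            cup_coverage_angle=75.0,
        )
        ph = generate_phantom(spec)
        from hipclear import fit_sphere

        fit = fit_sphere(ph.head)
        plane = build_alpha_plane(fit, ph.neck_axis, ph.shaft_axis)
        stack = build_plane_stack(plane, count_each_side=default_count_each_side(fit.radius))
        res = min_beta(ph.femur, ph.acetabulum, stack, fit, ph.neck_axis)
        expected = analytic_beta_in_plane(spec)
        assert expected < 0
        assert res.min_beta < 0
        assert abs(res.min_beta - analytic_beta_in_plane(spec, d=res.min_plane_index * 2.5)) < \
            2 * sampling_step_deg(spec)


class TestMinBeta:
    def test_min_equals_list_minimum(self, nocam_setup):
        ph, fit, plane = nocam_setup
        stack = build_plane_stack(plane, count_each_side=default_count_each_side(fit.radius))
        res = min_beta(ph.femur, ph.acetabulum, stack, fit, ph.neck_axis)
        assert res.min_beta == min(b for _, b, _, _ in res.per_plane)
        used = {i for i, *_ in res.per_plane}
        excluded = {i for i, _ in res.excluded_planes}
        assert used.isdisjoint(excluded)

    def test_min_at_cam_plane(self, phantom_cam, head_fit_cam):
        ph, fit = phantom_cam, head_fit_cam
        plane = build_alpha_plane(fit, ph.neck_axis, ph.shaft_axis)
        stack = build_plane_stack(plane, count_each_side=default_count_each_side(fit.radius))
        res = min_beta(ph.femur, ph.acetabulum, stack, fit, ph.neck_axis)
        assert abs(res.min_plane_index) <= 1  # cam is centred on the base plane

    def test_axisymmetric_phantom_matches_analytic(self, nocam_setup):
        ph, fit, plane = nocam_setup
        spec = ph.spec
        stack = build_plane_stack(plane, count_each_side=default_count_each_side(fit.radius))
        res = min_beta(ph.femur, ph.acetabulum, stack, fit, ph.neck_axis)
        for idx, beta, _, _ in res.per_plane:
            expected = analytic_beta_in_plane(spec, d=idx * stack.spacing)
            if not np.isnan(expected):
                assert abs(beta - expected) < 2 * sampling_step_deg(spec), idx

    def test_invariant_under_rigid_scene_motion(self, nocam_setup, rng):
        ph, fit, plane = nocam_setup
        stack = build_plane_stack(plane, count_each_side=3)
        res0 = min_beta(ph.femur, ph.acetabulum, stack, fit, ph.neck_axis)
        R = Rotation.random(random_state=np.random.RandomState(8)).as_matrix()
        T = RigidTransform(R, rng.uniform(-30, 30, 3))
        stack_t = build_plane_stack(
            Plane(T.apply(plane.point), R @ plane.normal), count_each_side=3
        )
        res1 = min_beta(
            ph.femur.transformed(T),
            ph.acetabulum.transformed(T),
            stack_t,
            SphereFit(T.apply(fit.center), fit.radius, fit.rms_residual),
            ph.neck_axis.transformed(T),
        )
        assert res1.min_beta == pytest.approx(res0.min_beta, abs=1e-6)
        assert res1.min_plane_index == res0.min_plane_index

    def test_no_usable_plane_raises(self, nocam_setup):
        ph, fit, _ = nocam_setup
        far = Plane(fit.center + np.array([0.0, 500.0, 0.0]), [0, 1, 0])
        stack = build_plane_stack(far, count_each_side=0)
        with pytest.raises(NoMeasurementError):
            min_beta(ph.femur, ph.acetabulum, stack, fit, ph.neck_axis)


class TestAdjustCenterDistance:
    def test_identity_when_matching(self, nocam_setup):
        ph, fit, _ = nocam_setup
        current = float(np.linalg.norm(fit.center - ph.cup_center))
        out = adjust_center_distance(ph.femur, fit, ph.cup_center, current)
        assert np.allclose(out.points, ph.femur.points)

    def test_two_mm_pullback(self):
        cloud = PointCloud(np.array([[52.0, 0, 0], [55.0, 1.0, 0], [50.0, -1.0, 0]]))
        fit = SphereFit([52.0, 0.0, 0.0], 25.0, 0.0)
        out = adjust_center_distance(cloud, fit, [0.0, 0.0, 0.0], 50.0)
        assert np.allclose(out.points[0], [50.0, 0, 0], atol=1e-9)

    def test_distance_postcondition_random(self, rng):
        for _ in range(20):
            center = rng.uniform(-50, 50, 3)
            acet = rng.uniform(-50, 50, 3)
            if np.linalg.norm(center - acet) < 1.0:
                continue
            ref = rng.uniform(10, 80)
            cloud = PointCloud(center + rng.normal(0, 5, (30, 3)))
            fit = SphereFit(center, 25.0, 0.0)
            out = adjust_center_distance(cloud, fit, acet, ref)
            shift = out.points[0] - cloud.points[0]
            new_center = center + shift
            assert np.linalg.norm(new_center - acet) == pytest.approx(ref, abs=1e-9)

    def test_coincident_centres_rejected(self):
        cloud = PointCloud(np.eye(3) * 10)
        fit = SphereFit([1.0, 1.0, 1.0], 5.0, 0.0)
        with pytest.raises(DegenerateGeometryError):
            adjust_center_distance(cloud, fit, [1.0, 1.0, 1.0], 10.0)


class TestPlaceModels:
    def test_identity_transforms_unchanged(self, nocam_setup):
        ph, fit, _ = nocam_setup
        ref = float(np.linalg.norm(fit.center - ph.cup_center))
        fem, ace = place_models_at_frame(
            ph.femur, ph.acetabulum, RigidTransform.identity(), RigidTransform.identity(),
            ref, fit, ph.cup_center,
        )
        assert np.allclose(fem.points, ph.femur.points, atol=1e-9)
        assert np.allclose(ace.points, ph.acetabulum.points)

    def test_distance_restored_after_random_poses(self, nocam_setup, rng):
        ph, fit, _ = nocam_setup
        ref = float(np.linalg.norm(fit.center - ph.cup_center))
        for k in range(5):
            Tf = RigidTransform(
                Rotation.random(random_state=np.random.RandomState(k)).as_matrix(),
                rng.uniform(-30, 30, 3),
            )
            Tp = RigidTransform(
                Rotation.random(random_state=np.random.RandomState(100 + k)).as_matrix(),
                rng.uniform(-30, 30, 3),
            )
            fem, ace = place_models_at_frame(
                ph.femur, ph.acetabulum, Tf, Tp, ref, fit, ph.cup_center
            )
            # recompute centres from the placed clouds' known construction
            head_new = fem.points[: len(ph.femur.points)].mean(axis=0) - (
                ph.femur.points.mean(axis=0) - fit.center
            ) @ Tf.rotation.T
            acet_new = Tp.apply(ph.cup_center)
            assert np.linalg.norm(head_new - acet_new) == pytest.approx(ref, abs=1e-6)


class TestMonotonicity:
    def test_beta_decreases_with_cam_amplitude(self):
        from hipclear import fit_sphere

        betas = []
        for amp in (0.0, 1.0, 2.0, 3.0, 4.0):
            spec = HipPhantomSpec(seed=3, cam_amplitude=amp)
            ph = generate_phantom(spec)
            fit = fit_sphere(ph.head)
            plane = build_alpha_plane(fit, ph.neck_axis, ph.shaft_axis)
            stack = build_plane_stack(plane, count_each_side=4)
            betas.append(min_beta(ph.femur, ph.acetabulum, stack, fit, ph.neck_axis).min_beta)
        step = sampling_step_deg(HipPhantomSpec())
        assert all(b2 <= b1 + step for b1, b2 in zip(betas, betas[1:]))
        assert betas[-1] < betas[0] - 5
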