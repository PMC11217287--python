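"""Curvature estimation, the analytic ellipsoid oracle and the θ statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedmech import curvature as curv
from seedmech import synthetic as syn
from seedmech.mesh import EllipsoidSpec


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


unit_vectors = st.builds(
    lambda x, y, z: _unit([x, y, z]),
    *(st.floats(-1, 1).filter(lambda t: abs(t) > 1e-3) for _ in range(3)),
)


class TestAxisAngle:
    def test_identity_is_zero(self):
        assert curv.axis_angle([1, 0, 0], [1, 0, 0]) == pytest.approx(0.0)

    def test_orthogonal_is_ninety(self):
        assert curv.axis_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_antiparallel_is_zero(self):
        assert curv.axis_angle([1, 0, 0], [-1, 0, 0]) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=100)
    @given(u=unit_vectors, v=unit_vectors)
    def test_symmetry_and_sign_invariance(self, u, v):
        base = curv.axis_angle(u, v)
        assert curv.axis_angle(v, u) == pytest.approx(base, abs=1e-9)
        for su in (1, -1):
            for sv in (1, -1):
                assert curv.axis_angle(su * u, sv * v) == pytest.approx(base, abs=1e-9)
        assert 0.0 <= base <= 90.0

    def test_zero_vector_rejected(self):
        with pytest.raises(curv.UndefinedOrientationError):
            curv.axis_angle([0, 0, 0], [1, 0, 0])

    def test_badly_scaled_vector_rejected(self):
        with pytest.raises(curv.UndefinedOrientationError):
            curv.axis_angle([2, 0, 0], [1, 0, 0])


class TestEllipsoidOracle:
    def test_sphere_everywhere(self):
        spec = EllipsoidSpec.sphere(100.0)
        pc = curv.ellipsoid_curvature_oracle(spec, _unit([3, -2, 1]) * 100.0)
        assert pc.kappa_max == pytest.approx(0.01)
        assert pc.kappa_min == pytest.approx(0.01)

    def test_prolate_pole_is_umbilic(self):
        a, b = 170.0, 100.0
        pc = curv.ellipsoid_curvature_oracle(EllipsoidSpec(a, b, b), np.array([a, 0.0, 0.0]))
        assert pc.kappa_max == pytest.approx(a / b**2)
        assert pc.kappa_min == pytest.approx(a / b**2)

    def test_prolate_equator(self):
        a, b = 170.0, 100.0
        pc = curv.ellipsoid_curvature_oracle(EllipsoidSpec(a, b, b), np.array([0.0, b, 0.0]))
        assert pc.kappa_max == pytest.approx(1.0 / b)
        assert pc.kappa_min == pytest.approx(b / a**2)

    def test_triaxial_max_axis_in_xz_plane_at_flank(self):
        spec = EllipsoidSpec(170.0, 100.0, 85.0)
        pc = curv.ellipsoid_curvature_oracle(spec, np.array([0.0, 100.0, 0.0]))
        assert pc.kappa_max == pytest.approx(spec.b / spec.c**2)
        assert pc.kappa_min == pytest.approx(spec.b / spec.a**2)
        assert abs(pc.axis_max[1]) < 1e-9  # tangent plane at (0,b,0) is the x–z plane
        assert abs(abs(pc.axis_max[2]) - 1.0) < 1e-9  # max curvature along z

    def test_off_surface_point_rejected(self):
        with pytest.raises(curv.ProjectionError):
            curv.ellipsoid_curvature_oracle(EllipsoidSpec.sphere(1.0), np.array([1.1, 0.0, 0.0]))


class TestEstimateCurvature:
    def test_sphere_curvature_and_isotropy(self, sphere4):
        tess = syn.tessellate_surface(sphere4, 60, rng_seed=11)
        cf = curv.estimate_curvature(sphere4, tess, 30.0)
        mean_k = 0.5 * (cf.kappa_max + cf.kappa_min)
        assert float(mean_k.mean()) == pytest.approx(0.01, rel=0.03)
        assert float(np.nanmean(cf.anisotropy)) < 0.05

    def test_spheroid_equator_pair(self):
        spec = EllipsoidSpec(170.0, 100.0, 100.0)
        mesh = syn.make_ellipsoid_mesh(spec, 4)
        tess = syn.tessellate_surface(mesh, 120, rng_seed=5)
        cf = curv.estimate_curvature(mesh, tess, 30.0)
        eq = np.abs(tess.cell_centroids[:, 0]) < 0.15 * spec.a
        assert float(cf.kappa_max[eq].mean()) == pytest.approx(1.0 / spec.b, rel=0.05)
        assert float(cf.kappa_min[eq].mean()) == pytest.approx(spec.b / spec.a**2, rel=0.05)

    def test_error_decreases_with_refinement(self):
        """Vertex-density error dominates at a fixed 65 µm neighbourhood,
        so the oracle error shrinks as the mesh is refined."""
        spec = EllipsoidSpec.sphere(100.0)
        errors = []
        for refinement in (2, 3, 4):
            mesh = syn.make_ellipsoid_mesh(spec, refinement)
            tess = syn.tessellate_surface(mesh, 20, rng_seed=2)
            cf = curv.estimate_curvature(mesh, tess, 65.0)
            kappa = np.concatenate([cf.kappa_max, cf.kappa_min])
            errors.append(float(np.abs(kappa - 0.01).mean()))
        assert errors[0] > errors[1] > errors[2]

    def test_radius_below_resolution_rejected(self, sphere4):
        tess = syn.tessellate_surface(sphere4, 30, rng_seed=1)
        with pytest.raises(ValueError, match="mean edge length"):
            curv.estimate_curvature(sphere4, tess, 10.0)

    def test_axes_orthogonal_to_normal(self, twodpa_1000cells):
        _, tess, cf = twodpa_1000cells
        n = tess.cell_normals
        assert np.abs(np.einsum("ij,ij->i", cf.axis_max, n)).max() < 1e-3
        assert np.abs(np.einsum("ij,ij->i", cf.axis_max, cf.axis_min)).max() < 1e-6

    def test_euclidean_metric_agrees_on_sphere(self, sphere4):
        tess = syn.tessellate_surface(sphere4, 40, rng_seed=9)
        geo = curv.estimate_curvature(sphere4, tess, 30.0, metric="geodesic")
        euc = curv.estimate_curvature(sphere4, tess, 30.0, metric="euclidean")
        assert np.abs(geo.kappa_max - euc.kappa_max).max() < 5e-4


class TestCorrelation:
    def test_identical_axes_give_zero(self, twodpa_1000cells):
        _, _, cf = twodpa_1000cells
        orient = curv.OrientationField(
            cell_ids=cf.cell_ids.copy(),
            vectors=cf.axis_max.copy(),
            score=np.ones(len(cf.cell_ids)),
        )
        dist = curv.correlate_orientation_with_curvature(orient, cf)
        assert dist.median == pytest.approx(0.0, abs=1e-9)
        assert dist.counts.sum() == len(cf.cell_ids)

    def test_uniform_axial_field_mean_45(self, twodpa_1000cells):
        _, _, cf = twodpa_1000cells
        orient = syn.sample_cmt_field(cf, 0.0, 0.0, rng_seed=3)
        dist = curv.correlate_orientation_with_curvature(orient, cf)
        assert dist.mean == pytest.approx(45.0, abs=3.0)
        # KS distance to the uniform distribution on [0, 90]
        theta = np.sort(dist.theta.to_numpy())
        ecdf = np.arange(1, len(theta) + 1) / len(theta)
        ks = np.abs(ecdf - theta / 90.0).max()
        assert ks < 0.05

    def test_median_theta_monotone_in_concentration(self, twodpa_1000cells):
        _, _, cf = twodpa_1000cells
        medians = []
        for kappa in (2.0, 20.0, 200.0):
            orient = syn.sample_cmt_field(cf, kappa, 0.0, rng_seed=5)
            medians.append(curv.correlate_orientation_with_curvature(orient, cf).median)
        assert medians[0] > medians[1] > medians[2]
        assert medians[2] < 5.0

    def test_offset_ninety_gives_large_theta(self, twodpa_1000cells):
        _, _, cf = twodpa_1000cells
        orient = syn.sample_cmt_field(cf, 200.0, 90.0, rng_seed=6)
        dist = curv.correlate_orientation_with_curvature(orient, cf)
        assert dist.median > 85.0

    def test_empty_join_rejected(self, twodpa_1000cells):
        _, _, cf = twodpa_1000cells
        orient = curv.OrientationField(
            cell_ids=cf.cell_ids + 10_000, vectors=cf.axis_max, score=np.ones(len(cf.cell_ids))
        )
        with pytest.raises(curv.EmptyJoinError):
            curv.correlate_orientation_with_curvature(orient, cf)

    def test_frame_invariance_under_rigid_rotation(self, twodpa_1000cells):
        _, _, cf = twodpa_1000cells
        orient = syn.sample_cmt_field(cf, 10.0, 0.0, rng_seed=8)
        base = curv.correlate_orientation_with_curvature(orient, cf).theta.to_numpy()
        # rotate every vector field rigidly
        ang = np.deg2rad(37.0)
        R = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        cf_rot = curv.CurvatureField(
            cf.cell_ids,
            cf.kappa_max,
            cf.kappa_min,
            cf.axis_max @ R.T,
            cf.axis_min @ R.T,
            cf.anisotropy,
            cf.neighborhood_radius,
        )
        orient_rot = curv.OrientationField(orient.cell_ids, orient.vectors @ R.T, orient.score)
        rotated = curv.correlate_orientation_with_curvature(orient_rot, cf_rot).theta.to_numpy()
        assert np.abs(base - rotated).max() < 1e-6


class TestOrientationRelativeToPoint:
    def test_circumferential_ring_with_radial_outlier(self):
        ang = np.linspace(0.0, 2 * np.pi, 24, endpoint=False)
        centroids = np.column_stack([np.cos(ang), np.sin(ang)]) * 50.0
        # circumferential axis = tangent of the circle = radial angle + 90
        orientations = (np.degrees(ang) + 90.0) % 180.0
        orientations[5] = np.degrees(ang[5]) % 180.0  # one radial outlier
        dev = curv.orientation_relative_to_point(orientations, centroids, np.zeros(2))
        assert np.median(dev) == pytest.approx(0.0, abs=1e-9)
        assert dev.max() == pytest.approx(90.0, abs=1e-9)
        assert dev[5] == pytest.approx(90.0, abs=1e-9)

    def test_focus_on_centroid_rejected(self):
        with pytest.raises(curv.UndefinedOrientationError):
            curv.orientation_relative_to_point(
                np.array([0.0]), np.array([[1.0, 1.0]]), np.array([1.0, 1.0])
            )
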