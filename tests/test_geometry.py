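"""Geometry and forward-model tests against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

import opmsim as om
from opmsim.geometry import (
    ConductorSphere,
    CurrentDipole,
    GeometryError,
    SourceGrid,
    TriangularCoil,
    build_lead_fields,
    build_synthetic_helmet,
    free_space_dipole_field,
    segment_field,
    tangential_basis,
    triangle_coil_field,
)


def quadrature_coil_field(coil: TriangularCoil, point: np.ndarray) -> np.ndarray:
    """Adaptive-quadrature oracle for the Biot-Savart line integral."""
    B = np.zeros(3)
    v = coil.vertices
    for k in range(3):
        a, b = v[k], v[(k + 1) % 3]
        seg = b - a

        def integrand(t, comp):
            r = point - (a + t * seg)
            return np.cross(seg, r)[comp] / np.linalg.norm(r) ** 3

        for c in range(3):
            val, _ = quad(integrand, 0.0, 1.0, args=(c,), limit=200,
                          epsabs=1e-18, epsrel=1e-12)
            B[c] += 1e-7 * coil.current * val
    return B


class TestHelmet:
    def test_construction_invariants(self):
        arr = build_synthetic_helmet(64, head_radius=0.09, standoff=0.015, seed=1)
        assert arr.n_channels == 192
        assert arr.n_sensors == 64
        for s in range(64):
            R = arr.triad_rotation(s)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
        # one radial axis, two tangential, per sensor
        radials = arr.sensor_positions / np.linalg.norm(arr.sensor_positions,
                                                        axis=1, keepdims=True)
        z_axes = arr.orientations[2::3]
        assert np.allclose(z_axes, radials, atol=1e-12)

    def test_determinism_and_seed_sensitivity(self):
        a = build_synthetic_helmet(64, seed=1)
        b = build_synthetic_helmet(64, seed=1)
        c = build_synthetic_helmet(64, seed=2)
        assert np.array_equal(a.positions, b.positions)
        assert not np.allclose(a.positions, c.positions)

    def test_minimum_inter_sensor_spacing(self):
        # regression value computed from the generated default array
        arr = build_synthetic_helmet(64, head_radius=0.09, standoff=0.015, seed=1)
        assert pdist(arr.sensor_positions).min() > 0.02

    @pytest.mark.parametrize("kwargs", [
        {"n_sensors": 3}, {"head_radius": -0.1}, {"standoff": 0.0},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(GeometryError):
            build_synthetic_helmet(**{"n_sensors": 64, "head_radius": 0.09,
                                      "standoff": 0.015, "seed": 0, **kwargs})

    def test_tsv_round_trip(self, tmp_path):
        arr = build_synthetic_helmet(16, seed=3)
        arr.to_tsv(tmp_path / "channels.tsv")
        back = om.SensorArray.from_tsv(tmp_path / "channels.tsv")
        assert np.allclose(arr.positions, back.positions)
        assert np.allclose(arr.orientations, back.orientations)
        assert np.array_equal(arr.sensor_ids, back.sensor_ids)


class TestTriangleCoil:
    def test_zero_current_gives_zero_field(self):
        coil = TriangularCoil.default(current=0.0)
        assert np.allclose(triangle_coil_field(coil, np.array([0.0, 0.0, 0.05])), 0.0)

    def test_matches_quadrature_oracle(self):
        coil = TriangularCoil.default(current=1e-3)
        point = coil.centroid + 0.05 * coil.normal
        B = triangle_coil_field(coil, point)
        Bq = quadrature_coil_field(coil, point)
        assert np.linalg.norm(B - Bq) <= 1e-8 * np.linalg.norm(Bq)

    def test_far_field_matches_point_dipole(self):
        # at 10x the coil extent the equivalent moment is m = I * A
        coil = TriangularCoil.default(current=1e-3)
        point = coil.centroid + 0.45 * np.array([0.2, 0.3, 1.0]) / np.linalg.norm([0.2, 0.3, 1.0])
        B = triangle_coil_field(coil, point)
        r = point - coil.centroid
        rn, rh = np.linalg.norm(r), r / np.linalg.norm(r)
        m = coil.dipole_moment
        Bdip = 1e-7 * (3 * np.dot(m, rh) * rh - m) / rn**3
        assert np.linalg.norm(B - Bdip) <= 0.02 * np.linalg.norm(Bdip)
        assert np.isclose(coil.area, 1.125e-4)

    def test_linear_in_current(self):
        pt = np.array([0.01, 0.02, 0.06])
        B1 = triangle_coil_field(TriangularCoil.default(current=1e-3), pt)
        for scale in (0.1, 3.0, 100.0):
            Bs = triangle_coil_field(TriangularCoil.default(current=scale * 1e-3), pt)
            assert np.allclose(Bs, scale * B1, rtol=1e-12)

    def test_rotation_translation_equivariance(self):
        rng = np.random.default_rng(7)
        coil = TriangularCoil.default(current=2e-3)
        pt = np.array([0.02, -0.01, 0.07])
        B = triangle_coil_field(coil, pt)
        for _ in range(10):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3) * 0.05
            moved = coil.transformed(R, t)
            B2 = triangle_coil_field(moved, R @ pt + t)
            assert np.allclose(B2, R @ B, atol=1e-10 * np.linalg.norm(B) + 1e-25)

    def test_singularity_near_segment(self):
        coil = TriangularCoil.default(current=1e-3)
        on_edge = 0.5 * (coil.vertices[1] + coil.vertices[2])
        with pytest.raises(GeometryError):
            triangle_coil_field(coil, on_edge + np.array([0.0, 0.0, 1e-8]))

    def test_superposition_of_segments(self):
        a, b, c = np.eye(3) * 0.01
        p = np.array([0.03, 0.04, 0.05])
        B_ab = segment_field(a, b, 1.0, p)
        B_bc = segment_field(b, c, 1.0, p)
        both = segment_field(a, b, 1.0, p) + segment_field(b, c, 1.0, p)
        assert np.allclose(both, B_ab + B_bc, rtol=1e-12)


class TestSphericalDipole:
    sphere = ConductorSphere()

    def test_radial_dipole_is_silent(self):
        dip = CurrentDipole(np.array([0.0, 0.0, 0.05]), np.array([0.0, 0.0, 3e-8]))
        pts = np.array([[0.1, 0.02, 0.03], [0.0, 0.0, 0.12], [-0.08, 0.05, 0.06]])
        assert np.allclose(om.dipole_field_sphere(dip, self.sphere, pts), 0.0,
                           atol=1e-20)

    def test_linearity_in_moment(self):
        pos = np.array([0.01, 0.02, 0.05])
        pt = np.array([0.05, -0.03, 0.1])
        B1 = om.dipole_field_sphere(CurrentDipole(pos, np.array([1e-8, 0, 0])),
                                    self.sphere, pt)
        B2 = om.dipole_field_sphere(CurrentDipole(pos, np.array([2e-8, 0, 0])),
                                    self.sphere, pt)
        assert np.allclose(B2, 2 * B1, rtol=1e-12)

    def test_radial_component_matches_free_space_dipole(self):
        # volume currents contribute no radial field
        dip = CurrentDipole(np.array([0.013, -0.005, 0.051]),
                            np.array([1e-8, 2e-8, -0.5e-8]))
        for pt in ([0.05, 0.02, 0.1], [-0.02, 0.09, 0.04], [0.0, 0.0, 0.11]):
            pt = np.array(pt)
            rhat = pt / np.linalg.norm(pt)
            Bs = om.dipole_field_sphere(dip, self.sphere, pt)
            Bf = free_space_dipole_field(dip.moment, dip.position, pt)
            assert np.isclose(np.dot(Bs, rhat), np.dot(Bf, rhat), rtol=1e-10)

    def test_domain_errors(self):
        with pytest.raises(GeometryError):
            om.dipole_field_sphere(
                CurrentDipole(np.array([0.0, 0.0, 0.2]), np.array([1e-8, 0, 0])),
                self.sphere, np.array([0.0, 0.0, 0.12]))
        with pytest.raises(GeometryError):
            om.dipole_field_sphere(
                CurrentDipole(np.array([0.0, 0.0, 0.05]), np.array([1e-8, 0, 0])),
                self.sphere, np.array([0.0, 0.0, 0.03]))


class TestLeadFields:
    def test_definitional_consistency_and_depth(self, helmet16, sphere):
        grid = SourceGrid(np.array([[0.0, 0.0, z] for z in (0.02, 0.035, 0.05,
                                                            0.06, 0.07)]),
                          spacing=0.004)
        L = build_lead_fields(helmet16, grid, sphere)
        # column = per-channel projected field of the tangential unit dipole
        pos = grid.voxel_positions[2]
        e1, e2 = tangential_basis(pos - sphere.centre)
        B = om.dipole_field_sphere(CurrentDipole(pos, e1), sphere, helmet16.positions)
        expected = np.einsum("ij,ij->i", B, helmet16.orientations)
        assert np.allclose(L[:, 2, 0], expected, atol=1e-12)
        # norm grows monotonically toward the surface along the radial line
        norms = np.linalg.norm(L, axis=(0, 2))
        assert np.all(np.diff(norms) > 0)

    def test_voxel_outside_sphere_rejected(self, helmet16, sphere):
        grid = SourceGrid(np.array([[0.0, 0.0, 0.09]]), spacing=0.004)
        with pytest.raises(GeometryError):
            build_lead_fields(helmet16, grid, sphere)

    def test_centre_voxel_matches_free_space_radial_behaviour(self, helmet16, sphere):
        # a tangential moment at the sphere centre still produces the
        # free-space radial field component at every channel
        grid = SourceGrid(np.array([[0.0, 0.0, 0.0]]), spacing=0.004)
        L = build_lead_fields(helmet16, grid, sphere)
        e1, _ = tangential_basis(np.array([0.0, 0.0, 1.0]))
        Bf = free_space_dipole_field(e1, np.zeros(3), helmet16.positions)
        rhat = helmet16.positions / np.linalg.norm(helmet16.positions, axis=1,
                                                   keepdims=True)
        # compare radial projections channel-wise for the radial (Z) channels
        proj_model = L[2::3, 0, 0]
        proj_free = np.einsum("ij,ij->i", Bf, rhat)[2::3]
        assert np.allclose(proj_model, proj_free, rtol=1e-10)


def test_source_grid_regular_inside_sphere(sphere):
    grid = SourceGrid.regular(sphere, spacing=0.01)
    assert grid.n_voxels > 100
    assert np.all(np.linalg.norm(grid.voxel_positions, axis=1) < sphere.radius)
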