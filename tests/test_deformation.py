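"""Spherical frame, globe surface extraction and polar deformation maps."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from orbitmorph.deformation import (
    DeformationMap,
    aggregate_maps,
    build_frame,
    globe_surface_points,
    subject_deformation_map,
    to_deformation_map,
)


class TestFrame:
    def test_zenith_along_z_keeps_x_reference(self):
        f = build_frame(np.zeros(3), np.array([0, 0, 4.0]))
        assert np.allclose(f.zenith, [0, 0, 1])
        assert np.allclose(f.azimuth_ref, [1, 0, 0])

    def test_zenith_along_x_uses_fallback(self):
        f = build_frame(np.zeros(3), np.array([5.0, 0, 0]))
        assert np.allclose(f.zenith, [1, 0, 0])
        assert abs(f.zenith @ f.azimuth_ref) < 1e-12
        assert np.linalg.norm(f.azimuth_ref) == pytest.approx(1.0)

    def test_random_zeniths_orthonormal(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tip = rng.normal(size=3) * 10
            origin = rng.normal(size=3)
            f = build_frame(origin, origin + tip)
            assert abs(f.zenith @ f.azimuth_ref) < 1e-12
            assert np.linalg.norm(f.zenith) == pytest.approx(1.0, abs=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            build_frame(np.ones(3), np.ones(3))


def _sphere_cloud(radius, n=4000, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return radius * v / np.linalg.norm(v, axis=1, keepdims=True)


class TestSurfacePoints:
    def test_vertex_radii_near_globe_radius(self, default_phantom):
        labels, _, lms, _ = default_phantom
        pts = globe_surface_points(labels, "right")
        r = np.linalg.norm(pts - lms.require("globe_centre", "right"), axis=1)
        assert len(pts) > 1000
        assert np.all(np.abs(r - 11.3) < 0.5)

    def test_rigid_rotation_equivariance(self, default_phantom):
        from orbitmorph.io_formats import LabelVolume

        labels, _, _, _ = default_phantom
        rot = Rotation.from_euler("zyx", [40, 10, -25], degrees=True).as_matrix()
        T = np.eye(4)
        T[:3, :3] = rot
        rotated = LabelVolume(labels.data, T @ labels.affine, labels.label_table)
        a = globe_surface_points(labels, "left")
        b = globe_surface_points(rotated, "left")
        assert np.allclose(b, a @ rot.T, atol=1e-9)


class TestBinning:
    def test_constant_radius_everywhere(self):
        frame = build_frame(np.zeros(3), np.array([0, 0, 1.0]))
        m = to_deformation_map(_sphere_cloud(12.0), frame)
        occ = m.counts > 0
        assert np.allclose(m.grid[occ], 12.0, atol=1e-9)
        assert m.grid.shape == (30, 72)

    def test_anterior_points_discarded(self):
        frame = build_frame(np.zeros(3), np.array([0, 0, 1.0]))
        m = to_deformation_map(_sphere_cloud(10.0, n=6000), frame)
        frac = m.meta["n_anterior_discarded"] / 6000
        assert 0.45 <= frac <= 0.55

    def test_all_anterior_rejected(self):
        frame = build_frame(np.zeros(3), np.array([0, 0, 1.0]))
        pts = _sphere_cloud(10.0)
        pts = pts[pts[:, 2] < -1.0]
        with pytest.raises(ValueError):
            to_deformation_map(pts, frame)

    def test_frame_covariance_under_rotation(self):
        pts = _sphere_cloud(11.0, n=8000, seed=1) * [1.0, 1.0, 0.93]  # squashed
        frame = build_frame(np.zeros(3), np.array([0, 0, 1.0]))
        m1 = to_deformation_map(pts, frame)
        rot = Rotation.from_euler("xyz", [35, -15, 60], degrees=True).as_matrix()
        from orbitmorph.deformation import SphericalFrame

        frame_r = SphericalFrame(
            origin=np.zeros(3),
            zenith=rot @ frame.zenith,
            azimuth_ref=rot @ frame.azimuth_ref,
        )
        m2 = to_deformation_map(pts @ rot.T, frame_r)
        both = (m1.counts > 2) & (m2.counts > 2)
        assert np.nanmean(np.abs(m1.grid[both] - m2.grid[both])) < 0.05


class TestPhantomMaps:
    def test_sphere_gives_flat_map(self, default_phantom):
        labels, _, lms, _ = default_phantom
        m = subject_deformation_map(labels, lms, "right")
        occ = m.counts > 0
        assert np.nanmax(m.grid[occ]) - np.nanmin(m.grid[occ]) <= 0.5  # one voxel

    def test_flattened_centre_depressed_rim_unchanged(self, flattened_phantom):
        labels, _, lms, truth = flattened_phantom
        m = subject_deformation_map(labels, lms, "right")
        assert m.central_radius() == pytest.approx(10.8, abs=0.3)
        assert m.rim_radius() == pytest.approx(12.0, abs=0.3)
        # interior bins follow the analytic rule r(theta) = R(1-(1-f)cos^2)
        centres = (np.arange(30) + 0.5) / 30 * 90.0
        profile = np.nanmean(m.grid, axis=1)
        expected = truth.scleral_radius(centres)
        assert np.nanmax(np.abs(profile[2:-2] - expected[2:-2])) < 0.35

    def test_flattening_monotonicity(self, default_phantom, flattened_phantom):
        labels_s, _, lms_s, _ = default_phantom  # f = 1, R = 11.3
        labels_f, _, lms_f, _ = flattened_phantom  # f = 0.9, R = 12
        sphere = subject_deformation_map(labels_s, lms_s, "right")
        flat = subject_deformation_map(labels_f, lms_f, "right")
        # flattened centre is pulled well below its rim; sphere's is not
        assert flat.rim_radius() - flat.central_radius() > 0.8
        assert abs(sphere.rim_radius() - sphere.central_radius()) < 0.3


class TestAggregation:
    def _map(self, grid, counts=None):
        grid = np.asarray(grid, dtype=float)
        counts = np.ones_like(grid, dtype=int) if counts is None else counts
        return DeformationMap(grid=grid, counts=counts)

    def test_identical_maps_zero_variance(self):
        m = self._map(np.full((4, 6), 11.0))
        mean, var = aggregate_maps([m, m, m])
        assert np.allclose(mean.grid, 11.0)
        assert np.allclose(var.grid, 0.0)

    def test_two_maps_one_bin_offset(self):
        a = np.full((4, 6), 10.0)
        b = a.copy()
        b[2, 3] += 1.0
        _, var = aggregate_maps([self._map(a), self._map(b)])
        assert var.grid[2, 3] == pytest.approx(0.5)  # n=2 sample variance
        assert var.grid[0, 0] == pytest.approx(0.0)

    def test_monte_carlo_noise_variance(self):
        rng = np.random.default_rng(7)
        maps = [self._map(11.0 + rng.normal(0, 0.2, (4, 6))) for _ in range(20)]
        _, var = aggregate_maps(maps)
        assert np.mean(var.grid) == pytest.approx(0.04, rel=0.30)

    def test_missing_bins_flagged(self):
        a = np.full((3, 3), 9.0)
        counts = np.ones((3, 3), dtype=int)
        counts[1, 1] = 0
        mean, var = aggregate_maps([self._map(a, counts), self._map(a)])
        assert np.isnan(mean.grid[1, 1])
        assert mean.counts[1, 1] == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_maps([self._map(np.ones((3, 3))), self._map(np.ones((4, 4)))])


def test_csv_export(tmp_path, default_phantom):
    labels, _, lms, _ = default_phantom
    m = subject_deformation_map(labels, lms, "left")
    m.to_csv(tmp_path / "map.csv")
    grid = np.loadtxt(tmp_path / "map.csv", delimiter=",")
    assert grid.shape == (30, 72)
    assert (tmp_path / "map.json").exists()
    assert (tmp_path / "map_counts.csv").exists()
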