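"""The 19 bilateral metrics: planes, landmark distances, oblique
cross-sections, volumes, and whole-record extraction against phantom truth."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from orbitmorph.centerline import extract_centerline
from orbitmorph.io_formats import LabelVolume, Landmark, LandmarkSet
from orbitmorph.morphometrics import (
    METRIC_NAMES,
    MetricsRecord,
    Plane,
    cross_section_area,
    extract_all_metrics,
    fit_rim_plane,
    label_volume,
    landmark_distance_metrics,
    ons_area_3mm,
    ons_area_3mm_optimal,
    optic_canal_area,
    signed_plane_distance,
)
from orbitmorph.phantom import PhantomSpec, generate_orbit_phantom, generate_tube_phantom

from support import LANDMARK_METRICS, metric_tolerance


class TestRimPlane:
    def test_coplanar_square_exact(self):
        pts = [np.array(p, float) for p in [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)]]
        plane = fit_rim_plane(pts, orient_toward=np.array([0.5, 0.5, 5.0]))
        assert np.allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-12)
        assert plane.normal[2] > 0  # oriented toward the nerve tip

    def test_noisy_square_within_5_degrees(self):
        rng = np.random.default_rng(2)
        pts = [
            np.array([x, y, rng.uniform(-0.1, 0.1)])
            for x, y in [(0, 0), (1, 0), (0, 1), (1, 1)]
        ]
        plane = fit_rim_plane(pts, orient_toward=np.array([0.5, 0.5, 5.0]))
        angle = np.degrees(np.arccos(abs(plane.normal @ [0, 0, 1])))
        assert angle < 5.0

    def test_rigid_equivariance(self):
        pts = [np.array(p, float) for p in [(0, 0, 0), (2, 0, 0.1), (0, 2, -0.1), (2, 2, 0)]]
        tip = np.array([1.0, 1.0, 7.0])
        plane = fit_rim_plane(pts, tip)
        rot = Rotation.from_euler("xyz", [30, -20, 50], degrees=True).as_matrix()
        shift = np.array([4.0, -2.0, 1.0])
        plane_r = fit_rim_plane([rot @ p + shift for p in pts], rot @ tip + shift)
        assert np.allclose(plane_r.normal, rot @ plane.normal, atol=1e-9)
        assert np.allclose(plane_r.point, rot @ plane.point + shift, atol=1e-9)

    def test_collinear_rejected(self):
        pts = [np.array([i, 0.0, 0.0]) for i in range(4)]
        with pytest.raises(ValueError):
            fit_rim_plane(pts, np.array([0.0, 0.0, 1.0]))

    def test_signed_distance_examples(self):
        plane = Plane(point=np.zeros(3), normal=np.array([0, 0, 1.0]))
        assert signed_plane_distance(np.array([0, 0, 2.0]), plane) == pytest.approx(2.0)
        assert signed_plane_distance(np.array([3, 4, 0.0]), plane) == pytest.approx(0.0)
        assert signed_plane_distance(np.array([0, 0, -1.5]), plane) == pytest.approx(-1.5)


class TestLandmarkMetrics:
    def test_simple_distance(self):
        lms = LandmarkSet(
            [
                Landmark("lens_centre", "right", (0, 0, 0)),
                Landmark("globe_centre", "right", (0, 0, 7.3)),
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = landmark_distance_metrics(lms, "right")
        assert out["dist_lens_globe_centre"] == pytest.approx(7.3)
        assert np.isnan(out["globe_width"])  # missing pair -> NaN

    def test_missing_landmark_warns(self):
        lms = LandmarkSet([Landmark("lens_centre", "right", (0, 0, 0))])
        with pytest.warns(UserWarning, match="missing landmark"):
            landmark_distance_metrics(lms, "right")

    def test_canal_ellipse_area(self):
        a = np.array([0, 0, 2.0]); b = np.array([0, 0, -2.0])
        c = np.array([1.0, 0, 0]); d = np.array([-1.0, 0, 0])
        assert optic_canal_area(a, b, c, d) == pytest.approx(np.pi * 2 * 1)
        # circle: major = minor = 2r
        assert optic_canal_area(a, b, a, b) == pytest.approx(np.pi * 4.0)
        assert np.isnan(optic_canal_area(a, b, c, None))

    def test_canal_area_normative_scale(self):
        """Axes at the normative grand-mean scale: 4.56 x 4.09 mm."""
        a = np.array([0, 0, 2.28]); b = np.array([0, 0, -2.28])
        c = np.array([2.045, 0, 0]); d = np.array([-2.045, 0, 0])
        assert optic_canal_area(a, b, c, d) == pytest.approx(14.648, abs=5e-3)


class TestCrossSection:
    @pytest.fixture(scope="class")
    def cylinder(self):
        return generate_tube_phantom(radius=1.5, length=25.0)

    def test_perpendicular_cut_is_circle_area(self, cylinder):
        vol, start, end = cylinder
        mid = (start + end) / 2
        plane = Plane(point=mid, normal=np.array([0, -1.0, 0]))
        area = cross_section_area(vol, "optic_nerve", "right", plane, mid,
                                  half_extent=5.0)
        assert area == pytest.approx(np.pi * 1.5**2, rel=0.03)

    def test_30_degree_tilt_inflates_by_sec(self, cylinder):
        vol, start, end = cylinder
        mid = (start + end) / 2
        tilt = np.deg2rad(30.0)
        normal = np.array([np.sin(tilt), -np.cos(tilt), 0.0])
        area = cross_section_area(vol, "optic_nerve", "right", Plane(mid, normal),
                                  mid, half_extent=6.0)
        assert area == pytest.approx(np.pi * 1.5**2 / np.cos(tilt), rel=0.03)

    def test_plane_missing_structure_errors(self, cylinder):
        vol, start, end = cylinder
        outside = start + np.array([10.0, 5.0, 0.0])
        with pytest.raises(ValueError):
            cross_section_area(
                vol, "optic_nerve", "right",
                Plane(outside, np.array([0, -1.0, 0])), outside, half_extent=4.0,
            )


class TestSheathAreas:
    def test_3mm_area_and_optimal_on_phantom(self, default_phantom, default_record):
        _, _, _, truth = default_phantom
        for side in ("right", "left"):
            perp = default_record[("ons_3mm_area", side)]
            opt = default_record[("ons_3mm_optimal_area", side)]
            assert perp == pytest.approx(truth.metrics[("ons_3mm_area", side)], rel=0.05)
            assert opt <= perp + 0.5  # minimisation property (grid tolerance)

    def test_absent_sheath_label_gives_nan(self, default_phantom):
        labels, _, lms, _ = default_phantom
        table = {k: v for k, v in labels.label_table.items()
                 if k[0] != "optic_nerve_sheath"}
        stripped = LabelVolume(labels.data, labels.affine, table)
        cl = extract_centerline(
            stripped, "optic_nerve", "right",
            lms.require("on_tip", "right"), lms.require("optic_canal_start", "right"),
        )
        assert np.isnan(ons_area_3mm(cl, stripped, "right"))
        assert np.isnan(ons_area_3mm_optimal(cl, stripped, "right"))


class TestVolumes:
    def test_voxel_count_volume(self):
        data = np.zeros((12, 12, 12), dtype=np.int16)
        data[1:11, 1:11, 1:11] = 1  # 1000 voxels at 1 mm^3
        vol = LabelVolume(data, np.eye(4), {("globe", "right"): 1})
        assert label_volume(vol, "globe", "right") == pytest.approx(1.0)
        assert np.isnan(label_volume(vol, "lens", "right"))

    def test_phantom_globe_and_shell_volumes(self, default_phantom, default_record):
        _, _, _, truth = default_phantom
        assert default_record[("globe_volume", "right")] == pytest.approx(
            truth.metrics[("globe_volume", "right")], rel=0.02
        )
        assert default_record[("ons_volume", "left")] == pytest.approx(
            truth.metrics[("ons_volume", "left")], rel=0.05
        )


class TestFullRecord:
    def test_complete_phantom_38_finite_values(self, default_record):
        rows = default_record.to_rows()
        assert len(rows) == 38
        assert all(np.isfinite(v) for _, _, v, _ in rows)

    def test_recovery_against_truth(self, default_phantom, default_record):
        _, _, _, truth = default_phantom
        for (metric, side), expected in truth.metrics.items():
            got = default_record[(metric, side)]
            if metric in LANDMARK_METRICS:
                assert got == pytest.approx(expected, abs=1e-6), (metric, side)
            else:
                assert abs(got - expected) <= metric_tolerance(metric, expected), (
                    metric, side, expected, got,
                )

    def test_mirror_symmetry(self, default_record):
        for metric in METRIC_NAMES:
            r = default_record[(metric, "right")]
            l = default_record[(metric, "left")]
            if metric in LANDMARK_METRICS:
                assert r == pytest.approx(l, abs=1e-9), metric
            else:
                assert abs(r - l) <= max(0.03 * abs(r), 0.01), metric

    def test_missing_sheath_degrades_to_nan_not_omission(self, default_phantom):
        labels, _, lms, _ = default_phantom
        table = {k: v for k, v in labels.label_table.items()
                 if k[0] != "optic_nerve_sheath"}
        stripped = LabelVolume(labels.data, labels.affine, table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = extract_all_metrics(stripped, lms)
        rows = rec.to_rows()
        assert len(rows) == 38
        for metric in ("ons_3mm_area", "ons_3mm_optimal_area", "ons_volume"):
            assert np.isnan(rec[(metric, "right")])
        assert np.isfinite(rec[("globe_volume", "right")])

    def test_centres_from_labels_match_carved_com_truth(self, default_phantom):
        """With centres="labels" the globe centre is the centre of mass of
        the globe label, which excludes the carved-out lens; removing lens
        volume V_l at distance d from the sphere centre shifts the COM
        posteriorly by V_l d / (V_globe - V_l)."""
        labels, _, lms, truth = default_phantom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = extract_all_metrics(labels, lms, centres="labels")
        spec = PhantomSpec()
        d = truth.metrics[("dist_lens_globe_centre", "right")]
        v_lens = 4 / 3 * np.pi * np.prod(spec.lens_semiaxes)
        v_globe = 4 / 3 * np.pi * spec.globe_radius**3
        shift = v_lens * d / (v_globe - v_lens)
        assert rec[("dist_lens_globe_centre", "right")] == pytest.approx(
            d + shift, abs=0.1
        )

    def test_record_schema_is_closed(self):
        rec = MetricsRecord()
        with pytest.raises(KeyError):
            rec[("not_a_metric", "right")] = 1.0
        with pytest.raises(KeyError):
            rec[("globe_volume", "middle")] = 1.0
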