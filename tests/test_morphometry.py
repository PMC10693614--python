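"""Polygon smoothing, furthest pair, midline length, calibration, F1."""

import math

import numpy as np
import pytest

import dronesurvey as ds
from dronesurvey.morphometry import (
    BodyPolygon,
    area_perimeter,
    calibrate,
    f1_score,
    furthest_pair,
    midline_length,
    smooth_polygon,
    straight_length,
)

import helpers


def _regular_polygon(n=256, r=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return BodyPolygon(np.column_stack([r * np.cos(th), r * np.sin(th)]), unit="m")


def _thin_rectangle(length=300.0, height=1.0, n=150):
    xs = np.linspace(0, length, n)
    bottom = np.column_stack([xs, np.zeros(n)])
    top = np.column_stack([xs[::-1], np.full(n, height)])
    return BodyPolygon(np.vstack([bottom, top]), unit="cm")


class TestSmoothing:
    def test_vanishing_bandwidth_returns_input(self):
        poly = _regular_polygon(64)
        out = smooth_polygon(poly, 1e-12)
        np.testing.assert_allclose(out.vertices, poly.vertices, atol=1e-15)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            smooth_polygon(_regular_polygon(64), 0.0)

    def test_circle_radius_matches_cosine_sum_oracle(self):
        n, r, bw = 256, 1.0, 0.1
        sm = smooth_polygon(_regular_polygon(n, r), bw)
        radii = np.linalg.norm(sm.vertices, axis=1)
        expect = helpers.regular_polygon_smooth_radius(n, r, bw)
        np.testing.assert_allclose(radii, expect, atol=1e-9)

    def test_limbs_attenuated_body_preserved(self):
        # limb amplitude below the bandwidth: protrusion shrinks by >50%
        # while the half-width far from any limb moves by <5%
        poly, _ = ds.generate_body_polygon(
            250, 60, 0.0, n_limbs=2, limb_length=25, limb_width=10,
            vertex_count=512,
        )
        sm = smooth_polygon(poly, 0.3)
        v, u = poly.vertices * 100, sm.vertices * 100
        amp_orig = np.abs(v[:, 1]).max() - 30.0
        amp_sm = np.abs(u[:, 1]).max() - 30.0
        assert amp_sm < 0.5 * amp_orig
        sel_o = np.abs(v[:, 0] - 150) < 8
        sel_s = np.abs(u[:, 0] - 150) < 8
        hw_o = np.abs(v[sel_o, 1]).max()
        hw_s = np.abs(u[sel_s, 1]).max()
        assert abs(hw_s - hw_o) / hw_o < 0.05


class TestFurthestPair:
    def test_unit_square_diagonal_with_low_index_tiebreak(self):
        sq = BodyPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]), unit="m")
        i, j, d = furthest_pair(sq)
        assert (i, j) == (0, 2)
        assert d == pytest.approx(math.sqrt(2))

    def test_matches_exhaustive_search_on_random_polygons(self, rng):
        for _ in range(50):
            v = helpers.random_simple_polygon(rng, n=40)
            poly = BodyPolygon(v, unit="m")
            i, j, d = furthest_pair(poly)
            bi, bj, bd = helpers.brute_force_furthest(v)
            assert d == pytest.approx(bd, abs=1e-12)
            assert (i, j) == (bi, bj)

    def test_stadium_extremes_are_end_cap_apexes(self):
        poly, _ = ds.generate_body_polygon(250, 60, 0.0, n_limbs=0)
        i, j, d = furthest_pair(poly)
        ends = poly.vertices[[i, j]]
        # apexes sit on the centerline axis (y ~ 0) at the extreme x
        assert np.all(np.abs(ends[:, 1]) < 0.02)
        assert d * 100 == pytest.approx(250.0, rel=1e-3)


class TestMidline:
    def test_thin_rectangle_recovers_centerline(self):
        res = midline_length(_thin_rectangle(), bandwidth=2.0, resample_n=200)
        assert res.curved_length == pytest.approx(300.0, rel=0.01)

    def test_bent_capsule_recovers_known_length(self):
        poly, truth = ds.generate_body_polygon(250, 60, 0.8, n_limbs=4)
        res = midline_length(poly, bandwidth=0.5, resample_n=200)
        assert res.curved_length == pytest.approx(truth, rel=0.02)
        assert res.straight_length < res.curved_length

    def test_both_correction_modes_reported_and_close(self):
        poly, truth = ds.generate_body_polygon(250, 60, 0.5, n_limbs=4)
        a = midline_length(poly, 0.5, 200, correction="both_ends")
        b = midline_length(poly, 0.5, 200, correction="axis_gap")
        assert a.correction_mode == "both_ends"
        assert b.correction_mode == "axis_gap"
        assert a.curved_length == pytest.approx(truth, rel=0.02)
        assert b.curved_length == pytest.approx(truth, rel=0.02)

    def test_resampling_convergence(self):
        poly, _ = ds.generate_body_polygon(250, 60, 0.6, n_limbs=4)
        a = midline_length(poly, 0.5, 200).curved_length
        b = midline_length(poly, 0.5, 400).curved_length
        assert abs(a - b) / b < 0.002

    def test_straight_length_is_furthest_pair_distance(self, rng):
        for _ in range(10):
            poly = BodyPolygon(helpers.random_simple_polygon(rng), unit="m")
            _, _, d = furthest_pair(poly)
            assert straight_length(poly) == pytest.approx(d * 100, abs=1e-12)

    def test_rigid_motion_invariance_and_scale_equivariance(self):
        poly, _ = ds.generate_body_polygon(250, 60, 0.4, n_limbs=4)
        res = midline_length(poly, 0.5, 200)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = BodyPolygon(poly.vertices @ rot.T + [3.0, -8.0], unit="m")
        res2 = midline_length(moved, 0.5, 200)
        assert res2.curved_length == pytest.approx(res.curved_length, rel=1e-9)
        assert res2.area == pytest.approx(res.area, rel=1e-9)
        scaled = BodyPolygon(poly.vertices * 2.0, unit="m")
        res3 = midline_length(scaled, 1.0, 200)
        assert res3.straight_length == pytest.approx(2 * res.straight_length, rel=1e-9)
        assert res3.area == pytest.approx(4 * res.area, rel=1e-9)

    def test_degenerate_adjacent_extremes_raise(self):
        v = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 0.4], [4.9, 0.5]])
        with pytest.raises(ValueError):
            midline_length(BodyPolygon(v, unit="m"), bandwidth=1e-9, resample_n=20)


class TestAreaPerimeter:
    def test_unit_square(self):
        sq = BodyPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]), unit="cm")
        area, perim = area_perimeter(sq)
        assert area == pytest.approx(1.0)
        assert perim == pytest.approx(4.0)

    def test_fine_polygon_approximates_circle_area(self):
        circle = _regular_polygon(256, r=2.0)
        area, perim = area_perimeter(circle)
        assert area == pytest.approx(np.pi * (200.0) ** 2, rel=1e-3)

    def test_self_intersecting_polygon_rejected(self):
        bow = BodyPolygon(np.array([[0, 0], [2, 2], [2, 0], [0, 2]]), unit="m")
        with pytest.raises(ValueError):
            area_perimeter(bow)


class TestCalibration:
    def test_identity_data_gives_unit_regression(self):
        rep = calibrate([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert rep["slope"] == pytest.approx(1.0)
        assert rep["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert rep["r_squared"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.2, 2.9, 3.4, 5.1, 7.5])
        y = np.array([1.9, 3.3, 4.8, 6.0, 9.4])
        n = len(x)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        rep = calibrate(y, x)
        assert rep["slope"] == pytest.approx(slope, abs=1e-12)
        assert rep["intercept"] == pytest.approx(intercept, abs=1e-12)
        resid = y - (intercept + slope * x)
        r2 = 1 - resid.var() / y.var()
        assert rep["r_squared"] == pytest.approx(r2, abs=1e-12)
        assert rep["f_statistic"] == pytest.approx(r2 / (1 - r2) * (n - 2), rel=1e-9)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            calibrate([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_panel_pipeline_noiseless_calibration_is_identity(self):
        panels = ds.generate_panels(seed=3)
        measured = [straight_length(p) / 100 for p in panels]
        reference = [
            p.properties["side_m"] * math.sqrt(2) for p in panels
        ]  # square diagonal
        rep = calibrate(measured, reference)
        assert rep["slope"] == pytest.approx(1.0, rel=1e-9)
        assert rep["r_squared"] == pytest.approx(1.0)


class TestDetectionMetrics:
    def test_equal_precision_recall_equals_f1(self):
        m = f1_score(8, 2, 2)
        assert m.precision == m.recall == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)

    def test_direct_formula_evaluation(self):
        m = f1_score(8, 2, 1)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(8 / 9)
        assert m.f1 == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))

    def test_undefined_combinations_flagged_not_raised(self):
        m = f1_score(0, 0, 5)
        assert m.f1 == 0.0 and not m.defined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            f1_score(-1, 0, 0)


class TestGeoJSON:
    def test_roundtrip_preserves_geometry_and_properties(self, tmp_path):
        poly, _ = ds.generate_body_polygon(250, 60, 0.3, n_limbs=2)
        poly.properties["id"] = 7
        path = tmp_path / "polys.geojson"
        ds.write_polygons_geojson([poly], path)
        back = ds.read_polygons_geojson(path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].vertices, poly.vertices)
        assert back[0].properties["id"] == 7
        assert back[0].properties["truth_length_cm"] == 250.0

    def test_geographic_degrees_refused(self):
        with pytest.raises(ValueError):
            BodyPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]), unit="deg")
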