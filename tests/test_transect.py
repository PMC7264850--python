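"""Projection, contour estimation, signed distances, and binning."""

import numpy as np
import pandas as pd
import pytest

from hzclines import ZoneConfig, generate_zone
from hzclines.synthetic import contour_polyline
from hzclines.transect import (
    EARTH_RADIUS_M,
    ContourLine,
    estimate_contour,
    make_bins,
    project_coordinates,
    signed_distance,
    signed_distances,
)
from hzclines.transect import ContourError


class TestProjection:
    def test_centroid_maps_to_origin(self):
        df = pd.DataFrame({"tree_id": ["a"], "lon": [-115.5], "lat": [37.46]})
        out = project_coordinates(df)
        assert out["x_m"].iloc[0] == pytest.approx(0.0)
        assert out["y_m"].iloc[0] == pytest.approx(0.0)

    def test_latitude_arc_length(self):
        df = pd.DataFrame({"tree_id": ["a", "b"], "lon": [-115.5, -115.5],
                           "lat": [37.455, 37.465]})
        out = project_coordinates(df)
        dy = out["y_m"].iloc[1] - out["y_m"].iloc[0]
        assert dy == pytest.approx(EARTH_RADIUS_M * 0.01 * np.pi / 180.0, abs=0.1)
        assert dy == pytest.approx(1112.0, abs=0.5)

    def test_study_area_coordinates_handled(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "tree_id": [f"t{i}" for i in range(20)],
            "lon": -115.5 + rng.uniform(-0.1, 0.1, 20),
            "lat": 37.46 + rng.uniform(-0.05, 0.05, 20),
        })
        out = project_coordinates(df)
        assert np.all(np.isfinite(out[["x_m", "y_m"]].to_numpy()))

    def test_round_trip_inversion(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "tree_id": [f"t{i}" for i in range(10)],
            "lon": -115.5 + rng.uniform(-0.1, 0.1, 10),
            "lat": 37.46 + rng.uniform(-0.05, 0.05, 10),
        })
        from hzclines.transect import unproject_coordinates

        back = unproject_coordinates(project_coordinates(df))
        np.testing.assert_allclose(back["lon"], df["lon"], atol=1e-10)
        np.testing.assert_allclose(back["lat"], df["lat"], atol=1e-10)

    def test_planar_passthrough_and_mixed_rejection(self):
        planar = pd.DataFrame({"tree_id": ["a"], "x_m": [3.0], "y_m": [4.0]})
        assert project_coordinates(planar)["x_m"].iloc[0] == 3.0
        mixed = pd.DataFrame({"tree_id": ["a"], "x_m": [0.0], "y_m": [0.0],
                              "lon": [0.0], "lat": [0.0]})
        with pytest.raises(ValueError, match="mixed"):
            project_coordinates(mixed)


class TestContour:
    def test_logistic_field_midpoint(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.uniform(-4000, 4000, 400), rng.uniform(0, 3000, 400)])
        q = 1.0 / (1.0 + np.exp(-4.0 * (pts[:, 0] - 500.0) / 1500.0))
        c = estimate_contour(pts, q, grid_resolution=200.0)
        assert np.max(np.abs(c.vertices[:, 0] - 500.0)) < 200.0

    def test_level_outside_range_errors(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(0, 1000, 50), rng.uniform(0, 1000, 50)])
        with pytest.raises(ContourError, match="no contour"):
            estimate_contour(pts, np.full(50, 0.3), grid_resolution=100.0)

    def test_sinusoid_zone_recovered_within_hausdorff_bound(self):
        cfg = ZoneConfig(n_trees=600, n_snps=0, seed=13, contour_shape="sinusoid",
                         contour_amplitude=800.0, contour_period=4000.0)
        trees = generate_zone(cfg)
        pts = np.array([[t.x, t.y] for t in trees])
        q = np.array([t.q_true for t in trees])
        grid_res = 250.0
        est = estimate_contour(pts, q, grid_resolution=grid_res)
        truth = contour_polyline(cfg, n_points=800)

        def directed(a, b):
            return max(
                abs(signed_distance(p, ContourLine(b, 1.0), np.array([-1e6, 0.0])))
                for p in a
            )

        # clip the estimated contour to the core y-range to avoid edge effects
        core = est.vertices[(est.vertices[:, 1] > 500) & (est.vertices[:, 1] < 3500)]
        h = max(directed(core, truth.vertices), directed(truth.vertices[
            (truth.vertices[:, 1] > 500) & (truth.vertices[:, 1] < 3500)], est.vertices))
        assert h < 2 * grid_res


class TestSignedDistance:
    def test_vertical_line_perpendicular_distance(self):
        line = ContourLine(np.array([[0.0, -10.0], [0.0, 10.0]]), 1.0)
        d = signed_distance(np.array([3.0, 4.0]), line, np.array([-10.0, 0.0]))
        assert d == pytest.approx(3.0)
        d_west = signed_distance(np.array([-3.0, 4.0]), line, np.array([-10.0, 0.0]))
        assert d_west == pytest.approx(-3.0)

    def test_point_on_contour_is_zero(self):
        line = ContourLine(np.array([[0.0, 0.0], [100.0, 100.0]]), 1.0)
        assert signed_distance(np.array([50.0, 50.0]), line, np.array([0.0, 100.0])) == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        # a wiggly polyline
        ys = np.linspace(0.0, 1000.0, 40)
        xs = 100.0 * np.sin(ys / 80.0) + 5.0 * rng.standard_normal(40)
        line = ContourLine(np.column_stack([xs, ys]), 1.0)
        from shapely.geometry import LineString, Point

        oracle = LineString(line.vertices)
        ref = np.array([-500.0, 500.0])
        pts = np.column_stack([rng.uniform(-400, 400, 100), rng.uniform(-100, 1100, 100)])
        got = signed_distances(pts, line, ref)
        for p, g in zip(pts, got):
            assert abs(abs(g) - Point(p).distance(oracle)) < 1e-6

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ContourLine(np.array([[1.0, 1.0], [1.0, 1.0]]), 1.0)


class TestMakeBins:
    def test_engineered_19_bins(self):
        # 19 x 250 m bins, 5 trees each, evenly filled
        d = np.concatenate([np.full(5, -2375.0 + 250.0 * i + 125.0) for i in range(19)])
        ids = [f"t{i}" for i in range(len(d))]
        bins = make_bins(ids, d, bin_width=250.0, min_per_bin=3)
        assert len(bins) == 19

    def test_single_location_single_bin(self):
        bins = make_bins(["a", "b", "c", "d"], np.zeros(4))
        assert len(bins) == 1
        assert bins[0].n_trees == 4

    def test_membership_conserved_under_collapse(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            d = rng.normal(0, 1200, 80)
            ids = [f"t{trial}_{i}" for i in range(80)]
            bins = make_bins(ids, d, bin_width=250.0, min_per_bin=3)
            members = sorted(tid for b in bins for tid in b.member_ids)
            assert members == sorted(ids)
            assert all(b.n_trees >= 3 for b in bins)
            centers = [b.mean_distance for b in bins]
            assert centers == sorted(centers)

    def test_too_few_trees_errors(self):
        with pytest.raises(ValueError):
            make_bins(["a"], np.array([0.0]), min_per_bin=3)

    def test_nan_distances_excluded(self):
        d = np.array([0.0, 10.0, 20.0, np.nan])
        bins = make_bins(["a", "b", "c", "d"], d, bin_width=250.0, min_per_bin=3)
        assert sum(b.n_trees for b in bins) == 3
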