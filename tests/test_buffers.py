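import numpy as np
import pytest
from shapely.geometry import Polygon, box

import lurkit as lk
from lurkit.buffers import GeoLayer, extract_at_point, read_geojson, write_geojson
from lurkit.geodata import ValidationError
from lurkit.raster import Raster


def _point_layer(pts, **kw):
    return GeoLayer("pts", "points", points=np.asarray(pts, float), **kw)


class TestPointCounts:
    def test_empty_layer(self):
        assert lk.count_points_in_buffer(_point_layer(np.empty((0, 2))), (0, 0), 500) == 0

    def test_enumerated_distances(self):
        pts = [(100, 0), (0, 400), (600, 0)]
        assert lk.count_points_in_buffer(_point_layer(pts), (0, 0), 500) == 2

    def test_center_point_and_closed_boundary(self):
        layer = _point_layer([(0, 0), (25, 0)])
        assert lk.count_points_in_buffer(layer, (0, 0), 25) == 2  # boundary in

    def test_random_configs_match_brute_force(self, rng):
        for _ in range(30):
            pts = rng.uniform(-2000, 2000, (200, 2))
            c = rng.uniform(-500, 500, 2)
            r = rng.uniform(100, 1500)
            brute = sum(
                1 for p in pts if np.hypot(p[0] - c[0], p[1] - c[1]) <= r
            )
            assert lk.count_points_in_buffer(_point_layer(pts), c, r) == brute


class TestLineLength:
    def test_diameter_chord(self):
        layer = GeoLayer("l", "lines", lines=[np.array([[-5000.0, 0], [5000.0, 0]])])
        assert lk.line_length_in_buffer(layer, (0, 0), 500) == pytest.approx(1000.0)

    def test_disjoint_segment(self):
        layer = GeoLayer("l", "lines", lines=[np.array([[2000.0, 2000], [3000.0, 3000]])])
        assert lk.line_length_in_buffer(layer, (0, 0), 500) == 0.0

    def test_zero_length_segment(self):
        layer = GeoLayer("l", "lines", lines=[np.array([[10.0, 10.0], [10.0, 10.0]])])
        assert lk.line_length_in_buffer(layer, (0, 0), 500) == 0.0

    def test_random_segments_match_dense_sampling(self, rng):
        r = 500.0
        for _ in range(10):
            segs = [rng.uniform(-1200, 1200, (2, 2)) for _ in range(10)]
            layer = GeoLayer("l", "lines", lines=segs)
            got = lk.line_length_in_buffer(layer, (0, 0), r)
            step = 0.01
            total = 0.0
            for seg in segs:
                d = seg[1] - seg[0]
                length = float(np.hypot(*d))
                if length == 0:
                    continue
                n = int(length / step)
                t = (np.arange(n) + 0.5) / n
                pts = seg[0] + t[:, None] * d
                inside = (pts**2).sum(axis=1) <= r * r
                total += inside.sum() * (length / n)
            assert got == pytest.approx(total, rel=5e-3, abs=0.5)


class TestPolygonArea:
    def test_full_disk(self):
        layer = GeoLayer("p", "polygons", polygons=[box(-2000, -2000, 2000, 2000)])
        got = lk.polygon_area_in_buffer(layer, (0, 0), 500)
        assert got == pytest.approx(np.pi * 500**2, rel=5e-4)

    def test_half_disk(self):
        layer = GeoLayer("p", "polygons", polygons=[box(0, -2000, 4000, 2000)])
        got = lk.polygon_area_in_buffer(layer, (0, 0), 500)
        assert got == pytest.approx(np.pi * 500**2 / 2, rel=5e-4)

    def test_overlapping_polygons_not_double_counted(self):
        sq = box(-1000, -1000, 1000, 1000)
        layer1 = GeoLayer("p", "polygons", polygons=[sq])
        layer2 = GeoLayer("p", "polygons", polygons=[sq, sq])
        a1 = lk.polygon_area_in_buffer(layer1, (0, 0), 500)
        a2 = lk.polygon_area_in_buffer(layer2, (0, 0), 500)
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_invalid_polygon_named(self):
        bowtie = Polygon([(0, 0), (100, 100), (100, 0), (0, 100)])
        layer = GeoLayer("p", "polygons", polygons=[box(0, 0, 10, 10), bowtie])
        with pytest.raises(ValidationError, match="polygon 1"):
            lk.polygon_area_in_buffer(layer, (0, 0), 500)

    def test_random_rectangles_match_monte_carlo(self, rng):
        r = 600.0
        for _ in range(5):
            polys = [
                box(*np.sort(rng.uniform(-1500, 1500, 2)),
                    *np.sort(rng.uniform(-1500, 1500, 2)))
                for _ in range(6)
            ]
            layer = GeoLayer("p", "polygons", polygons=polys)
            got = lk.polygon_area_in_buffer(layer, (0, 0), r)
            n = 200_000
            rho = np.sqrt(rng.uniform(0, 1, n)) * r
            theta = rng.uniform(0, 2 * np.pi, n)
            x, y = rho * np.cos(theta), rho * np.sin(theta)
            from shapely import contains_xy
            from shapely.ops import unary_union
            hit = contains_xy(unary_union(polys), x, y).mean()
            disk = np.pi * r * r
            se = disk * np.sqrt(max(hit * (1 - hit), 1e-9) / n)
            assert abs(got - hit * disk) < 3 * se + 1e-3 * disk


class TestRasterMean:
    def _raster(self, vals):
        return GeoLayer("r", "raster",
                        raster=Raster(vals, 0.0, 0.0, 100.0),
                        radii=(250.0, 500.0))

    def test_constant_field(self):
        layer = self._raster(np.full((20, 20), 3.25))
        assert lk.raster_mean_in_buffer(layer, (1000, 1000), 700) == 3.25

    def test_single_cell(self, rng):
        vals = rng.normal(size=(20, 20))
        layer = self._raster(vals)
        # centre of cell (row from top = 19-5 = 14, col = 3)
        got = lk.raster_mean_in_buffer(layer, (350.0, 550.0), 50.0)
        assert got == vals[14, 3]

    def test_random_configs_match_enumeration(self, rng):
        for _ in range(20):
            vals = rng.normal(size=(15, 18))
            rast = Raster(vals, rng.uniform(-100, 100), rng.uniform(-100, 100), 100.0)
            layer = GeoLayer("r", "raster", raster=rast, radii=(250.0,))
            c = (rng.uniform(0, 1800), rng.uniform(0, 1500))
            r = rng.uniform(60, 800)
            acc = []
            for row in range(15):
                for col in range(18):
                    x = rast.origin_x + (col + 0.5) * 100.0
                    y = rast.origin_y + (15 - row - 0.5) * 100.0
                    if (x - c[0]) ** 2 + (y - c[1]) ** 2 <= r * r:
                        acc.append(vals[row, col])
            expect = float(np.mean(acc)) if acc else float("nan")
            got = lk.raster_mean_in_buffer(layer, c, r)
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, rel=1e-12)

    def test_outside_extent_warns_and_missing(self):
        layer = self._raster(np.ones((5, 5)))
        with pytest.warns(UserWarning):
            got = lk.raster_mean_in_buffer(layer, (50_000, 50_000), 300)
        assert np.isnan(got)

    def test_radius_below_half_cell_rejected(self):
        layer = self._raster(np.ones((5, 5)))
        with pytest.raises(ValueError):
            lk.raster_mean_in_buffer(layer, (250, 250), 10.0)


class TestNearestDistance:
    def test_singleton_and_zero(self):
        layer = _point_layer([(0.0, 1234.5)], mode="nearest_distance")
        assert lk.nearest_distance(layer, (0, 0)) == pytest.approx(1234.5)
        assert lk.nearest_distance(layer, (0, 1234.5)) == 0.0

    def test_empty_layer_error(self):
        layer = _point_layer(np.empty((0, 2)), mode="nearest_distance")
        with pytest.raises(ValueError):
            lk.nearest_distance(layer, (0, 0))

    def test_random_matches_brute_force(self, rng):
        pts = rng.uniform(-5000, 5000, (100, 2))
        layer = _point_layer(pts, mode="nearest_distance")
        c = rng.uniform(-1000, 1000, 2)
        brute = min(np.hypot(p[0] - c[0], p[1] - c[1]) for p in pts)
        assert lk.nearest_distance(layer, c) == pytest.approx(brute, rel=1e-12)


class TestGeometricProperties:
    """Monotonicity, locality and translation invariance of the engine."""

    def _random_layers(self, rng):
        return [
            _point_layer(rng.uniform(0, 8000, (150, 2)), radii=(100.0, 500.0, 2000.0)),
            GeoLayer("ln", "lines",
                     lines=[rng.uniform(0, 8000, (2, 2)) for _ in range(40)],
                     radii=(100.0, 500.0, 2000.0)),
            GeoLayer("pg", "polygons",
                     polygons=[box(x, y, x + rng.uniform(100, 900),
                                   y + rng.uniform(100, 900))
                               for x, y in rng.uniform(0, 8000, (30, 2))],
                     radii=(100.0, 500.0, 2000.0)),
        ]

    def test_monotone_in_radius(self, rng):
        radii = list(lk.DEFAULT_RADII)
        for _ in range(5):
            layers = self._random_layers(rng)
            c = rng.uniform(1000, 7000, 2)
            for layer in layers:
                op = {"points": lk.count_points_in_buffer,
                      "lines": lk.line_length_in_buffer,
                      "polygons": lk.polygon_area_in_buffer}[layer.kind]
                vals = [op(layer, c, r) for r in radii]
                assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:])), layer.kind

    def test_locality(self, rng):
        """Discarding geometry beyond r + eps leaves the value unchanged."""
        r, eps = 800.0, 1.0
        c = np.array([4000.0, 4000.0])
        pts = rng.uniform(0, 8000, (300, 2))
        layer = _point_layer(pts)
        keep = np.hypot(*(pts - c).T) <= r + eps
        near = _point_layer(pts[keep])
        assert (lk.count_points_in_buffer(layer, c, r)
                == lk.count_points_in_buffer(near, c, r))

    def test_translation_invariance(self, rng):
        shift = np.array([12345.6789, -9876.54321])
        c = np.array([2000.0, 3000.0])
        layers = self._random_layers(rng)
        for layer in layers:
            op = {"points": lk.count_points_in_buffer,
                  "lines": lk.line_length_in_buffer,
                  "polygons": lk.polygon_area_in_buffer}[layer.kind]
            before = op(layer, c, 700.0)
            if layer.kind == "points":
                moved = _point_layer(layer.points + shift)
            elif layer.kind == "lines":
                moved = GeoLayer("ln", "lines",
                                 lines=[l + shift for l in layer.lines])
            else:
                from shapely.affinity import translate
                moved = GeoLayer("pg", "polygons",
                                 polygons=[translate(p, *shift) for p in layer.polygons])
            after = op(moved, c + shift, 700.0)
            assert after == pytest.approx(before, rel=1e-9, abs=1e-6)


class TestDesignMatrix:
    def test_static_layer_repeats_across_years(self, rng):
        import pandas as pd
        stations = [lk.StationRecord("S1", 1000.0, 1000.0, 10.0),
                    lk.StationRecord("S2", 4000.0, 4000.0, 20.0)]
        periods = pd.DataFrame({
            "station_id": ["S1", "S2"] * 3,
            "period": [str(y) for y in (2010, 2010, 2011, 2011, 2012, 2012)],
            "mean_nox": rng.uniform(10, 40, 6),
        })
        layer = _point_layer(rng.uniform(0, 5000, (50, 2)), radii=(500.0, 1000.0))
        table = lk.build_design_matrix(stations, periods, [layer])
        assert len(table) == 6
        for sid in ("S1", "S2"):
            sub = table.data[table.data["station_id"] == sid]
            assert sub["pts@500"].nunique() == 1
            assert sub["pts@1000"].nunique() == 1

    def test_values_match_individual_extraction(self, small_scene):
        scene, design, _ = small_scene
        st = scene.stations[3]
        row = design.data[(design.data["station_id"] == st.station_id)].iloc[0]
        for layer in scene.layers:
            for col, val in extract_at_point(layer, (st.x, st.y)).items():
                assert row[col] == pytest.approx(val, rel=1e-12), col

    def test_zero_layers_gives_covariates_only(self, rng):
        import pandas as pd
        stations = [lk.StationRecord("S1", 0.0, 0.0, 10.0)]
        periods = pd.DataFrame({"station_id": ["S1"], "period": ["2010"],
                                "mean_nox": [25.0]})
        table = lk.build_design_matrix(stations, periods, [])
        assert set(table.predictor_columns) == {"nox", "altitude"}

    def test_unknown_station_rejected(self, rng):
        import pandas as pd
        stations = [lk.StationRecord("S1", 0.0, 0.0, 10.0)]
        periods = pd.DataFrame({"station_id": ["S1", "S9"], "period": ["2010"] * 2,
                                "mean_nox": [25.0, 30.0]})
        with pytest.raises(ValueError, match="S9"):
            lk.build_design_matrix(stations, periods, [])

    def test_csv_sidecar_round_trip(self, tmp_path, small_scene):
        _, design, _ = small_scene
        path = tmp_path / "design.csv"
        design.to_csv(path)
        back = lk.PredictorTable.from_csv(path)
        assert back.predictor_columns == design.predictor_columns
        assert back.sign_priors() == design.sign_priors()
        np.testing.assert_allclose(
            back.data[back.predictor_columns].to_numpy(float),
            design.data[design.predictor_columns].to_numpy(float), rtol=1e-12)


class TestGeoJSON:
    def test_layer_round_trip(self, tmp_path, small_scene):
        scene, _, _ = small_scene
        for layer in scene.layers:
            if layer.kind == "raster":
                continue
            p = tmp_path / f"{layer.name}.geojson"
            write_geojson(layer, p)
            back = read_geojson(p)
            assert (back.name, back.kind, back.sign_prior, back.mode) == \
                (layer.name, layer.kind, layer.sign_prior, layer.mode)
            c = (scene.config.width / 2, scene.config.height / 2)
            assert extract_at_point(back, c) == extract_at_point(layer, c)
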