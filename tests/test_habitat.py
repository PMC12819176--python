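"""GeoJSON habitat I/O, port buffering, point-in-polygon classification
and habitat-use proportions."""

import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import cpforage as cf
from cpforage.geometry import LocalProjection
from cpforage.habitats import HabitatPolygon, HabitatValidationError


def _feature(name, category, htype, priority, coords):
    return {
        "type": "Feature",
        "properties": {"name": name, "category": category,
                       "habitat_type": htype, "priority": priority},
        "geometry": {"type": "Polygon", "coordinates": [coords]},
    }


SQUARE = [[-71.4, -29.9], [-71.3, -29.9], [-71.3, -29.8], [-71.4, -29.8], [-71.4, -29.9]]
BOWTIE = [[0, 0], [1, 1], [1, 0], [0, 1], [0, 0]]


class TestHabitatIO:
    def _write(self, tmp_path, features):
        p = tmp_path / "h.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
        return p

    def test_two_valid_features_read(self, tmp_path):
        p = self._write(tmp_path, [
            _feature("wet", "natural", "wetland", 3, SQUARE),
            _feature("dump", "anthropogenic", "landfill", 2,
                     [[c[0] + 1, c[1]] for c in SQUARE]),
        ])
        polys = cf.read_habitat_polygons(p)
        assert [pl.name for pl in polys] == ["wet", "dump"]

    def test_unknown_category_fatal(self, tmp_path):
        p = self._write(tmp_path, [_feature("x", "city", "wetland", 1, SQUARE)])
        with pytest.raises(HabitatValidationError, match="category"):
            cf.read_habitat_polygons(p)

    def test_type_category_mismatch_fatal(self, tmp_path):
        p = self._write(tmp_path, [_feature("x", "natural", "landfill", 1, SQUARE)])
        with pytest.raises(HabitatValidationError, match="inconsistent"):
            cf.read_habitat_polygons(p)

    def test_missing_property_fatal(self, tmp_path):
        feat = _feature("x", "natural", "wetland", 1, SQUARE)
        del feat["properties"]["priority"]
        p = self._write(tmp_path, [feat])
        with pytest.raises(HabitatValidationError, match="priority"):
            cf.read_habitat_polygons(p)

    def test_self_intersecting_ring_fatal_with_name(self, tmp_path):
        p = self._write(tmp_path, [_feature("bow", "natural", "wetland", 1, BOWTIE)])
        with pytest.raises(HabitatValidationError, match="bow"):
            cf.read_habitat_polygons(p)

    def test_unclosed_ring_auto_closed(self, tmp_path):
        p = self._write(tmp_path, [_feature("sq", "natural", "wetland", 1, SQUARE[:-1])])
        (poly,) = cf.read_habitat_polygons(p)
        assert poly.geometry.is_valid and poly.geometry.area > 0

    def test_roundtrip(self, tmp_path, habitat_map):
        p = tmp_path / "out.geojson"
        cf.write_habitat_polygons(habitat_map, p)
        back = cf.read_habitat_polygons(p)
        assert [b.name for b in back] == [h.name for h in habitat_map]
        for b, h in zip(back, habitat_map):
            assert b.geometry.symmetric_difference(h.geometry).area < 1e-12


def _port(side_m=200.0, lat0=-29.95, lon0=-71.39):
    proj = LocalProjection(lat0, lon0)
    half = side_m / 2.0
    lat_a, lon_a = proj.to_latlon(-half, -half)
    lat_b, lon_b = proj.to_latlon(half, half)
    return HabitatPolygon("port", "anthropogenic", "fish_market_cove_port", 1,
                          box(min(lon_a, lon_b), min(lat_a, lat_b),
                              max(lon_a, lon_b), max(lat_a, lat_b)))


class TestPortBuffer:
    def test_zero_buffers_identity(self):
        core = _port()
        out = cf.buffer_port_polygon(core, 270.0, offshore_km=0.0, inland_m=0.0)
        # every vertex within 1 m of the original geometry
        assert out.geometry.symmetric_difference(core.geometry).area < 1e-10

    def test_square_area_matches_analytic_half_dilation(self):
        core = _port(side_m=200.0)
        out = cf.buffer_port_polygon(core, 270.0, offshore_km=1.0, inland_m=200.0)
        proj = LocalProjection(-29.95, -71.39)
        import shapely
        local = shapely.transform(
            out.geometry,
            lambda pts: np.column_stack(proj.to_xy(pts[:, 1], pts[:, 0])),
        )
        a, r1, r2 = 200.0, 1000.0, 200.0
        analytic = a * a + 2 * a * (r1 + r2) + np.pi * (r1 ** 2 + r2 ** 2) / 2.0
        assert abs(local.area - analytic) / analytic < 0.02

    def test_seaward_point_membership(self):
        core = _port(side_m=200.0)
        out = cf.buffer_port_polygon(core, 270.0, offshore_km=1.0, inland_m=200.0)
        proj = LocalProjection(-29.95, -71.39)
        from shapely.geometry import Point
        # 900 m seaward (west) of the dockside (west edge at x=-100 m)
        lat, lon = proj.to_latlon(-100.0 - 900.0, 0.0)
        assert out.geometry.covers(Point(lon, lat))
        lat, lon = proj.to_latlon(-100.0 - 1200.0, 0.0)
        assert not out.geometry.covers(Point(lon, lat))
        # inland side is limited to 200 m
        lat, lon = proj.to_latlon(100.0 + 150.0, 0.0)
        assert out.geometry.covers(Point(lon, lat))
        lat, lon = proj.to_latlon(100.0 + 400.0, 0.0)
        assert not out.geometry.covers(Point(lon, lat))

    def test_degenerate_polygon_fatal(self):
        from shapely.geometry import Polygon
        degen = HabitatPolygon("p", "anthropogenic", "fish_market_cove_port", 1,
                               Polygon([(0, 0), (0, 1), (0, 2), (0, 0)]))
        with pytest.raises(HabitatValidationError):
            cf.buffer_port_polygon(degen, 270.0)

    def test_wrong_type_rejected(self):
        wrong = HabitatPolygon("w", "natural", "wetland", 3, box(0, 0, 1, 1))
        with pytest.raises(ValueError):
            cf.buffer_port_polygon(wrong, 270.0)


def _winding_number_inside(lat, lon, ring):
    """Independent even-odd ray-casting point-in-polygon oracle."""
    x, y = lon, lat
    inside = False
    n = len(ring)
    j = n - 1
    for i in range(n):
        xi, yi = ring[i]
        xj, yj = ring[j]
        if (yi > y) != (yj > y):
            x_cross = (xj - xi) * (y - yi) / (yj - yi) + xi
            if x < x_cross:
                inside = not inside
        j = i
    return inside


class TestAssignHabitat:
    def test_centroid_gets_polygon_label(self, habitat_map):
        landfill = next(p for p in habitat_map if p.name == "landfill_south")
        c = landfill.geometry.centroid
        out = cf.assign_habitat(pd.DataFrame({"lat": [c.y], "lon": [c.x]}), habitat_map)
        assert out["habitat_type"].iloc[0] == "landfill"

    def test_priority_resolves_overlaps(self, habitat_map):
        # the buffered port overlaps the open sea; the port (priority 1) wins
        port = next(p for p in habitat_map if p.name == "port_south_influence")
        sea = next(p for p in habitat_map if p.name == "sea_south")
        inter = port.geometry.intersection(sea.geometry)
        pt = inter.representative_point()
        out = cf.assign_habitat(pd.DataFrame({"lat": [pt.y], "lon": [pt.x]}), habitat_map)
        assert out["habitat_type"].iloc[0] == "fish_market_cove_port"

    def test_point_outside_everything_unclassified(self, habitat_map):
        out = cf.assign_habitat(pd.DataFrame({"lat": [0.0], "lon": [0.0]}), habitat_map)
        assert out["habitat_type"].iloc[0] == "unclassified"

    def test_agrees_with_ray_casting_oracle_on_random_points(self):
        rng = np.random.default_rng(5)
        polys = [
            HabitatPolygon("a", "natural", "wetland", 2, box(-71.45, -30.0, -71.35, -29.9)),
            HabitatPolygon("b", "anthropogenic", "landfill", 1,
                           box(-71.40, -29.95, -71.30, -29.85)),
        ]
        lats = rng.uniform(-30.05, -29.80, 10_000)
        lons = rng.uniform(-71.50, -71.25, 10_000)
        out = cf.assign_habitat(pd.DataFrame({"lat": lats, "lon": lons}), polys)
        rings = {p.name: list(p.geometry.exterior.coords) for p in polys}
        for lat, lon, got in zip(lats, lons, out["habitat_type"]):
            in_a = _winding_number_inside(lat, lon, rings["a"])
            in_b = _winding_number_inside(lat, lon, rings["b"])
            expect = "landfill" if in_b else ("wetland" if in_a else "unclassified")
            assert got == expect

    def test_label_invariant_under_polygon_order(self, habitat_map):
        rng = np.random.default_rng(7)
        pts = pd.DataFrame({
            "lat": rng.uniform(-30.1, -29.1, 500),
            "lon": rng.uniform(-71.6, -71.2, 500),
        })
        a = cf.assign_habitat(pts, habitat_map)
        shuffled = list(habitat_map)
        rng.shuffle(shuffled)
        b = cf.assign_habitat(pts, shuffled)
        assert (a["habitat_type"] == b["habitat_type"]).all()


class TestProportions:
    def _table(self, types, cats, bird="A", status="urban", season="summer"):
        return pd.DataFrame({
            "bird_id": bird, "status": status, "season": season,
            "habitat_type": types, "habitat_category": cats,
        })

    def test_simple_arithmetic(self):
        t = self._table(
            ["landfill"] * 60 + ["open_sea"] * 40,
            ["anthropogenic"] * 60 + ["natural"] * 40,
        )
        use = cf.bird_season_use(t)
        assert use["prop_anthropogenic"].iloc[0] == pytest.approx(0.60)

    def test_all_natural_gives_zero(self):
        t = self._table(["open_sea"] * 30, ["natural"] * 30)
        assert cf.bird_season_use(t)["prop_anthropogenic"].iloc[0] == 0.0

    def test_per_group_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        types = rng.choice(["landfill", "open_sea", "wetland", "unclassified"], 500)
        cats = np.select(
            [types == "landfill", types == "unclassified"],
            ["anthropogenic", "unclassified"], "natural",
        )
        t = self._table(types, cats)
        long = cf.habitat_proportions(t)
        assert long.groupby(["bird_id", "season"])["proportion"].sum().iloc[0] == pytest.approx(1.0)

    def test_unclassified_excluded_from_dichotomy(self):
        t = self._table(
            ["landfill"] * 30 + ["open_sea"] * 30 + ["unclassified"] * 40,
            ["anthropogenic"] * 30 + ["natural"] * 30 + ["unclassified"] * 40,
        )
        assert cf.bird_season_use(t)["prop_anthropogenic"].iloc[0] == pytest.approx(0.5)

    def test_recovers_sampling_weights_on_labelled_points(self, habitat_map):
        # points drawn inside polygons with anthropogenic weight 0.7
        rng = np.random.default_rng(3)
        anthro = [p for p in habitat_map if p.category == "anthropogenic"]
        natural = [p for p in habitat_map if p.category == "natural"]
        pts = []
        for _ in range(2500):
            pool = anthro if rng.random() < 0.7 else natural
            poly = pool[rng.integers(len(pool))]
            c = poly.geometry.representative_point()
            pts.append((c.y, c.x))
        df = pd.DataFrame(pts, columns=["lat", "lon"])
        df["bird_id"] = "A"
        df["status"] = "urban"
        df["season"] = "summer"
        labelled = cf.assign_habitat(df, habitat_map)
        got = cf.bird_season_use(labelled)["prop_anthropogenic"].iloc[0]
        assert got == pytest.approx(0.7, abs=0.05)
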