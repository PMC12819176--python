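"""Habitat polygons: GeoJSON I/O, port buffering, point classification,
and per-bird-season habitat-use proportions.

Habitats follow the field dichotomy for coastal gulls: *natural* (coastal
areas, open sea, wetlands, rocky shores, sandy beaches, uninhabited islands)
versus *anthropogenic* (urban/suburban areas, landfills, agricultural
fields, recreational beaches, fish markets/coves/ports). Overlapping
polygons are resolved by an explicit integer priority (lower wins), so e.g.
a buffered port supersedes the open sea it overlaps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape
from shapely.strtree import STRtree

from .geometry import LocalProjection
from .io import seasons_of

logger = logging.getLogger(__name__)

NATURAL_TYPES = frozenset({
    "coastal_area", "open_sea", "wetland", "rocky_shore", "sandy_beach",
    "uninhabited_island",
})
ANTHROPOGENIC_TYPES = frozenset({
    "urban_suburban", "landfill", "agricultural_field", "recreational_beach",
    "fish_market_cove_port",
})
CATEGORIES = ("natural", "anthropogenic")
UNCLASSIFIED = "unclassified"


class HabitatValidationError(ValueError):
    pass


@dataclass
class HabitatPolygon:
    """Named habitat polygon with its class attributes.

    ``priority``: lower number wins where polygons overlap.
    ``geometry``: shapely (Multi)Polygon in WGS84 lon/lat order.
    """

    name: str
    category: str
    habitat_type: str
    priority: int
    geometry: Polygon

    def validate(self) -> "HabitatPolygon":
        if self.category not in CATEGORIES:
            raise HabitatValidationError(
                f"{self.name}: category {self.category!r} not in {CATEGORIES}"
            )
        expected = NATURAL_TYPES if self.category == "natural" else ANTHROPOGENIC_TYPES
        if self.habitat_type not in expected:
            raise HabitatValidationError(
                f"{self.name}: habitat_type {self.habitat_type!r} inconsistent "
                f"with category {self.category!r}"
            )
        if self.geometry.is_empty or self.geometry.area == 0:
            raise HabitatValidationError(f"{self.name}: degenerate (zero-area) geometry")
        if not self.geometry.is_valid:
            raise HabitatValidationError(f"{self.name}: self-intersecting ring")
        return self


def read_habitat_polygons(path) -> list[HabitatPolygon]:
    """Read a GeoJSON FeatureCollection of habitat polygons.

    Each feature must carry properties ``name``, ``category``
    (natural/anthropogenic), ``habitat_type`` and integer ``priority``.
    Rings are closed automatically (GeoJSON implies closure); self-
    intersecting rings are fatal, reported with the feature name.
    """
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise HabitatValidationError("input is not a GeoJSON FeatureCollection")
    polys = []
    for feat in fc.get("features", []):
        props = feat.get("properties") or {}
        for key in ("name", "category", "habitat_type", "priority"):
            if key not in props:
                raise HabitatValidationError(f"feature missing property {key!r}")
        geom = shape(feat["geometry"])
        polys.append(
            HabitatPolygon(
                name=str(props["name"]),
                category=str(props["category"]),
                habitat_type=str(props["habitat_type"]),
                priority=int(props["priority"]),
                geometry=geom,
            ).validate()
        )
    return polys


def write_habitat_polygons(polys, path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {
                    "name": p.name,
                    "category": p.category,
                    "habitat_type": p.habitat_type,
                    "priority": p.priority,
                },
                "geometry": mapping(p.geometry),
            }
            for p in polys
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def buffer_port_polygon(
    core: HabitatPolygon,
    seaward_bearing_deg: float,
    offshore_km: float = 1.0,
    inland_m: float = 200.0,
) -> HabitatPolygon:
    """Dilate a fish-market/cove/port polygon into its area of influence.

    Ports attract gulls beyond the dockside: fish remains are discarded
    roughly 1 km offshore and processing/waste facilities extend ~200 m
    inland. The core polygon is buffered by ``offshore_km`` on its seaward
    half and ``inland_m`` on its landward half, split by the line through
    the centroid perpendicular to ``seaward_bearing_deg`` (degrees clockwise
    from north, pointing to sea). Work happens in a local equirectangular
    projection centred on the centroid, then returns to WGS84.
    """
    if core.habitat_type != "fish_market_cove_port":
        raise ValueError("buffer_port_polygon applies to fish_market_cove_port polygons")
    if core.geometry.area == 0:
        raise HabitatValidationError(f"{core.name}: degenerate polygon")
    c = core.geometry.centroid
    proj = LocalProjection(c.y, c.x)

    def to_local(geom):
        return shapely.transform(geom, lambda pts: np.column_stack(proj.to_xy(pts[:, 1], pts[:, 0])))

    def to_wgs(geom):
        def f(pts):
            lat, lon = proj.to_latlon(pts[:, 0], pts[:, 1])
            return np.column_stack([lon, lat])
        return shapely.transform(geom, f)

    local = to_local(core.geometry)
    r_sea = offshore_km * 1000.0
    r_land = float(inland_m)
    if r_sea == 0 and r_land == 0:
        return replace(core)
    # seaward unit vector (bearing measured clockwise from north)
    ux = np.sin(np.radians(seaward_bearing_deg))
    uy = np.cos(np.radians(seaward_bearing_deg))
    big = 1e6
    # half-planes through the local origin (the centroid)
    sea_half = Polygon([
        (-big * uy, big * ux), (big * uy, -big * ux),
        (big * uy + big * ux, -big * ux + big * uy),
        (-big * uy + big * ux, big * ux + big * uy),
    ])
    land_half = Polygon([
        (-big * uy, big * ux), (big * uy, -big * ux),
        (big * uy - big * ux, -big * ux - big * uy),
        (-big * uy - big * ux, big * ux - big * uy),
    ])
    pieces = [local]
    if r_sea > 0:
        pieces.append(local.buffer(r_sea, quad_segs=64).intersection(sea_half))
    if r_land > 0:
        pieces.append(local.buffer(r_land, quad_segs=64).intersection(land_half))
    merged = shapely.unary_union(pieces)
    # the half-plane seams can leave hairline defects, amplified by the
    # projection round-trip; snap to a fine grid and repair
    out_geom = shapely.make_valid(
        shapely.set_precision(to_wgs(merged), 1e-9)
    )
    if out_geom.geom_type == "GeometryCollection":
        out_geom = shapely.unary_union([g for g in out_geom.geoms if g.area > 0])
    return replace(core, name=f"{core.name}_influence", geometry=out_geom)


def assign_habitat(points: pd.DataFrame, polygons) -> pd.DataFrame:
    """Label each location with the habitat of the containing polygon.

    ``points`` needs ``lat``/``lon`` columns; returns a copy with
    ``habitat_type`` and ``habitat_category`` columns. Where several
    polygons contain a point the smallest priority number wins (ties break
    on polygon name for determinism). Boundary points count as inside.
    Points in no polygon are labelled ``unclassified``.
    """
    polygons = sorted(polygons, key=lambda p: (p.priority, p.name))
    out = points.copy()
    n = len(out)
    labels = np.full(n, UNCLASSIFIED, dtype=object)
    cats = np.full(n, UNCLASSIFIED, dtype=object)
    if n and polygons:
        pts = shapely.points(out["lon"].to_numpy(float), out["lat"].to_numpy(float))
        tree = STRtree([p.geometry for p in polygons])
        # 'covered_by' (not 'within') so boundary points count as inside
        pt_i, poly_i = tree.query(pts, predicate="covered_by")
        if len(pt_i):
            best = pd.DataFrame({"pt": pt_i, "poly": poly_i}).groupby("pt")["poly"].min()
            labels[best.index.to_numpy()] = [polygons[j].habitat_type for j in best.to_numpy()]
            cats[best.index.to_numpy()] = [polygons[j].category for j in best.to_numpy()]
    out["habitat_type"] = labels
    out["habitat_category"] = cats
    n_un = int((labels == UNCLASSIFIED).sum())
    if n_un:
        logger.info("assign_habitat: %d/%d location(s) unclassified", n_un, n)
    return out


def habitat_proportions(
    labelled: pd.DataFrame,
    keep_unclassified: bool = True,
    tz_offset_h: float | None = None,
) -> pd.DataFrame:
    """Per bird x season habitat-use table.

    ``labelled`` needs ``bird_id``, ``status``, ``habitat_type``,
    ``habitat_category`` and either a ``season`` column or a ``timestamp``
    column (season then derived from local time). Returns one row per
    bird x season with per-type counts/proportions (long format) plus the
    summary ``prop_anthropogenic`` = anthropogenic / (anthropogenic +
    natural); unclassified locations are retained as their own class when
    ``keep_unclassified`` but never enter that dichotomy.
    """
    df = labelled.copy()
    if "season" not in df.columns:
        from .io import DEFAULT_TZ_OFFSET_H
        off = DEFAULT_TZ_OFFSET_H if tz_offset_h is None else tz_offset_h
        df["season"] = seasons_of(df["timestamp"], off)
    if not keep_unclassified:
        df = df[df["habitat_type"] != UNCLASSIFIED]
    rows = []
    for (bird, status, season), grp in df.groupby(["bird_id", "status", "season"], sort=True):
        total = len(grp)
        if total == 0:
            continue
        counts = grp["habitat_type"].value_counts()
        n_anth = int((grp["habitat_category"] == "anthropogenic").sum())
        n_nat = int((grp["habitat_category"] == "natural").sum())
        denom = n_anth + n_nat
        prop_anth = n_anth / denom if denom else np.nan
        for htype, cnt in counts.items():
            rows.append({
                "bird_id": bird, "status": status, "season": season,
                "habitat_type": htype, "n_locations": int(cnt),
                "proportion": cnt / total, "total": total,
                "prop_anthropogenic": prop_anth,
            })
    res = pd.DataFrame(rows)
    if not len(res):
        logger.warning("habitat_proportions: no classified locations")
    return res


def bird_season_use(labelled: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """One row per bird x season with ``prop_anthropogenic`` (model input)."""
    long = habitat_proportions(labelled, **kwargs)
    if not len(long):
        return pd.DataFrame(columns=["bird_id", "status", "season", "total", "prop_anthropogenic"])
    return (
        long.groupby(["bird_id", "status", "season"], as_index=False)
        .agg(total=("total", "first"), prop_anthropogenic=("prop_anthropogenic", "first"))
    )
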