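"""Synthetic central-place-forager GPS datasets with known ground truth.

The generator emulates the study system this package analyses: solar
GPS-GSM-tagged gulls from an urban colony and a wild island colony,
tracked for a year at battery-dependent intervals, making foraging trips
whose rate, duration, extent and habitat targets vary by colony status and
austral season, with wild birds relocating to a coastal resting site after
breeding. Movement is deliberately simple — straight out, dwell at the
target, straight back, with slight heading jitter — so that every trip,
resting interval and injected outlier is exactly known and downstream
stages can be validated against that truth. It is a test harness, not a
behavioural model of gulls.

All randomness flows from a master seed through per-bird
``numpy.random.SeedSequence`` children, so any single bird is reproducible
in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit as special_expit
from shapely.geometry import Polygon, box

from .geometry import destination_point, haversine_km
from .habitats import ANTHROPOGENIC_TYPES, HabitatPolygon, buffer_port_polygon
from .io import DEFAULT_TZ_OFFSET_H, SEASON_OF_MONTH, SEASONS, Track, season_of

logger = logging.getLogger(__name__)

#: Device recording intervals (minutes) and the battery band they imply.
INTERVAL_BATTERY_MID = {5: 94.0, 15: 82.0, 30: 62.0, 60: 38.0, 120: 15.0}

#: Seasonal recording-interval mixtures. Summer matches the reported
#: year-round fractions (most fixes come from the bright months): 38 % at
#: 5 min, 41 % at 15 min, 12 % at 30 min, 5 % hourly, rest slower. Winter
#: shifts mass toward the long intervals (weak sunlight, low charge).
DEFAULT_DUTY_CYCLE = {
    "summer": {5: 0.38, 15: 0.41, 30: 0.12, 60: 0.05, 120: 0.04},
    "autumn": {5: 0.25, 15: 0.35, 30: 0.25, 60: 0.10, 120: 0.05},
    "winter": {5: 0.10, 15: 0.25, 30: 0.35, 60: 0.20, 120: 0.10},
    "spring": {5: 0.25, 15: 0.35, 30: 0.25, 60: 0.10, 120: 0.05},
}

#: Trips per day by season (same for both colonies): the seasonal ordering
#: follows the reported trip counts (most in summer, fewest in winter).
DEFAULT_TRIP_RATE = {s: r for s, r in
                     zip(SEASONS, (1.8, 1.2, 0.45, 0.75))}

#: Mean trip duration (h) per status x season; the summer values are the
#: reported seasonal estimates (0.8 h urban, 2.7 h wild).
DEFAULT_DURATION_H = {
    ("urban", "summer"): 0.8, ("urban", "autumn"): 1.2,
    ("urban", "winter"): 1.5, ("urban", "spring"): 1.0,
    ("wild", "summer"): 2.7, ("wild", "autumn"): 3.5,
    ("wild", "winter"): 3.0, ("wild", "spring"): 2.5,
}

#: Mean trip extent (km from the current central location).
DEFAULT_EXTENT_KM = {
    ("urban", "summer"): 3.0, ("urban", "autumn"): 3.5,
    ("urban", "winter"): 2.5, ("urban", "spring"): 3.0,
    ("wild", "summer"): 6.0, ("wild", "autumn"): 9.0,
    ("wild", "winter"): 8.0, ("wild", "spring"): 7.0,
}

#: Share of trip targets in anthropogenic habitat, per status x season.
#: Urban birds always above wild ones; both rise after breeding.
DEFAULT_ANTHRO_WEIGHT = {
    ("urban", "summer"): 0.70, ("urban", "autumn"): 0.80,
    ("urban", "winter"): 0.90, ("urban", "spring"): 0.75,
    ("wild", "summer"): 0.25, ("wild", "autumn"): 0.35,
    ("wild", "winter"): 0.48, ("wild", "spring"): 0.30,
}

_ANTHRO_SPLIT = {
    "fish_market_cove_port": 0.35, "landfill": 0.30, "urban_suburban": 0.20,
    "agricultural_field": 0.10, "recreational_beach": 0.05,
}
_NATURAL_SPLIT = {
    "open_sea": 0.50, "wetland": 0.20, "sandy_beach": 0.15, "rocky_shore": 0.15,
}


def habitat_weights_for(anthro_total: float) -> dict:
    """Expand a total anthropogenic share into per-type target weights."""
    w = {t: anthro_total * s for t, s in _ANTHRO_SPLIT.items()}
    w.update({t: (1.0 - anthro_total) * s for t, s in _NATURAL_SPLIT.items()})
    return w


@dataclass
class RelocationConfig:
    """Post-breeding relocation of wild birds to a coastal resting site."""

    status: str = "wild"
    seasons: tuple = ("winter",)
    probability: float = 0.9
    site: tuple[float, float] = (-29.952, -71.384)  # coast near the urban area
    delay_days: tuple[float, float] = (2.0, 8.0)
    stay_days: tuple[float, float] = (40.0, 70.0)


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic population.

    Defaults are the study conditions: 4 urban + 4 wild birds tracked from
    3 Dec 2022 to 3 Dec 2023, ~20 m GPS noise, 1 % injected speed
    outliers, seasonal duty cycling, and status x season trip behaviour
    per the constants above.
    """

    n_birds_urban: int = 4
    n_birds_wild: int = 4
    colony_urban: tuple[float, float] = (-29.951, -71.370)
    colony_wild: tuple[float, float] = (-29.238, -71.528)
    start: str = "2022-12-03T00:00:00Z"
    end: str = "2023-12-03T00:00:00Z"
    trip_rate_per_day: dict = field(default_factory=lambda: dict(DEFAULT_TRIP_RATE))
    trip_duration_mean_h: dict = field(default_factory=lambda: dict(DEFAULT_DURATION_H))
    trip_extent_km: dict = field(default_factory=lambda: dict(DEFAULT_EXTENT_KM))
    anthro_weight: dict = field(default_factory=lambda: dict(DEFAULT_ANTHRO_WEIGHT))
    duty_cycle: dict = field(default_factory=lambda: {s: dict(m) for s, m in DEFAULT_DUTY_CYCLE.items()})
    gps_noise_m: float = 20.0
    outlier_rate: float = 0.01
    #: per-bird heterogeneity: SD of a bird-level logit offset on the
    #: anthropogenic target weight, and lognormal sigma of a bird-level
    #: trip-duration multiplier (mean 1) — the "individual identity"
    #: signal the mixed models' random intercept absorbs
    bird_anthro_sd_logit: float = 0.3
    bird_duration_sd: float = 0.12
    min_trip_duration_h: float = 0.6
    max_trip_duration_h: float = 8.0
    travel_fraction: float = 0.15
    speed_cap_kmh: float = 55.0
    relocation: RelocationConfig | None = field(default_factory=RelocationConfig)
    tz_offset_h: float = DEFAULT_TZ_OFFSET_H
    seed: int = 0

    def validate(self) -> "SimConfig":
        for season, mix in self.duty_cycle.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"duty-cycle weights for {season} sum to {total}, not 1")
        if self.gps_noise_m < 0 or self.outlier_rate < 0:
            raise ValueError("noise and outlier rate must be non-negative")
        for key, r in self.trip_rate_per_day.items():
            if (r if np.isscalar(r) else min(r)) < 0:
                raise ValueError(f"negative trip rate for {key}")
        return self

    def rate(self, status: str, season: str) -> float:
        r = self.trip_rate_per_day
        return r.get((status, season), r.get(season, 0.0))


def oracle_config(**overrides) -> SimConfig:
    """Noise-free, outlier-free configuration with dense sampling.

    This is the regime in which trip segmentation provably recovers the
    generated trips exactly: no position noise, sampling never sparser
    than 15 min, and trips at least 45 min long, so every excursion is
    observed beyond the trip threshold. Used for oracle-equivalence tests.
    """
    dense = {s: {5: 0.5, 15: 0.5} for s in SEASONS}
    cfg = SimConfig(
        gps_noise_m=0.0,
        outlier_rate=0.0,
        duty_cycle=dense,
        min_trip_duration_h=0.75,
        relocation=None,
    )
    return replace(cfg, **overrides)


def default_habitat_map() -> list[HabitatPolygon]:
    """Synthetic habitat map surrounding the two colonies.

    A rectangle-world caricature of a coastal study region: a north zone
    (island colony off a coast at 71.46 W) and a south zone (urban colony
    behind a coast at 71.40 W), each with the full set of habitat types
    within foraging range, plus port polygons carrying their dilated area
    of influence. Geometry is synthetic; only the class structure and
    priorities mirror real maps.
    """

    def hp(name, category, htype, priority, lon0, lat0, lon1, lat1):
        return HabitatPolygon(name, category, htype, priority, box(lon0, lat0, lon1, lat1))

    polys = [
        # north zone (wild colony on an island ~6 km off the coast)
        hp("sea_north", "natural", "open_sea", 9, -72.5, -29.45, -71.46, -29.0),
        hp("island_damas", "natural", "uninhabited_island", 2, -71.548, -29.258, -71.508, -29.218),
        hp("coast_north", "natural", "coastal_area", 8, -71.46, -29.45, -71.44, -29.0),
        hp("wetland_north", "natural", "wetland", 3, -71.46, -29.27, -71.42, -29.23),
        hp("rocky_north", "natural", "rocky_shore", 3, -71.47, -29.32, -71.45, -29.26),
        hp("beach_north", "natural", "sandy_beach", 3, -71.47, -29.22, -71.45, -29.16),
        hp("landfill_north", "anthropogenic", "landfill", 2, -71.43, -29.26, -71.41, -29.24),
        hp("fields_north", "anthropogenic", "agricultural_field", 4, -71.44, -29.20, -71.38, -29.12),
        hp("resort_north", "anthropogenic", "recreational_beach", 3, -71.475, -29.16, -71.455, -29.12),
        hp("village_north", "anthropogenic", "urban_suburban", 6, -71.45, -29.35, -71.41, -29.31),
        # south zone (urban colony on a rooftop in the city)
        hp("sea_south", "natural", "open_sea", 9, -72.5, -30.3, -71.40, -29.45),
        hp("coast_south", "natural", "coastal_area", 8, -71.40, -30.3, -71.38, -29.45),
        hp("city_south", "anthropogenic", "urban_suburban", 6, -71.38, -29.99, -71.30, -29.91),
        hp("landfill_south", "anthropogenic", "landfill", 2, -71.34, -29.97, -71.32, -29.95),
        hp("wetland_south", "natural", "wetland", 3, -71.38, -29.93, -71.35, -29.90),
        hp("beach_south", "natural", "sandy_beach", 3, -71.405, -30.00, -71.385, -29.97),
        hp("rocky_south", "natural", "rocky_shore", 3, -71.41, -30.04, -71.39, -30.00),
        hp("resort_south", "anthropogenic", "recreational_beach", 3, -71.405, -29.94, -71.385, -29.92),
        hp("fields_south", "anthropogenic", "agricultural_field", 4, -71.35, -30.05, -71.28, -29.99),
    ]
    # port cores, dilated into their area of influence (1 km offshore,
    # 200 m inland); the influence polygon is what locations are matched to
    port_n = hp("cove_north", "anthropogenic", "fish_market_cove_port", 1,
                -71.475, -29.30, -71.455, -29.28)
    port_s = hp("port_south", "anthropogenic", "fish_market_cove_port", 1,
                -71.40, -29.96, -71.385, -29.945)
    polys.append(buffer_port_polygon(port_n, seaward_bearing_deg=270.0))
    polys.append(buffer_port_polygon(port_s, seaward_bearing_deg=270.0))
    return [p.validate() for p in polys]


@dataclass
class GroundTruth:
    """Generator event log: what the pipeline should recover."""

    trips: pd.DataFrame         # bird_id, status, start, end, season, habitat_type, ...
    resting_sites: pd.DataFrame  # bird_id, lat, lon, start, end
    outliers: pd.DataFrame      # bird_id, timestamp

    @staticmethod
    def concat(parts: list["GroundTruth"]) -> "GroundTruth":
        def cat(frames):
            frames = [f for f in frames if len(f)]
            return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        return GroundTruth(
            cat([p.trips for p in parts]),
            cat([p.resting_sites for p in parts]),
            cat([p.outliers for p in parts]),
        )


def _epoch_s(ts) -> float:
    t = pd.Timestamp(ts)
    if t.tzinfo is None:
        t = t.tz_localize("UTC")
    return t.value / 1e9


def _season_at_s(t_s: float, tz_offset_h: float) -> str:
    return season_of(pd.Timestamp(int(t_s * 1e9), tz="UTC"), tz_offset_h)


def _season_boundaries_s(start_s: float, end_s: float, tz_offset_h: float) -> np.ndarray:
    """Epoch seconds of local month-starts of Dec/Mar/Jun/Sep in the span."""
    t0 = pd.Timestamp(int(start_s * 1e9), tz="UTC") + pd.Timedelta(hours=tz_offset_h)
    t1 = pd.Timestamp(int(end_s * 1e9), tz="UTC") + pd.Timedelta(hours=tz_offset_h)
    months = pd.date_range(t0.normalize().replace(day=1), t1, freq="MS")
    starts = [m for m in months if m.month in (12, 3, 6, 9)]
    out = np.array(
        [(m - pd.Timedelta(hours=tz_offset_h)).value / 1e9 for m in starts], dtype=float
    )
    return out[(out > start_s) & (out < end_s)]


def sample_instants(
    start_s: float,
    end_s: float,
    duty_cycle: dict,
    tz_offset_h: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Strictly increasing sampling instants over [start_s, end_s].

    Each step is drawn from the recording-interval mixture of the season
    the device is currently in.
    """
    bounds = list(_season_boundaries_s(start_s, end_s, tz_offset_h)) + [end_s]
    out = [start_s]
    t = start_s
    for b in bounds:
        season = _season_at_s(t, tz_offset_h)
        mix = duty_cycle[season]
        intervals = np.array(sorted(mix), dtype=float)
        weights = np.array([mix[i] for i in sorted(mix)], dtype=float)
        total = weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"duty-cycle weights for {season} sum to {total}")
        weights = weights / total
        mean_step = float(np.dot(intervals, weights)) * 60.0
        while t < b:
            n = max(16, int((b - t) / mean_step * 1.15) + 8)
            steps = rng.choice(intervals, size=n, p=weights) * 60.0
            cum = t + np.cumsum(steps)
            inside = cum[cum <= b]
            out.extend(inside.tolist())
            if len(inside) < len(cum):
                start_of_next = float(inside[-1]) if len(inside) else t
                if start_of_next < b:
                    # a step that *starts* before the boundary may cross it
                    # (the device only re-evaluates its charge at fix times)
                    nxt = float(cum[len(inside)])
                    if nxt <= end_s:
                        out.append(nxt)
                    t = nxt
                else:
                    t = start_of_next  # steps from here use the new season
                break
            t = float(cum[-1]) if len(cum) else b
    return np.array(sorted(set(out)), dtype=float)


def simulate_duty_cycle(
    config: SimConfig, season: str, n_hours: float, rng: np.random.Generator
) -> np.ndarray:
    """Sampling instants (seconds from 0) for ``n_hours`` under one season's
    recording-interval mixture; instants run from 0 to n_hours inclusive."""
    if n_hours <= 0:
        raise ValueError("n_hours must be positive")
    mix = config.duty_cycle[season]
    intervals = np.array(sorted(mix), dtype=float)
    weights = np.array([mix[i] for i in sorted(mix)], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"duty-cycle weights for {season} sum to {weights.sum()}")
    horizon = n_hours * 3600.0
    out = [0.0]
    t = 0.0
    while t < horizon:
        n = max(16, int((horizon - t) / (np.dot(intervals, weights) * 60.0)) + 8)
        steps = rng.choice(intervals, size=n, p=weights) * 60.0
        cum = t + np.cumsum(steps)
        keep = cum[cum <= horizon]
        out.extend(keep.tolist())
        t = float(cum[-1])
    return np.array(out, dtype=float)


class _TargetIndex:
    """Target points per habitat type: ring sampling at the requested
    extent, with an area-scaled candidate cloud as fallback."""

    def __init__(self, habitat_map: list[HabitatPolygon], rng: np.random.Generator):
        import shapely

        self.by_type: dict[str, np.ndarray] = {}
        self.union_by_type: dict[str, object] = {}
        groups: dict[str, list[np.ndarray]] = {}
        geoms: dict[str, list] = {}
        for poly in habitat_map:
            # ~one candidate per 8 km^2 so even the open-sea rectangles are
            # densely covered, never fewer than 48 per polygon
            area_km2 = poly.geometry.area * (111.32 ** 2) * abs(
                np.cos(np.radians(poly.geometry.centroid.y))
            )
            n = int(np.clip(area_km2 / 8.0, 48, 1500))
            pts = self._sample_in(poly.geometry, n, rng)
            groups.setdefault(poly.habitat_type, []).append(pts)
            geoms.setdefault(poly.habitat_type, []).append(poly.geometry)
        for htype, parts in groups.items():
            self.by_type[htype] = np.vstack(parts)
            self.union_by_type[htype] = shapely.unary_union(geoms[htype])

    @staticmethod
    def _sample_in(geom, n: int, rng: np.random.Generator) -> np.ndarray:
        from shapely.geometry import Point
        minx, miny, maxx, maxy = geom.bounds
        pts = []
        tries = 0
        while len(pts) < n and tries < 200 * n:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            tries += 1
            if geom.covers(Point(x, y)):
                pts.append((y, x))  # (lat, lon)
        return np.array(pts, dtype=float)

    def pick(self, htype: str, central: tuple[float, float], extent_km: float,
             rng: np.random.Generator) -> tuple[float, float, float]:
        """Target (lat, lon, dist_km) of type ``htype``, as close to the
        requested extent from ``central`` as the map allows."""
        from shapely.geometry import Point

        # first try points on the ring at the requested extent
        union = self.union_by_type[htype]
        for spread in (0.08, 0.2, 0.4):
            brg = rng.uniform(0.0, 360.0, 24)
            rad = extent_km * rng.uniform(1.0 - spread, 1.0 + spread, 24)
            for b, r in zip(brg, rad):
                lat, lon = destination_point(central[0], central[1], float(b), float(r))
                if union.covers(Point(lon, lat)):
                    return lat, lon, float(r)
        # fall back to the candidate nearest the requested extent
        cands = self.by_type[htype]
        d = haversine_km(cands[:, 0], cands[:, 1], central[0], central[1])
        order = np.argsort(np.abs(d - extent_km))
        k = order[: min(5, len(order))]
        j = int(rng.choice(k))
        return float(cands[j, 0]), float(cands[j, 1]), float(d[j])


def _residency_blocks(cfg: SimConfig, status: str, start_s: float, end_s: float,
                      rng: np.random.Generator):
    """(start, end, kind, lat, lon) residency blocks for one bird."""
    colony = cfg.colony_urban if status == "urban" else cfg.colony_wild
    blocks = []
    reloc = cfg.relocation
    if (
        reloc is not None
        and status == reloc.status
        and rng.random() < reloc.probability
    ):
        # relocate at the start of the first configured season in the span
        bounds = _season_boundaries_s(start_s, end_s, cfg.tz_offset_h)
        entry = None
        for b in bounds:
            if _season_at_s(b + 60.0, cfg.tz_offset_h) in reloc.seasons:
                entry = b
                break
        if entry is not None:
            delay = rng.uniform(*reloc.delay_days) * 86400.0
            stay = rng.uniform(*reloc.stay_days) * 86400.0
            s0 = min(entry + delay, end_s)
            s1 = min(s0 + stay, end_s)
            if s1 - s0 > 86400.0:
                blocks = [
                    (start_s, s0, "colony", *colony),
                    (s0, s1, "resting_site", *reloc.site),
                    (s1, end_s, "colony", *colony),
                ]
    if not blocks:
        blocks = [(start_s, end_s, "colony", *colony)]
    return [b for b in blocks if b[1] > b[0]]


def simulate_bird(
    config: SimConfig,
    bird_id: str,
    status: str,
    rng: np.random.Generator,
    habitat_map: list[HabitatPolygon] | None = None,
    targets: _TargetIndex | None = None,
) -> tuple[Track, GroundTruth]:
    """Simulate one bird's year: residency, trips, duty-cycled sampling,
    GPS noise and injected speed outliers. Returns the observed Track and
    the exact event log (GroundTruth)."""
    cfg = config.validate()
    if habitat_map is None:
        habitat_map = default_habitat_map()
    if targets is None:
        targets = _TargetIndex(habitat_map, np.random.default_rng(12345))
    start_s, end_s = _epoch_s(cfg.start), _epoch_s(cfg.end)
    if end_s - start_s < 86400.0:
        raise ValueError("simulation period must be at least one day")
    blocks = _residency_blocks(cfg, status, start_s, end_s, rng)

    way_t: list[float] = [start_s]
    way_lat: list[float] = [blocks[0][3]]
    way_lon: list[float] = [blocks[0][4]]
    trip_rows = []
    site_rows = []

    # bird-level heterogeneity (what the random intercept models)
    bird_logit_off = rng.normal(0.0, cfg.bird_anthro_sd_logit) if cfg.bird_anthro_sd_logit > 0 else 0.0
    if cfg.bird_duration_sd > 0:
        bird_dur_mult = float(np.exp(rng.normal(-0.5 * cfg.bird_duration_sd ** 2, cfg.bird_duration_sd)))
    else:
        bird_dur_mult = 1.0

    transit_speed = 45.0  # km/h, colony <-> resting-site relocations
    prev_pos = (blocks[0][3], blocks[0][4])
    for (b0, b1, kind, clat, clon) in blocks:
        # travel to the block's central if the bird is elsewhere
        t_ready = b0
        if haversine_km(prev_pos[0], prev_pos[1], clat, clon) > 0.05:
            tt = haversine_km(prev_pos[0], prev_pos[1], clat, clon) / transit_speed * 3600.0
            t_ready = min(b0 + tt, b1)
            way_t.extend([b0, t_ready])
            way_lat.extend([prev_pos[0], clat])
            way_lon.extend([prev_pos[1], clon])
        if kind == "resting_site":
            site_rows.append({
                "bird_id": bird_id, "lat": clat, "lon": clon,
                "start": pd.Timestamp(int(b0 * 1e9), tz="UTC"),
                "end": pd.Timestamp(int(b1 * 1e9), tz="UTC"),
            })
        t = t_ready + (43200.0 if kind == "resting_site" else 0.0)  # settle in
        while True:
            season = _season_at_s(t, cfg.tz_offset_h)
            rate = cfg.rate(status, season)
            if rate <= 0:
                # no trips this season: jump to the next season boundary
                nxt = [b for b in _season_boundaries_s(t, b1, cfg.tz_offset_h)]
                if not nxt:
                    break
                t = float(nxt[0]) + 60.0
                continue
            gap = rng.exponential(24.0 / rate) * 3600.0 + 0.6 * 3600.0
            ts = t + gap
            if ts >= b1 - 3600.0:
                break
            season = _season_at_s(ts, cfg.tz_offset_h)
            mean_d = cfg.trip_duration_mean_h[(status, season)] * bird_dur_mult
            lo = cfg.min_trip_duration_h
            for _ in range(100):
                d = lo + rng.gamma(2.0, max(mean_d - lo, 0.05) / 2.0)
                if d <= cfg.max_trip_duration_h:
                    break
            d_s = d * 3600.0
            if ts + d_s >= b1 - 600.0:
                break
            mean_e = cfg.trip_extent_km[(status, season)]
            e_req = max(1.2, rng.gamma(4.0, mean_e / 4.0))
            a_cell = cfg.anthro_weight[(status, season)]
            a_bird = float(special_expit(np.log(a_cell / (1 - a_cell)) + bird_logit_off))
            weights = habitat_weights_for(a_bird)
            types = sorted(weights)
            probs = np.array([weights[h] for h in types])
            probs = probs / probs.sum()
            htype = str(rng.choice(types, p=probs))
            tlat, tlon, e = targets.pick(htype, (clat, clon), e_req, rng)
            # speed chosen so travel takes ~travel_fraction of the trip
            v = float(np.clip(2.0 * e / max(cfg.travel_fraction * d, 1e-6), 10.0, cfg.speed_cap_kmh))
            tt_s = e / v * 3600.0
            if 2.0 * tt_s > 0.5 * d_s:
                # target farther than this trip can cover at the speed cap:
                # stretch the trip so dwell still dominates (keeps the
                # habitat ground truth exact; rare under the defaults)
                d_s = 2.0 * tt_s / 0.5
                d = d_s / 3600.0
                if ts + d_s >= b1 - 600.0:
                    break
            # slight heading jitter via a perpendicular mid-point offset
            off = rng.normal(0.0, 0.06) * e
            mlat, mlon = (clat + tlat) / 2.0, (clon + tlon) / 2.0
            dx, dy = tlon - clon, tlat - clat
            norm = float(np.hypot(dx, dy)) or 1.0
            mlat += -dx / norm * (off / 111.32)
            mlon += dy / norm * (off / 111.32)
            way_t.extend([ts, ts + 0.5 * tt_s, ts + tt_s, ts + d_s - tt_s, ts + d_s])
            way_lat.extend([clat, mlat, tlat, tlat, clat])
            way_lon.extend([clon, mlon, tlon, tlon, clon])
            trip_rows.append({
                "bird_id": bird_id, "status": status,
                "start": pd.Timestamp(int(ts * 1e9), tz="UTC"),
                "end": pd.Timestamp(int((ts + d_s) * 1e9), tz="UTC"),
                "season": season, "habitat_type": htype,
                "habitat_category": "anthropogenic" if htype in ANTHROPOGENIC_TYPES else "natural",
                "central_kind": kind, "central_lat": clat, "central_lon": clon,
                "target_lat": tlat, "target_lon": tlon,
                "extent_km": e, "duration_h": d, "travel_h": tt_s / 3600.0,
            })
            t = ts + d_s
        prev_pos = (clat, clon)
    way_t.append(end_s)
    way_lat.append(prev_pos[0])
    way_lon.append(prev_pos[1])

    # observe the continuous path at duty-cycled instants
    inst = sample_instants(start_s, end_s, cfg.duty_cycle, cfg.tz_offset_h, rng)
    wt = np.array(way_t)
    order = np.argsort(wt, kind="stable")
    wt = wt[order]
    wlat = np.array(way_lat)[order]
    wlon = np.array(way_lon)[order]
    lat = np.interp(inst, wt, wlat)
    lon = np.interp(inst, wt, wlon)

    if cfg.gps_noise_m > 0:
        m_per_deg = 111_320.0
        lat = lat + rng.normal(0.0, cfg.gps_noise_m, len(lat)) / m_per_deg
        lon = lon + rng.normal(0.0, cfg.gps_noise_m, len(lon)) / (
            m_per_deg * np.cos(np.radians(lat))
        )

    outlier_rows = []
    if cfg.outlier_rate > 0 and len(inst) > 2:
        raw = np.flatnonzero(rng.random(len(inst)) < cfg.outlier_rate)
        chosen = []
        for i in raw:
            if 0 < i < len(inst) - 1 and (not chosen or i - chosen[-1] > 1):
                chosen.append(int(i))
        for i in chosen:
            dt_max_h = max(inst[i] - inst[i - 1], inst[i + 1] - inst[i]) / 3600.0
            d_out = 151.0 * dt_max_h + 5.0  # guarantees > 70 km/h on both sides
            brg = rng.uniform(0.0, 360.0)
            lat[i], lon[i] = destination_point(lat[i], lon[i], brg, d_out)
            outlier_rows.append({
                "bird_id": bird_id,
                "timestamp": pd.Timestamp(int(inst[i] * 1e9), tz="UTC"),
            })

    # battery charge consistent with the interval that produced each fix
    steps_min = np.diff(inst) / 60.0
    batt = np.empty(len(inst))
    batt[1:] = [
        INTERVAL_BATTERY_MID.get(int(round(s)), 15.0) for s in steps_min
    ]
    batt[0] = batt[1] if len(batt) > 1 else 90.0
    batt = np.clip(batt + rng.uniform(-5, 5, len(batt)), 1.0, 100.0)

    fixes = pd.DataFrame({
        "timestamp": pd.to_datetime((inst * 1e9).astype("int64"), utc=True),
        "lat": lat,
        "lon": lon,
        "battery_pct": np.round(batt, 1),
        "flag": "ok",
    })
    track = Track(bird_id, status, fixes)
    truth = GroundTruth(
        trips=pd.DataFrame(trip_rows),
        resting_sites=pd.DataFrame(site_rows),
        outliers=pd.DataFrame(outlier_rows),
    )
    return track, truth


def simulate_population(
    config: SimConfig | None = None,
    habitat_map: list[HabitatPolygon] | None = None,
) -> tuple[list[Track], GroundTruth, pd.DataFrame]:
    """Simulate the whole population from a master seed.

    Returns (tracks, ground truth, truth table). The truth table has one
    row per status x season with the configured behaviour (trip rate,
    mean duration/extent, anthropogenic target weight) next to the
    realised ground-truth means, for parameter-recovery tests.
    """
    cfg = (config or SimConfig()).validate()
    if cfg.n_birds_urban + cfg.n_birds_wild < 2:
        raise ValueError("need at least two birds")
    if habitat_map is None:
        habitat_map = default_habitat_map()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_birds_urban + cfg.n_birds_wild + 1)
    targets = _TargetIndex(habitat_map, np.random.default_rng(children[-1]))
    tracks, truths = [], []
    plan = [("urban", i) for i in range(cfg.n_birds_urban)] + [
        ("wild", i) for i in range(cfg.n_birds_wild)
    ]
    for (status, i), child in zip(plan, children):
        bird_id = f"{status[0].upper()}{i + 1}"
        rng = np.random.default_rng(child)
        tr, gt = simulate_bird(cfg, bird_id, status, rng, habitat_map, targets)
        tracks.append(tr)
        truths.append(gt)
    truth = GroundTruth.concat(truths)

    rows = []
    for status in ("urban", "wild"):
        for season in SEASONS:
            sub = truth.trips
            sub = sub[(sub["status"] == status) & (sub["season"] == season)] if len(sub) else sub
            rows.append({
                "status": status, "season": season,
                "trip_rate_per_day": cfg.rate(status, season),
                "duration_mean_h": cfg.trip_duration_mean_h[(status, season)],
                "extent_mean_km": cfg.trip_extent_km[(status, season)],
                "anthro_weight": cfg.anthro_weight[(status, season)],
                "n_trips_true": int(len(sub)),
                "duration_mean_true": float(sub["duration_h"].mean()) if len(sub) else np.nan,
                "extent_mean_true": float(sub["extent_km"].mean()) if len(sub) else np.nan,
                "anthro_target_share_true": float(
                    (sub["habitat_category"] == "anthropogenic").mean()
                ) if len(sub) else np.nan,
            })
    return tracks, truth, pd.DataFrame(rows)


def expected_bird_season_use(
    truth_trips: pd.DataFrame,
    habitat_map: list[HabitatPolygon],
    interval_min: float = 15.0,
    tz_offset_h: float = DEFAULT_TZ_OFFSET_H,
) -> pd.DataFrame:
    """Generator-side expected habitat-use shares, from the event log alone.

    Reconstructs each ground-truth trip's 15-min grid positions directly
    from its logged geometry (central, target, travel time) — without
    touching the segmentation or interpolation stages — classifies them
    against the habitat map, and aggregates to per status x season
    anthropogenic shares. Serves as the independent oracle the pipeline's
    habitat-use output is compared against.
    """
    from .habitats import assign_habitat, bird_season_use

    pts = []
    step_h = interval_min / 60.0
    for row in truth_trips.itertuples():
        d, tt = float(row.duration_h), float(row.travel_h)
        n = int(np.floor(d / step_h)) + 1
        u = np.arange(n) * step_h
        lat = np.full(n, row.target_lat, dtype=float)
        lon = np.full(n, row.target_lon, dtype=float)
        out = u < tt
        back = u > d - tt
        with np.errstate(invalid="ignore"):
            f_out = np.where(tt > 0, u / max(tt, 1e-9), 1.0)
            f_back = np.where(tt > 0, (d - u) / max(tt, 1e-9), 1.0)
        lat[out] = row.central_lat + (row.target_lat - row.central_lat) * f_out[out]
        lon[out] = row.central_lon + (row.target_lon - row.central_lon) * f_out[out]
        lat[back] = row.central_lat + (row.target_lat - row.central_lat) * f_back[back]
        lon[back] = row.central_lon + (row.target_lon - row.central_lon) * f_back[back]
        pts.append(pd.DataFrame({
            "bird_id": row.bird_id, "status": row.status, "season": row.season,
            "lat": lat, "lon": lon,
        }))
    if not pts:
        return pd.DataFrame(columns=["status", "season", "prop_anthropogenic"])
    labelled = assign_habitat(pd.concat(pts, ignore_index=True), habitat_map)
    per_bird = bird_season_use(labelled)
    return (
        per_bird.groupby(["status", "season"], as_index=False)
        .agg(prop_anthropogenic=("prop_anthropogenic", "mean"))
    )
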