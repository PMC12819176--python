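"""Track cleaning and central-place trip segmentation.

A *trip* is an excursion at least 300 m from the bird's current central
location that keeps it away for more than 30 min. The central location is
the colony during breeding; outside breeding it may temporarily become a
*resting site* — a cluster of fixes where the bird overnighted or stayed
more than 24 h. Before segmentation, fixes implying travel faster than
70 km/h are removed as device errors (gulls do not sustain such speeds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import haversine_km
from .io import DEFAULT_TZ_OFFSET_H, Track, season_of

logger = logging.getLogger(__name__)

DEFAULT_TRIP_DIST_M = 300.0
DEFAULT_MIN_AWAY_MIN = 30.0
DEFAULT_MAX_SPEED_KMH = 70.0


@dataclass
class CentralLocation:
    """Colony or resting site acting as trip reference over [start, end]."""

    kind: str  # 'colony' | 'resting_site'
    lat: float
    lon: float
    start: pd.Timestamp
    end: pd.Timestamp
    bird_id: str = ""


@dataclass
class Trip:
    """A contiguous excursion from the central location.

    ``departure``/``return_time`` are the bounding fixes: the last fix
    still within the distance threshold before leaving and the first fix
    back within it (duration is measured between them). ``fixes`` includes
    those two anchor fixes. Incomplete trips (track or central interval
    ended while the bird was away) carry ``complete=False`` and are
    excluded from metrics by default.
    """

    bird_id: str
    status: str | None
    central: CentralLocation
    departure: pd.Timestamp
    return_time: pd.Timestamp
    fixes: pd.DataFrame
    season: str
    complete: bool = True
    trip_id: str = ""

    @property
    def duration_h(self) -> float:
        return (self.return_time - self.departure).total_seconds() / 3600.0


def _segment_speeds_kmh(fixes: pd.DataFrame) -> np.ndarray:
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    lat = fixes["lat"].to_numpy(float)
    lon = fixes["lon"].to_numpy(float)
    d = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt_h = np.diff(t) / 3600.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt_h > 0, d / dt_h, np.inf)


def _violations(t_s: np.ndarray, lat: np.ndarray, lon: np.ndarray, vmax: float) -> np.ndarray:
    """Boolean per-segment mask of speed violations."""
    d = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt_h = np.diff(t_s) / 3600.0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt_h > 0, d / dt_h, np.inf)
    return v > vmax


def filter_speed_outliers(
    track: Track, max_speed_kmh: float = DEFAULT_MAX_SPEED_KMH
) -> tuple[Track, pd.DataFrame]:
    """Remove fixes implying impossible travel speeds.

    While any consecutive-fix segment exceeds ``max_speed_kmh``, the fix
    whose removal most reduces the number of violating segments is dropped
    (ties drop the later fix). Returns the cleaned track and the removed
    fixes (flagged ``speed_outlier``). Tracks with < 2 fixes pass through.
    """
    if len(track) < 2:
        return track, track.fixes.iloc[0:0].copy()
    f = track.fixes
    t_s = f["timestamp"].astype("int64").to_numpy() / 1e9
    lat = f["lat"].to_numpy(float)
    lon = f["lon"].to_numpy(float)
    idx = np.arange(len(f))
    removed: list[int] = []

    def seg_viol(i: np.ndarray) -> np.ndarray:
        return _violations(t_s[i], lat[i], lon[i], max_speed_kmh)

    viol = seg_viol(idx)
    while viol.any():
        vpos = np.flatnonzero(viol)
        cand = np.unique(np.concatenate([vpos, vpos + 1]))
        # removing fix p only turns segments (p-1,p) and (p,p+1) into one
        # segment (p-1,p+1), so each candidate's gain is local
        last = len(idx) - 1
        old = np.zeros(len(cand), dtype=int)
        new = np.zeros(len(cand), dtype=int)
        inner = (cand > 0) & (cand < last)
        old[cand == 0] = viol[0]
        old[cand == last] = viol[last - 1]
        ci = cand[inner]
        old[inner] = viol[ci - 1].astype(int) + viol[ci].astype(int)
        if ci.size:
            a, b = idx[ci - 1], idx[ci + 1]
            d = haversine_km(lat[a], lon[a], lat[b], lon[b])
            dt_h = (t_s[b] - t_s[a]) / 3600.0
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(dt_h > 0, d / dt_h, np.inf)
            new[inner] = (v > max_speed_kmh).astype(int)
        gain = old - new
        # best gain; ties drop the later fix
        best = np.flatnonzero(gain == gain.max())[-1]
        p = int(cand[best])
        removed.append(int(idx[p]))
        idx = np.delete(idx, p)
        if len(idx) < 2:
            viol = np.zeros(0, dtype=bool)
            break
        viol = np.delete(viol, min(p, len(viol) - 1))
        if 0 < p < len(idx):
            a, b = idx[p - 1], idx[p]
            d = float(haversine_km(lat[a], lon[a], lat[b], lon[b]))
            dt_h = (t_s[b] - t_s[a]) / 3600.0
            viol[p - 1] = (d / dt_h > max_speed_kmh) if dt_h > 0 else True
    alive = np.ones(len(f), dtype=bool)
    alive[removed] = False
    removed_df = f.iloc[sorted(removed)].copy()
    removed_df["flag"] = "speed_outlier"
    clean = f.iloc[np.flatnonzero(alive)].reset_index(drop=True)
    if removed:
        logger.info(
            "filter_speed_outliers: %s removed %d fix(es)", track.bird_id, len(removed)
        )
    return replace(track, fixes=clean), removed_df


def _covers_full_night(
    start: pd.Timestamp,
    end: pd.Timestamp,
    tz_offset_h: float,
    night_start_h: int = 22,
    night_end_h: int = 5,
) -> bool:
    """True if [start, end] contains a complete local 22:00-05:00 night."""
    s = start + pd.Timedelta(hours=tz_offset_h)
    e = end + pd.Timedelta(hours=tz_offset_h)
    day = s.normalize() - pd.Timedelta(days=1)
    while day <= e.normalize():
        n0 = day + pd.Timedelta(hours=night_start_h)
        n1 = day + pd.Timedelta(days=1, hours=night_end_h)
        if s <= n0 and e >= n1:
            return True
        day += pd.Timedelta(days=1)
    return False


def detect_resting_sites(
    track: Track,
    colony: tuple[float, float],
    cluster_radius_m: float = 300.0,
    min_stay_h: float = 24.0,
    night_window: tuple[int, int] = (22, 5),
    min_colony_separation_km: float = 1.0,
    tz_offset_h: float = DEFAULT_TZ_OFFSET_H,
    merge_gap_h: float = 36.0,
) -> list[CentralLocation]:
    """Find resting sites: clusters where the bird overnighted or stayed >24 h.

    Sequential spatio-temporal clustering: consecutive fixes each within
    ``cluster_radius_m`` of the running centroid form a candidate; a
    candidate becomes a resting site if it spans a full local night window
    or lasts longer than ``min_stay_h``. Candidates near the colony
    (< ``min_colony_separation_km``) are absorbed into the colony.
    Promoted candidates at the same place separated by less than
    ``merge_gap_h`` (e.g. nights split by daytime trips) merge into one
    site whose interval spans them all.
    """
    f = track.fixes
    if not len(f):
        return []
    lat = f["lat"].to_numpy(float)
    lon = f["lon"].to_numpy(float)
    ts = f["timestamp"]
    radius_km = cluster_radius_m / 1000.0

    candidates: list[tuple[int, int, float, float]] = []  # (i0, i1, clat, clon)
    i0 = 0
    clat, clon, n = lat[0], lon[0], 1
    for i in range(1, len(f)):
        if haversine_km(lat[i], lon[i], clat, clon) <= radius_km:
            n += 1
            clat += (lat[i] - clat) / n
            clon += (lon[i] - clon) / n
        else:
            candidates.append((i0, i - 1, clat, clon))
            i0, clat, clon, n = i, lat[i], lon[i], 1
    candidates.append((i0, len(f) - 1, clat, clon))

    promoted = []
    for i0, i1, clat, clon in candidates:
        if haversine_km(clat, clon, colony[0], colony[1]) < min_colony_separation_km:
            continue  # colony itself remains the central there
        start, end = ts.iloc[i0], ts.iloc[i1]
        dur_h = (end - start).total_seconds() / 3600.0
        if dur_h > min_stay_h or _covers_full_night(
            start, end, tz_offset_h, night_window[0], night_window[1]
        ):
            promoted.append(CentralLocation("resting_site", clat, clon, start, end, track.bird_id))

    merged: list[CentralLocation] = []
    for site in promoted:
        if merged:
            prev = merged[-1]
            gap_h = (site.start - prev.end).total_seconds() / 3600.0
            if (
                haversine_km(prev.lat, prev.lon, site.lat, site.lon) <= radius_km
                and gap_h < merge_gap_h
            ):
                merged[-1] = replace(prev, end=site.end)
                continue
        merged.append(site)
    return merged


def build_central_timeline(
    track: Track, colony: tuple[float, float], sites: list[CentralLocation]
) -> list[CentralLocation]:
    """Partition the track span into central-location intervals.

    The timeline starts at the colony, switches to each resting site over
    that site's active interval and back to the colony (or the next site)
    afterwards. Resting-site intervals must not overlap.
    """
    f = track.fixes
    if not len(f):
        return []
    t0, t1 = track.start, track.end
    sites = sorted(sites, key=lambda s: s.start)
    for a, b in zip(sites, sites[1:]):
        if b.start < a.end:
            raise ValueError("overlapping resting-site intervals")
    timeline: list[CentralLocation] = []
    cursor = t0
    for s in sites:
        if s.start > cursor:
            timeline.append(CentralLocation("colony", colony[0], colony[1], cursor, s.start, track.bird_id))
        timeline.append(replace(s, start=max(s.start, cursor)))
        cursor = s.end
    if cursor < t1 or not timeline:
        timeline.append(CentralLocation("colony", colony[0], colony[1], cursor, t1, track.bird_id))
    return timeline


def segment_trips(
    track: Track,
    timeline: list[CentralLocation],
    dist_m: float = DEFAULT_TRIP_DIST_M,
    min_away_min: float = DEFAULT_MIN_AWAY_MIN,
    tz_offset_h: float = DEFAULT_TZ_OFFSET_H,
    keep_incomplete: bool = True,
) -> list[Trip]:
    """Cut a (speed-filtered) track into trips from its central locations.

    Within each central interval, a trip opens at the last fix within
    ``dist_m`` of the central before a run of fixes all beyond it, and
    closes at the first fix back within ``dist_m``. If the run is cut by
    the end of the interval (central switch or track end) the trip is
    flagged incomplete. Trips are kept when the time between the bounding
    fixes exceeds ``min_away_min``. Season comes from the departure time
    in local time.
    """
    f = track.fixes
    trips: list[Trip] = []
    if not len(f):
        return trips
    if not timeline:
        raise ValueError("empty central timeline")
    tl = sorted(timeline, key=lambda c: c.start)
    if tl[0].start > track.start or tl[-1].end < track.end:
        raise ValueError("central timeline does not cover track span")
    for prev, nxt in zip(tl, tl[1:]):
        if nxt.start > prev.end:
            raise ValueError("gap in central timeline")

    ts = f["timestamp"]
    lat = f["lat"].to_numpy(float)
    lon = f["lon"].to_numpy(float)
    thresh_km = dist_m / 1000.0
    counter = 0
    for central in tl:
        # fixes falling in this central interval (inclusive start, exclusive
        # end except for the final interval, so each fix belongs once)
        last = central is tl[-1]
        if last:
            mask = (ts >= central.start) & (ts <= central.end)
        else:
            mask = (ts >= central.start) & (ts < central.end)
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) < 2:
            continue
        dist = haversine_km(lat[idx], lon[idx], central.lat, central.lon)
        away = dist > thresh_km
        j = 0
        n = len(idx)
        while j < n:
            if not away[j]:
                j += 1
                continue
            # run of away fixes [j, k)
            k = j
            while k < n and away[k]:
                k += 1
            open_i = j - 1 if j > 0 else j          # anchor: last inside fix
            complete = k < n
            close_i = k if complete else n - 1      # anchor: first fix back inside
            dep = ts.iloc[idx[open_i]]
            ret = ts.iloc[idx[close_i]]
            away_min = (ret - dep).total_seconds() / 60.0
            if away_min > min_away_min and (complete or keep_incomplete):
                counter += 1
                sub = f.iloc[idx[open_i]: idx[close_i] + 1].reset_index(drop=True)
                trips.append(
                    Trip(
                        bird_id=track.bird_id,
                        status=track.status,
                        central=central,
                        departure=dep,
                        return_time=ret,
                        fixes=sub,
                        season=season_of(dep, tz_offset_h),
                        complete=bool(complete and j > 0),
                        trip_id=f"{track.bird_id}_{counter:04d}",
                    )
                )
            j = k
    trips.sort(key=lambda tr: tr.departure)
    for i, tr in enumerate(trips, 1):
        tr.trip_id = f"{track.bird_id}_{i:04d}"
    return trips


def trips_table(trips: list[Trip]) -> pd.DataFrame:
    """Flat summary table of trips (one row each), mirroring trips.csv."""
    return pd.DataFrame(
        [
            {
                "trip_id": t.trip_id,
                "bird_id": t.bird_id,
                "status": t.status,
                "central_kind": t.central.kind,
                "departure": t.departure,
                "return": t.return_time,
                "duration_h": t.duration_h,
                "n_fixes": len(t.fixes),
                "season": t.season,
                "complete": t.complete,
            }
            for t in trips
        ]
    )
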