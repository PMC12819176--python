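"""Geometry, speed filtering, resting sites, central timeline and trips."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cpforage as cf
from cpforage.geometry import EARTH_RADIUS_KM, destination_point
from cpforage.segmentation import CentralLocation

COLONY = (-29.951, -71.370)


class TestHaversine:
    def test_identity(self):
        assert cf.haversine_km(-29.9, -71.3, -29.9, -71.3) == 0.0

    def test_meridian_and_equator_closed_form(self):
        per_degree = 2 * np.pi * EARTH_RADIUS_KM / 360.0
        assert abs(cf.haversine_km(0, 0, 0, 1) - per_degree) < 1e-3
        assert abs(cf.haversine_km(0, 0, 1, 0) - per_degree) < 1e-3
        assert abs(cf.haversine_km(10, 5, 15, 5) - 5 * per_degree) < 1e-3

    @given(
        st.floats(-80, 80), st.floats(-179, 179),
        st.floats(-80, 80), st.floats(-179, 179),
    )
    def test_symmetry_and_nonnegativity(self, lat1, lon1, lat2, lon2):
        d1 = cf.haversine_km(lat1, lon1, lat2, lon2)
        d2 = cf.haversine_km(lat2, lon2, lat1, lon1)
        assert d1 >= 0
        assert abs(d1 - d2) < 1e-9

    def test_destination_point_roundtrip(self):
        lat2, lon2 = destination_point(-29.9, -71.3, 37.0, 12.5)
        assert abs(cf.haversine_km(-29.9, -71.3, lat2, lon2) - 12.5) < 1e-6


def _track_at_speed(track_factory, n=6, step_min=10, lat0=-29.9, dlat=0.01):
    """n fixes moving north at ~6.7 km/h (well under any speed limit)."""
    times = pd.date_range("2023-01-01", periods=n, freq=f"{step_min}min", tz="UTC")
    lats = lat0 + dlat * np.arange(n) * 0.1
    return track_factory("A", times, lats, [-71.3] * n)


def _brute_force_minimal_removal(track, vmax=70.0):
    """Smallest fix subset whose removal clears all speed violations."""
    f = track.fixes
    t = f["timestamp"].astype("int64").to_numpy() / 1e9
    lat, lon = f["lat"].to_numpy(), f["lon"].to_numpy()

    def ok(keep):
        idx = [i for i in range(len(f)) if i in keep]
        for a, b in zip(idx, idx[1:]):
            d = cf.haversine_km(lat[a], lon[a], lat[b], lon[b])
            if d / ((t[b] - t[a]) / 3600.0) > vmax:
                return False
        return True

    everything = set(range(len(f)))
    for k in range(len(f) + 1):
        for drop in itertools.combinations(range(len(f)), k):
            if ok(everything - set(drop)):
                return set(drop)
    raise AssertionError("unreachable")


class TestSpeedFilter:
    def test_clean_track_unchanged(self, track_factory):
        tr = _track_at_speed(track_factory)
        out, removed = cf.filter_speed_outliers(tr)
        assert len(removed) == 0
        pd.testing.assert_frame_equal(out.fixes, tr.fixes)

    def test_single_displaced_fix_matches_brute_force(self, track_factory):
        times = pd.date_range("2023-01-01", periods=5, freq="10min", tz="UTC")
        lats = [-29.90, -29.90, -28.50, -29.90, -29.90]  # 3rd fix ~155 km away
        tr = track_factory("A", times, lats, [-71.3] * 5)
        out, removed = cf.filter_speed_outliers(tr)
        assert set(removed.index) == {2}
        assert _brute_force_minimal_removal(tr) == {2}
        assert (removed["flag"] == "speed_outlier").all()

    def test_two_adjacent_displaced_fixes_both_removed(self, track_factory):
        times = pd.date_range("2023-01-01", periods=6, freq="10min", tz="UTC")
        lats = [-29.90, -29.90, -28.50, -27.00, -29.90, -29.90]
        tr = track_factory("A", times, lats, [-71.3] * 6)
        out, removed = cf.filter_speed_outliers(tr)
        assert set(removed.index) == {2, 3}
        assert _brute_force_minimal_removal(tr) == {2, 3}

    def test_tiny_track_passes_through(self, track_factory):
        tr = track_factory("A", ["2023-01-01T00:00Z"], [-29.9], [-71.3])
        out, removed = cf.filter_speed_outliers(tr)
        assert len(out) == 1 and len(removed) == 0

    def test_no_removals_on_noise_free_cruise(self, oracle_population):
        _, tracks, _, _ = oracle_population
        for tr in tracks[:2]:
            _, removed = cf.filter_speed_outliers(tr)
            assert len(removed) == 0


def _stationary(times):
    return [COLONY[0]] * len(times), [COLONY[1]] * len(times)


class TestRestingSites:
    def test_bird_always_at_colony_yields_no_sites(self, track_factory):
        times = pd.date_range("2023-06-01", periods=200, freq="1h", tz="UTC")
        tr = track_factory("A", times, *_stationary(times))
        assert cf.detect_resting_sites(tr, COLONY) == []

    def test_multi_night_stay_found_with_right_interval(self, track_factory):
        cove = destination_point(*COLONY, 90.0, 40.0)  # 40 km east
        times = pd.date_range("2023-06-01", periods=24 * 5, freq="1h", tz="UTC")
        lats, lons = [], []
        for t in times:
            at_cove = pd.Timestamp("2023-06-02", tz="UTC") <= t < pd.Timestamp("2023-06-05", tz="UTC")
            lats.append(cove[0] if at_cove else COLONY[0])
            lons.append(cove[1] if at_cove else COLONY[1])
        tr = track_factory("A", times, lats, lons)
        sites = cf.detect_resting_sites(tr, COLONY)
        assert len(sites) == 1
        site = sites[0]
        assert cf.haversine_km(site.lat, site.lon, *cove) < 0.3
        assert site.start <= pd.Timestamp("2023-06-02T01:00Z")
        assert site.end >= pd.Timestamp("2023-06-04T22:00Z")

    def test_daytime_loaf_is_not_a_site(self, track_factory):
        spot = destination_point(*COLONY, 90.0, 10.0)
        # away 10:00-16:00 local (14:00-20:00 UTC): no night, < 24 h
        times = pd.date_range("2023-06-01", periods=48, freq="1h", tz="UTC")
        lats, lons = [], []
        for t in times:
            away = 14 <= t.hour < 20 and t.day == 1
            lats.append(spot[0] if away else COLONY[0])
            lons.append(spot[1] if away else COLONY[1])
        tr = track_factory("A", times, lats, lons)
        assert cf.detect_resting_sites(tr, COLONY) == []


class TestCentralTimeline:
    def _site(self, bird, start, end, km_east=40.0):
        lat, lon = destination_point(*COLONY, 90.0, km_east)
        return CentralLocation("resting_site", lat, lon,
                               pd.Timestamp(start, tz="UTC"), pd.Timestamp(end, tz="UTC"), bird)

    def test_no_sites_single_colony_interval(self, track_factory):
        times = pd.date_range("2023-01-01", periods=10, freq="1h", tz="UTC")
        tr = track_factory("A", times, *_stationary(times))
        tl = cf.build_central_timeline(tr, COLONY, [])
        assert len(tl) == 1
        assert tl[0].kind == "colony"
        assert tl[0].start == tr.start and tl[0].end == tr.end

    def test_mid_track_site_gives_three_intervals(self, track_factory):
        times = pd.date_range("2023-06-01", periods=240, freq="1h", tz="UTC")
        tr = track_factory("A", times, *_stationary(times))
        site = self._site("A", "2023-06-03", "2023-06-06")
        tl = cf.build_central_timeline(tr, COLONY, [site])
        assert [c.kind for c in tl] == ["colony", "resting_site", "colony"]
        # intervals partition the track span
        assert tl[0].start == tr.start and tl[-1].end == tr.end
        for a, b in zip(tl, tl[1:]):
            assert a.end == b.start

    def test_back_to_back_sites_leave_no_colony_between(self, track_factory):
        times = pd.date_range("2023-06-01", periods=400, freq="1h", tz="UTC")
        tr = track_factory("A", times, *_stationary(times))
        s1 = self._site("A", "2023-06-03", "2023-06-06")
        s2 = self._site("A", "2023-06-06", "2023-06-09", km_east=60.0)
        tl = cf.build_central_timeline(tr, COLONY, [s1, s2])
        assert [c.kind for c in tl] == ["colony", "resting_site", "resting_site", "colony"]

    def test_overlapping_sites_rejected(self, track_factory):
        times = pd.date_range("2023-06-01", periods=300, freq="1h", tz="UTC")
        tr = track_factory("A", times, *_stationary(times))
        s1 = self._site("A", "2023-06-03", "2023-06-06")
        s2 = self._site("A", "2023-06-05", "2023-06-08")
        with pytest.raises(ValueError, match="overlap"):
            cf.build_central_timeline(tr, COLONY, [s1, s2])


class TestSegmentTrips:
    def _timeline(self, tr):
        return cf.build_central_timeline(tr, COLONY, [])

    def test_all_fixes_near_colony_no_trips(self, track_factory):
        times = pd.date_range("2023-01-01", periods=20, freq="15min", tz="UTC")
        tr = track_factory("A", times, *_stationary(times))
        assert cf.segment_trips(tr, self._timeline(tr)) == []

    def test_45_min_excursion_is_one_trip_with_anchor_boundaries(self, track_factory):
        away = destination_point(*COLONY, 90.0, 2.0)
        times = pd.date_range("2023-01-01", periods=12, freq="15min", tz="UTC")
        # fixes 0-3 at colony, 4-7 away (45 min span), 8-11 back
        lats = [COLONY[0]] * 4 + [away[0]] * 4 + [COLONY[0]] * 4
        lons = [COLONY[1]] * 4 + [away[1]] * 4 + [COLONY[1]] * 4
        tr = track_factory("A", times, lats, lons)
        trips = cf.segment_trips(tr, self._timeline(tr))
        assert len(trips) == 1
        t = trips[0]
        assert t.departure == times[3]       # last fix inside before leaving
        assert t.return_time == times[8]     # first fix back inside
        assert t.complete
        assert len(t.fixes) == 6
        assert t.season == "summer"

    def test_20_min_excursion_rejected(self, track_factory):
        away = destination_point(*COLONY, 90.0, 2.0)
        times = pd.date_range("2023-01-01", periods=10, freq="10min", tz="UTC")
        lats = [COLONY[0]] * 4 + [away[0]] * 2 + [COLONY[0]] * 4
        lons = [COLONY[1]] * 4 + [away[1]] * 2 + [COLONY[1]] * 4
        tr = track_factory("A", times, lats, lons)
        # away anchors span fixes 3..6 = 30 min, not more
        assert cf.segment_trips(tr, self._timeline(tr)) == []

    def test_track_ending_away_yields_incomplete_trip(self, track_factory):
        away = destination_point(*COLONY, 90.0, 2.0)
        times = pd.date_range("2023-01-01", periods=8, freq="15min", tz="UTC")
        lats = [COLONY[0]] * 4 + [away[0]] * 4
        lons = [COLONY[1]] * 4 + [away[1]] * 4
        tr = track_factory("A", times, lats, lons)
        trips = cf.segment_trips(tr, self._timeline(tr))
        assert len(trips) == 1 and not trips[0].complete
        assert cf.segment_trips(tr, self._timeline(tr), keep_incomplete=False) == []

    def test_timeline_gap_is_fatal(self, track_factory):
        times = pd.date_range("2023-01-01", periods=10, freq="1h", tz="UTC")
        tr = track_factory("A", times, *_stationary(times))
        broken = [
            CentralLocation("colony", *COLONY, tr.start, times[3], "A"),
            CentralLocation("colony", *COLONY, times[5], tr.end, "A"),
        ]
        with pytest.raises(ValueError, match="gap|cover"):
            cf.segment_trips(tr, broken)

    def test_trip_invariants_on_simulated_data(self, oracle_trips):
        for trips in oracle_trips.values():
            for t in trips:
                if not t.complete:
                    continue
                assert t.duration_h * 60.0 > 30.0
                d = cf.haversine_km(
                    t.fixes["lat"].to_numpy(), t.fixes["lon"].to_numpy(),
                    t.central.lat, t.central.lon,
                )
                assert d.max() > 0.3
                assert t.fixes["timestamp"].is_monotonic_increasing
                assert t.departure == t.fixes["timestamp"].iloc[0]
                assert t.return_time == t.fixes["timestamp"].iloc[-1]

    def test_segmentation_is_idempotent_on_trip_boundaries(self, oracle_population):
        cfg, tracks, _, _ = oracle_population
        tr = tracks[0]
        colony = cfg.colony_urban
        tl = cf.build_central_timeline(tr, colony, [])
        first = cf.segment_trips(tr, tl)
        again = cf.segment_trips(tr, cf.build_central_timeline(tr, colony, []))
        assert [(t.departure, t.return_time) for t in first] == [
            (t.departure, t.return_time) for t in again
        ]
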