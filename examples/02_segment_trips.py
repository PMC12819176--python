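"""Clean a track and cut it into central-place foraging trips.

The speed filter removes fixes implying > 70 km/h travel; resting sites
(overnight or > 24 h clusters away from the colony) become temporary
central locations; a trip is an excursion > 300 m from the active central
lasting > 30 min.
"""

import cpforage as cf

cfg = cf.SimConfig(n_birds_urban=1, n_birds_wild=1,
                   start="2023-05-20T00:00:00Z", end="2023-08-20T00:00:00Z",
                   seed=7)
tracks, truth, _ = cf.simulate_population(cfg)

for tr in tracks:
    colony = cfg.colony_urban if tr.status == "urban" else cfg.colony_wild
    clean, removed = cf.filter_speed_outliers(tr)
    sites = cf.detect_resting_sites(clean, colony)
    timeline = cf.build_central_timeline(clean, colony, sites)
    trips = cf.segment_trips(clean, timeline)
    print(f"\n{tr.bird_id} ({tr.status}): {len(removed)} speed outliers removed, "
          f"{len(sites)} resting site(s), {len(trips)} trips")
    for s in sites:
        print(f"  resting site at ({s.lat:.3f}, {s.lon:.3f}) "
              f"active {s.start:%b %d} - {s.end:%b %d}")
    print(cf.trips_table(trips).head(5).to_string(index=False))
# wild birds typically relocate to a coastal resting site after breeding
# (winter); their trips then start from that site, not the colony.
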