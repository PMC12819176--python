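# cpforage

Central-place foraging analysis for GPS-tracked seabirds: trip
segmentation, habitat use and seasonal urban-vs-wild comparison.

`cpforage` is written for movement ecologists working with solar
GPS-GSM tracking of colony-based birds — here, kelp gulls (*Larus
dominicanus*) from an urban rooftop colony and a wild island colony in
northern Chile — who need a reproducible path from raw Movebank-style fix
tables to per-trip movement metrics, habitat-use proportions and mixed
models, without the manual GIS and visual-inspection steps such analyses
traditionally involve. A synthetic track generator with exact ground
truth makes every stage testable at desk scale.

## The method

**Trips.** A foraging *trip* is an excursion at least 300 m from the
bird's *central location* lasting more than 30 min. The central location
is the colony; outside the breeding season it may temporarily become a
*resting site* — a cluster of fixes where the bird overnighted (local
22:00–05:00) or stayed > 24 h. Fixes implying travel above 70 km/h are
removed first (device errors; gulls do not sustain such speeds). Trip
boundaries are anchored at the last fix within 300 m before departure and
the first fix back within 300 m.

**Habitat use.** Because solar tags record at battery-dependent intervals
(5/15/30/60/120 min), trip locations are linearly interpolated to a
common 15-min grid — only for trips < 24 h without gaps ≥ 60 min
(≥ 90 min tolerated for urban birds in winter). Each grid location is
assigned the habitat polygon containing it (integer priority resolves
overlaps, e.g. a port's 1-km offshore / 200-m inland buffered area of
influence over the open sea), and per bird × season

> prop. anthropogenic = n(anthropogenic) / (n(anthropogenic) + n(natural)).

**Movement metrics.** Per complete trip: duration (h) between the anchor
fixes; maximum distance (km) as the farthest great-circle distance from
the *colony* (even for trips from a resting site); path length (km)
summed over consecutive fixes.

**Models.** With bird *i*, status *s* (urban/wild), season *t*:

- habitat use: `y_ist ~ Beta(μ_ist φ, (1-μ_ist) φ)`,
  `logit(μ_ist) = β₀ + status_s + season_t + (status:season)_st + b_i`
- trip metrics: `y ~ Gamma(k, μ/k)` with `log μ` given the same linear
  predictor,

with `b_i ~ N(0, σ_b²)` a per-bird random intercept, sum-to-zero factor
coding, maximum likelihood via a Laplace approximation (cross-checked
against glmmTMB to ~5 decimals). Inference: type-III Wald χ² per term
(df 1/3/3 for status/season/interaction), estimated marginal means with
back-transformed intervals, single-step (Tukey) adjusted pairwise
contrasts, and a likelihood-ratio test against the null
(intercept + random intercept) model. Intervals use t quantiles with
between-cluster degrees of freedom (n_birds − 2); α = 0.05.

## Worked example

`examples/` holds one short script per capability. The one-call pipeline
(`examples/06_full_pipeline.py`) simulates half a study year for 2 urban
and 2 wild birds and runs every stage:

```
$ python examples/06_full_pipeline.py
{
 "n_birds": 4,
 "n_fixes_read": 46624,
 "n_locations_interpolated": 1763,
 "n_locations_original": 6051,
 "n_speed_outliers_removed": 488,
 "n_trips": 821,
 "n_trips_complete": 821,
 "n_trips_interpolated": 255,
 "trips_per_season": {
  "autumn": 341,
  "summer": 478,
  "winter": 2
 }
}

mean proportion anthropogenic per cell:
  urban:autumn: 0.842 (n=2)
  urban:summer: 0.869 (n=2)
  wild:autumn: 0.187 (n=2)
  wild:summer: 0.095 (n=2)
```

46,624 raw fixes yield 821 trips (mostly in summer, when solar charge
keeps sampling dense); 488 injected speed outliers are removed — exactly
the injected set; the 6,051 original trip locations become 1,763
15-min-grid locations over the 255 interpolation-eligible trips. Urban
birds spend 84–87 % of trip locations in anthropogenic habitats versus
10–19 % for wild birds — the central contrast the mixed models then test
(see `examples/05_mixed_models.py` for a full-year run with the beta and
gamma GLMM tables). Stage CSVs, `models.json` and a provenance-stamped
`report.json` land in the output directory; the same run is available
from the shell as `cpforage simulate --out DIR --seed 1`.

Real data enter through `cpforage run --fixes fixes.csv --polygons
habitats.geojson --statuses statuses.csv --colony-urban LAT,LON
--colony-wild LAT,LON` with Movebank-dialect CSV and a GeoJSON
FeatureCollection of habitat polygons (properties: `name`, `category`,
`habitat_type`, `priority`).

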