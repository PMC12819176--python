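# Methods

This note documents the models and procedures implemented in
`cpforage`, the parameters that matter, the numerical choices behind
them, and what the synthetic-data tests do and do not demonstrate.

## Trip segmentation

A track is first cleaned by the **speed filter**: while any
consecutive-fix segment implies travel above `max_speed_kmh`
(default 70 km/h), the fix whose removal most reduces the number of
violating segments is dropped, ties dropping the later fix. Because
removing a fix only merges its two adjacent segments, the gain is
evaluated locally, making the filter O(n + k·c) for k removals. On
synthetic data with injected single-fix displacements the filter removes
exactly the injected set; the automated filter replaces the visual
inspection step traditional in this kind of analysis, trading judgement
for reproducibility.

**Central locations.** The colony is the default central location.
Resting sites are found by sequential spatio-temporal clustering: a run
of consecutive fixes each within `cluster_radius_m` (300 m) of the
running centroid is promoted to a site when it spans a complete local
night window (22:00–05:00) or exceeds `min_stay_h` (24 h); candidates
within `min_colony_separation_km` (1 km) of the colony are absorbed into
it, and promoted runs at the same place separated by less than 36 h
(nights split by daytime trips) merge. The clustering radius, night
window and merge gap are judgement calls exposed as parameters; the
radius deliberately equals the trip threshold so "at the site" and "on a
trip from the site" are complementary. The central-location timeline
partitions the track span: colony intervals alternate with site
intervals, switching at each site's first and last fix.

**Trips.** Within each central interval, a trip opens at the last fix
within `dist_m` (300 m) of the active central before a run of fixes all
beyond it, and closes at the first fix back within `dist_m`; it is kept
when the time between those two anchor fixes exceeds `min_away_min`
(30 min, strict). Anchoring to observed fixes makes boundaries
deterministic under irregular sampling; duration is measured between the
anchors, so each boundary can sit up to one sampling interval away from
the true departure/return. A trip cut by the end of its central interval
(track end, or a central-location switch) is emitted with
`complete=False` and excluded from metrics and interpolation. Austral
season (summer = Dec–Feb through spring = Sep–Nov) is assigned from the
departure time in local time, modelled as a fixed UTC−4 offset —
daylight saving is ignored because all rules are month- or night-level
and a fixed offset keeps results reproducible; the offset is a parameter
everywhere it matters.

## Interpolation

Eligible trips (duration < 24 h; largest gap < 60 min, or < 90 min for
urban birds in winter; both comparisons strict) are resampled to a grid
`t_k = departure + k·15 min` for `t_k ≤ return`, so an eligible trip
yields exactly `floor(duration_min/15) + 1` points. Latitude and
longitude are interpolated linearly and independently in time; at trip
scales (< 100 km) the chord-versus-great-circle discrepancy is metres,
far below tag precision (~20 m). The grid is anchored at the trip's own
departure rather than the clock, keeping trips self-contained.

## Habitat classification and use

Habitat polygons carry `category` (natural / anthropogenic),
`habitat_type` (six natural, five anthropogenic classes) and an integer
`priority`; classification assigns each location the covering polygon
with the smallest priority, boundary points counting as inside. Default
priority ordering puts buffered ports before landfills and other
specific types before urban/suburban sprawl before the open sea, because
port buffers by construction overlap sea and city. Port polygons are
dilated into their area of influence — 1 km on the seaward half, 200 m
on the landward half, split by the line through the centroid
perpendicular to a supplied seaward bearing — in a local equirectangular
projection (scale error < 0.1 % at 10 km) and returned to WGS84.

Habitat-use proportions are count-based: per bird × season, the number
of interpolated trip locations per habitat type over the group total.
Locations covered by no polygon are retained as `unclassified` but
excluded from the anthropogenic/natural dichotomy, whose denominator is
the classified total. Colony-resident fixes do not enter habitat use;
only trip locations do.

## Movement metrics

Duration (h), maximum distance from the colony (km; always the colony,
even for trips from a resting site, so post-breeding relocations appear
as large distances) and path length (km; great-circle sum over
consecutive fixes, sphere radius 6371.0088 km). Metrics use the original
speed-filtered fixes, not the interpolated ones: interpolation smooths
the path and would deflate its length. GPS noise (~20 m) is not
corrected; it is negligible at km scales.

## Mixed models

Both families use fixed effects status + season + status:season under
sum-to-zero coding and a per-bird random intercept `b_i ~ N(0, σ_b²)`:
beta with logit link (precision φ, a single scalar) for the
anthropogenic-use proportion (one row per bird × season), gamma with log
link (shape k) for the three trip metrics (one row per trip).
Proportions of exactly 0 or 1 are first compressed,
`y' = (y(N−1) + ½)/N`, since the beta support is open.

Estimation maximises the Laplace-approximated marginal likelihood: the
scalar random intercepts are profiled out by a vectorised per-group
Newton inner loop, and BFGS handles the outer parameters
(β, log σ_b, log dispersion), with a Nelder–Mead polish if BFGS reports
non-convergence. The covariance of the estimates is the inverse of a
central-difference Hessian of the negative marginal log-likelihood
(relative step 10⁻⁴). On shared fixtures the fits agree with glmmTMB
(beta, mixed) to about 5 decimals in coefficients, σ_b, φ and
log-likelihood, and with statsmodels' gamma GLM (fixed effects, σ_b = 0)
to optimizer precision; implementations using adaptive quadrature may
differ in the third decimal. A design missing any status × season cell
is rank-deficient under the interaction coding and is rejected rather
than silently pseudo-inverted.

Inference follows the conventions of the R mixed-model stack this
emulates: type-III Wald χ² per term (status 1 df, season 3, interaction
3; with sum-to-zero coding in a balanced design each block is adjusted
for the others), estimated marginal means at equal factor weights with
intervals formed on the link scale and back-transformed, single-step
max-|z| adjusted pairwise contrasts (the multivariate-normal rectangle
probability is evaluated by fixed-seed Monte Carlo on the possibly
singular correlation matrix, 10⁵ draws, so results are deterministic),
and a likelihood-ratio test against the intercept-plus-random-intercept
null. One deliberate small-sample choice: coefficient and EMM intervals
use t quantiles with between-cluster degrees of freedom
(n_birds − 2 = 6 for the 8-bird design) instead of normal quantiles —
the sampling distribution of the Wald statistic for the between-bird
status effect at 8 clusters is close to t₆, and normal quantiles
undercover by several points there. Wald χ² statistics remain
asymptotic (χ² = z² at 1 df). With strong bird heterogeneity
(σ_b ≳ 0.5 on the logit scale at 8 birds) even these intervals
undercover somewhat, because the ML variance-component estimate is
itself noisy; that is a property of maximum-likelihood mixed models at
few clusters, shared by the reference implementations, and is the main
caveat on the small-sample inference.

## The synthetic generator

The generator emulates the study conditions: 4 urban + 4 wild birds, one
year from 3 Dec 2022, Gaussian position noise of 20 m, 1 % injected
speed outliers, and battery-dependent sampling with seasonal mixtures —
summer {5 min: 38 %, 15: 41 %, 30: 12 %, 60: 5 %, 120: 4 %}, winter
shifted toward the long intervals, equinox seasons in between. Trip
rates per day (1.8/1.2/0.45/0.75 across summer/autumn/winter/spring)
reproduce the reported seasonal ordering of trip counts; mean durations
(urban 0.8 h and wild 2.7 h in summer, rising off-season) and extents
(urban ~3 km, wild 6–9 km) encode the urban-shorter/closer contrast as
configuration, not hard-coded behaviour; anthropogenic target weights
(urban 0.70–0.90, wild 0.25–0.48, both rising post-breeding) do the same
for habitat use. Wild birds relocate with probability 0.9 to a coastal
resting site near the urban area for 40–70 days at the start of winter.
Per-bird heterogeneity — a logit offset (SD 0.3) on the anthropogenic
weight and a lognormal multiplier (σ 0.12) on trip duration — supplies
the individual-identity signal the random intercepts absorb. Movement is
straight out / dwell / straight back with slight heading jitter and
speeds capped at 55 km/h, so genuine movement never trips the 70 km/h
filter and every trip, resting interval and outlier is exactly logged.
Randomness descends from a master seed through per-bird `SeedSequence`
children, so single birds are reproducible in isolation. Injected
outliers are displaced far enough that both adjacent segments exceed
70 km/h at the local sampling interval, and are never adjacent to one
another — matching the single-displaced-fix error mode of real tags.

The synthetic habitat map is a rectangle-world caricature — two coastal
zones, each with the full set of habitat classes within foraging range
of its colony — labelled synthetic throughout; only the class structure,
priorities and buffered ports mirror real maps.

**What the oracle tests show.** Exact trip recovery (100 % precision and
recall, boundaries within one sampling interval) is verified under the
generator's *oracle configuration*: zero noise, zero outliers, sampling
never sparser than 15 min, trips ≥ 45 min. That is the regime where
exact recovery is a theorem; under the realistic seasonal duty cycle a
sub-hour trip can fall entirely inside a 60–120-min gap, and two trips
separated by a short colony visit that no fix lands in merge into one —
so detected trip counts run ~10–20 % below truth and detected durations
slightly above, most strongly in winter. Passing the oracle test
therefore validates the segmentation logic, not the claim that sparse
real-world sampling loses nothing. Similarly, measured habitat-use
proportions differ from the configured *target* weights by construction
(anchor fixes sit at the central location; travel legs cross other
habitats), so quantitative recovery is checked against a generator-side
reconstruction of expected grid positions from the event log, and the
urban > wild contrast is checked directly. The generator does not
attempt behavioural realism (no energetics, no weather, no
individual-level movement modes); conclusions about real gulls rest on
the real data, not on these simulations.

## Validation problem sizes

The test suite runs the oracle-equivalence check on 8 birds × 90 days
(~1,100 trips), speed-filter exactness on a 3-month noisy population
(~500 injected outliers), parameter-recovery for both GLMM families over
200 replicates of the 8-bird design, and null calibration (type-III
interaction type-I error, Tukey family-wise error) over 400 replicates
at 50 trips per cell — sizes chosen so the whole suite completes in a
few minutes on one CPU while keeping Monte-Carlo error on coverage and
error rates near one percentage point.

## Known limitations

- Resting-site detection assumes the tag keeps recording at the site; a
  bird roosting in a GPS shadow would be missed.
- The 300 m / 30 min trip definition, clustering radius and night window
  are operational conventions; results at other thresholds require
  re-running with those parameters.
- Beta precision φ is a single scalar (no dispersion covariates), and
  the models carry no temporal autocorrelation structure; trips of the
  same bird on the same day are treated as conditionally independent.
- Small-sample Wald inference at 8 clusters is approximate even with
  t-based intervals (see above); profile-likelihood or bootstrap
  intervals would be the next step if the interval itself were the
  scientific product.
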