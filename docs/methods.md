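# Methods

`stormcross` implements a track–cyclone interaction analysis for shorebirds
crossing the western Atlantic during the tropical-cyclone season: it measures
how much of each migratory journey is spent inside the basin's area of
highest storm occurrence, detects bird × storm encounters, classifies the
behavioural response, and tests whether encounter likelihood differs between
breeding populations. This note records the models, the operational choices
behind them, and what the synthetic test bed does and does not establish.

## Data model and filters

Telemetry is an ARGOS-style fix table (bird, UTC timestamp, lat/lon, location
class). Only classes 1–3 (positional error < 1 km) enter the analysis;
classes 0/A/B/Z are parsed but dropped. Duplicate (bird, timestamp) rows keep
the best class, ties keep the first row. No positional smoothing is applied.

Cyclones come from HURDAT2 best tracks (modern comma-delimited dialect; the
pre-2013 fixed-width dialect is rejected with an explicit error). The
climatology uses storms active between 15 July and 30 November (month–day
comparison within each year, so leap years need no special handling) in
1961–2018, restricted to tropical statuses TD/TS/HU. Subtropical statuses
(SD/SS) are excluded by default because the intensity taxonomy used for
encounters enumerates only depression-and-above tropical systems; a flag
re-admits them. Only standard synoptic records (00/06/12/18 UTC) are kept, so
each retained record carries equal lifespan weight: a storm contributes
points in proportion to how long it lived.

## Geometry

All distances and bearings are spherical great-circle quantities on the IUGG
mean radius (6371.0088 km); positions are manipulated as Earth-centred unit
vectors, which makes longitude wrap-around a non-issue. "Straight line" is
read everywhere as the great-circle segment, consistent with the use of
great-circle distances for path lengths.

Fixes arrive on transmitter duty cycles (24 h off / 5 h on or 48 h off /
10 h on), so boundary crossings almost never coincide with a fix. Crossing
instants are interpolated at a fixed mean flight speed of **14.8 m/s** (the
cohort-mean ground speed between in-flight fixes):

* region entry: `t = t_outside_fix + d(outside fix → boundary) / v`;
* region exit: `t = t_last_inside_fix + d(last inside fix → boundary) / v`;
* coast departure: `t = t_first_overwater_fix − d(coast → fix) / v`;
* coast arrival: `t = t_last_overwater_fix + d(fix → coast) / v`.

The coast rules interpolate from the in-flight fix rather than the (possibly
long-stationary) fix on land, because a bird can sit at a staging site for
days after its last land fix; the region rules measure forward from the last
outside fix. A `proportional` mode (linear in time across the fix gap) is
available as a config switch. If `d / v` overshoots the bracketing fix gap
the crossing time is clamped to the far fix with a warning.

## Migration segmentation

Stationarity is operationalised as: a maximal run of fixes that all stay
within **50 km** of the run's running centroid for at least **7 days**. The
radius comfortably exceeds class-1 ARGOS error (~1 km) and separates staging
stopovers (days–weeks) from territories (weeks–months); both numbers are
config. The first stationary phase is the breeding territory, the last the
winter territory. Departure is the last fix inside the breeding radius
before a displacement beyond twice the radius with no return within the
dwell window; a return within the window is logged as a false start and the
search resumes after it. Because duty cycles allow up to ~2 days between
fixes, a detected departure is accurate only to one duty-cycle gap.

The trans-oceanic leg is the longest run of over-water fixes flanked by the
two continental landmasses; its bounds come from the coast-crossing rules
above, its length is the over-water great-circle path plus the two coast
stubs, and the departure latitude is the latitude of the northern coast
crossing. Coastlines are an interface (any polygon geometry), not a bundled
dataset: tests use rectangular toy continents.

Rate of advance is total migration distance (fix-to-fix path between
departure and arrival) divided by duration in days.

## Cyclone climatology and exposure

Storm records are projected with a spherical Lambert azimuthal equal-area
projection centred at 25° N, 60° W before density estimation; fitting in an
equal-area plane keeps a single bandwidth meaningful in kilometres across
the basin's 40° latitude span. The density is a bivariate Gaussian KDE
evaluated by binning points on a square grid (default 25 km cells) and
convolving with the kernel via FFT; the grid is renormalised to unit mass.

Bandwidth selectors: `plugin` (default) is the bivariate normal-scale rule
H = n^(−1/3) Σ̂; `scv` minimises the smoothed cross-validation criterion for
H = h²Σ̂ with a normal-scale pilot — it is O(n²) in the point count, so
inputs beyond 2,500 points are thinned deterministically first; `fixed`
accepts a user bandwidth (tests pin this for determinism).

The x% risk region is the highest-density region: the threshold is the exact
cell-mass quantile (largest density t whose superlevel set holds ≥ x of the
mass) and the outline is traced with marching squares, assembled into
polygons with holes, and inverse-projected to lon/lat. HDRs are nested by
construction. On a standard bivariate normal the recovered 50% region
reproduces the closed-form disc (radius 1.1774 σ) to within the smoothing
inflation of the bandwidth, which the tests bound at a few percent.

Exposure is the summed time between interpolated entry and exit instants
across every excursion of a journey into the region; stationary intervals
inside the region count in full. The published procedure describes a single
entry and exit; summing multiple intervals is the natural generalisation.
Segments that dip into the region entirely between two outside fixes are
invisible at fix resolution and are not counted — a known limitation shared
with any fix-level overlay.

## Encounters

No spatial threshold for "tracks intersected during the same time period" is
stated in the source analysis, so the threshold is explicit config: an
in-flight encounter occurs when bird and storm centre, interpolated onto a
shared 30-minute grid, come within **300 km** (a typical gale-force
wind-field extent); one encounter is recorded per maximal below-threshold
interval, at minimum separation. A bird grounded at a stationary phase
records an encounter when a storm centre passes within **100 km** of the
phase centroid. Both radii are first-class configuration, and encounter
counts are monotone in the radius, so a sensitivity sweep is a loop over
configs. Encounters spanning a fix gap longer than 72 h are flagged low
confidence.

Storm intensity at the encounter instant interpolates best-track wind
linearly in time, converts knots to mph (× 1.15078), and applies the printed
Saffir–Simpson band edges (TD ≤ 38, TS 39–73, C1 74–95, C2 96–110, C3
111–129, C4 130–156, C5 ≥ 157 mph).

Response classification: **grounded** if a stationary interval (≥ 1 day
within 25 km) starting within 48 h of the encounter lies on an island
polygon; otherwise **detour** if the post-encounter day's bearing differs
from the pre-encounter day's bearing by more than 20° (circular difference);
otherwise **none**. Grounding supersedes detour; insufficient post-encounter
fixes yield **indeterminate**.

## Statistics

Two-sample t-tests are computed directly from group summaries (mean, SE, n),
with sd = SE·√n. The pooled-variance form is the default — the reported
degrees of freedom in the motivating comparisons equal n₁+n₂−2, which is the
pooled convention — with Welch available by flag. The implementation is
verified against raw-data reconstructions with exactly the stated moments.

The G-test of independence on 2×2 tables applies Yates' continuity
correction as "move each observed count 0.5 toward its expected value, never
past it", then G = 2 Σ O′ ln(O′/E) on 1 df. It is verified against an
independently coded brute-force oracle.

Encounter likelihood is modelled as a random-intercept logistic regression,
logit P(encounter) = x'β + u_year, u ~ N(0, σ²), fitted by maximising the
marginal likelihood with **adaptive Gauss–Hermite quadrature** (default 25
nodes, recentred on each group's posterior mode and rescaled by its
curvature). The quadrature implementation is owned by this package so it is
directly testable; an adapter to R's `lme4::glmer` provides an independent
cross-check in the test suite. Standard errors come from the observed
information (numerical Hessian). A variance estimate at the zero boundary
(σ² ≤ 1e-6) is flagged **singular** — the expected symptom of a
near-unique-level random effect such as bird identity with one or two
journeys per bird. Complete separation raises an error naming the covariate.
Candidate models (null; +population; +journey number; +both, all with the
year intercept) are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with models
within 2 ΔAICc flagged as ties and added-but-weak (|z| < 2) parameters
flagged as uninformative rather than auto-removed. Journey number is coded
categorically (1st/2nd/3rd), since an ordinal trend is not implied.

## Synthetic test bed

The generator builds the statistical structure the analysis assumes, with
exact ground truth, on a deliberately toy geography: rectangular continents
bracketing an open ocean and a five-island arc on the southern route. Two
route archetypes reproduce the field cohort parameters — a northern
population departing near 47.5° N on 5440 ± 434 km crossings lasting
6.1 ± 0.65 days far out to sea, and a southern population departing near
37.0° N on 3643 ± 651 km crossings lasting 4.5 ± 0.96 days through the
island arc (per-journey SDs are the printed SEs scaled by √n of the
respective cohorts). Infeasible draws (> 30 m/s implied flight speed) are
redrawn. Fixes are sampled on the population's duty cycle with
location-class labels from a fixed multinomial and Gaussian position noise
using each class's published error bound as the 1-σ scale.

Storms are six-hourly tracks with genesis in a box at 10–16° N, 65–52° W,
westward drift (~6 m/s) plus noise, Bernoulli recurvature to the northeast,
and a bounded random-walk wind spanning depression to hurricane strength.
The genesis box sits west of the offshore route's corridor-crossing
longitudes by design, so the resulting 50% density core lies over the island
route and only grazes the offshore route — the risk contrast the two real
routes exhibit. The motion model is deliberately minimal: it exercises
parsing, density estimation, classification and intersection; it is not
meteorologically faithful, carries no wind-field spatial structure, and its
density surface is not the published one (which depends on a specific
HURDAT2 snapshot).

Planted encounters warp a chosen storm so its centre passes at a requested
separation from the bird at a requested instant, with the positional offset
tapered to zero over ±36 h to preserve basin statistics. The separation is
defined against the bird's position as interpolated from the analysis-grade
(class 1–3) fixes — the quantity the detection stage can actually observe —
because duty-cycle gaps make the true simulated position unobservable and
the two can differ by hundreds of km across a 48-h gap on a curved route.
Plant instants snap to the storm's synoptic grid so the warp is exact there.

Consequently the test bed establishes: round-trip fidelity of the format
layer, recovery of generated departure/arrival/length/duration parameters,
exact recovery of planted encounters, the designed between-population
ordering of exposure and encounter rates, and correctness of the statistical
machinery against closed forms and oracles. It does not establish anything
about real ARGOS error structure (which is non-Gaussian and autocorrelated),
real coastline geometry, or the real basin's density surface.

## Numerical choices and limitations

* Grid cell 25 km by default; the HDR threshold is exact on the grid, so the
  achieved mass can exceed the requested mass by at most one cell's mass.
  Tests that compare against Gaussian closed forms use 10–20 km cells.
* Boundary crossings are located by densifying the great-circle segment to
  256 vertices before intersecting with polygon boundaries (sub-km error at
  fix-gap scales).
* The mixed-logit optimiser is BFGS on (β, σ) with |σ|; quadrature with 20
  vs 50 nodes changes the log-likelihood by < 1e-6 on test fixtures.
* All simulation entry points take explicit seeds; identical seeds reproduce
  byte-identical serialised outputs.
* Exposure and encounter results inherit the fix-level resolution of the
  telemetry: events shorter than a duty-cycle gap can be missed, and
  reported departure instants carry one-gap uncertainty.
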