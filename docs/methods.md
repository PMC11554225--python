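# Methods

This note documents the models, conventions and design choices behind
`effortmap`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Track preparation

**Trips and linking.** A trip is everything a vessel does between leaving
and returning to port.  Pings are linked to trips by vessel id and
temporal containment in `[depart, return]` (closed on both ends); trips of
one vessel must not overlap, and violations are fatal rather than
silently resolved.  Duplicate `(vessel, timestamp)` rows keep the first
file occurrence and are counted in the read report.

**Exclusion masking.** Pings strictly inside an exclusion polygon (e.g.
state waters) are removed; points exactly on the boundary are retained.
This is a documented, testable convention — the opposite choice would
change results only on a measure-zero set of real positions.

**Resampling.** Tracks are resampled to an exact 60 s grid anchored at
each segment's first observed timestamp.  Latitude, longitude and speed
are interpolated linearly in time; course over ground is first unwrapped
to a continuous angle so interpolation crosses the 0°/360° seam the
short way round (naive linear interpolation there invents 180° reversals
that would corrupt the course-change features).  Interpolation never
crosses a gap longer than 30 minutes (configurable): the track is split
into segments instead, because inventing positions across hours-long AIS
dropouts is worse than losing window support.  Resampling is idempotent,
and interpolated values never overshoot their observed neighbours.
Interpolation is performed on segment-relative seconds, not absolute
epoch seconds, for numerical conditioning.

## Features

Eleven candidates per ping, computed on a centred 15-minute window
(±7 grid minutes, truncated at segment edges):

| feature | units | note |
|---|---|---|
| `sog_avg`, `sog_std` | kn | sample SD (ddof = 1) |
| `crow_flies_km` | km | WGS84 geodesic, window start → end |
| `total_dist_km` | km | summed consecutive geodesics |
| `depth_avg`, `depth_std` | m, positive down | nearest-cell bathymetry sample |
| `cog_avg_abs_d` | deg | mean \|consecutive course change\| |
| `d_cog_startend` | deg in (−180, 180] | signed start → end change |
| `moon` | % | date-keyed illumination table, location-independent |
| `month`, `day_of_week` | 1–12, Mon = 0 | integer codes (trees split ordinally) |

Geodesics use a vectorised Vincenty inverse solution on the WGS84
ellipsoid (sub-millimetre agreement with Karney's algorithm at study
scale, verified against frozen reference values).  Windows with fewer
than 5 pings, or whose target ping has no depth (outside the bathymetry
raster or in a no-data cell), are flagged invalid and excluded from
training and prediction.  Course wrap handling is defined exactly by
`heading_change`: the minimal signed difference, with −180° mapped to
+180°.

Fishing labels come from observer hauls: a ping is fishing iff its
timestamp lies in the closed interval `[start, end]` of any haul of its
trip.  Whole-window labelling (marking a ping by any gear activity in the
surrounding window) is a known alternative; it is left as a config
extension point and not implemented.

## Classifier

A scikit-learn random forest stands behind the module surface: K trees on
bootstrap samples of size N, best-of-m splits (m = √p by default),
growth to a minimum leaf size, out-of-bag scoring.  Prediction is an
explicit majority vote over the fitted trees — not probability
averaging — with exact 0.5 ties classified as fishing.  The tie rule is
conservative for exposure mapping: it over-attributes value to locations
rather than losing it.

Cross-validation is **grouped by trip** everywhere (tuning, RFE):
adjacent 1-minute pings are near-duplicates, and ungrouped folds leak
them across the split, inflating scores.  Tuning maximises mean grouped-CV
AUC over a (K, depth) grid, breaking ties toward fewer trees and then
shallower depth.  Recursive feature elimination drops the least important
feature per round, records grouped-CV accuracy per subset size, and
returns the smallest subset within 0.005 of the best accuracy — a
pragmatic rule chosen because accuracy curves plateau and the smaller
model is cheaper and more interpretable.

The 5-knot speed cutoff (fishing iff SOG ≤ 5 kn, the boundary counting
as fishing) is retained as the baseline delineation rule and as the VMS
tier's classifier.  Published speed bands for other gears (otter trawl,
sink gillnet) are provided as named presets only.

## Exposure

Per-trip triage is stepwise: AIS if available, else VMS, else VTR.  Each
trip contributes through exactly one tier, which is the guard against
double counting.  An AIS-tier trip whose classifier finds zero fishing
pings is demoted to VMS and then VTR, so no landed value vanishes.

Value attribution is even by design: a trip's landed value V over n
fishing locations puts V/n at each.  Weighting by vessel density or
resource abundance was considered and rejected as introducing additional
uncertainties; even splitting is objective and auditable.

The analysis grid is metric, 500 m × 500 m, with the origin snapped to
multiples of the cell size so grids built from different extents align.
Cells are half-open `[x, x+500) × [y, y+500)`; polygon membership is by
cell centre (a centre exactly on a lease boundary counts as inside).
The projected CRS is a local equirectangular projection about the
study-area centroid — over a ~150 km study area its distortion is a
fraction of a percent, and dollar totals are unaffected because binning
partitions points rather than reweighting them.  Rasters are stored as
Esri ASCII grids (plain text, GIS-readable).

Footprint rasters must be non-negative and sum to 1 within 1e-3
(fatal otherwise); valuation renormalises so each footprint sums to its
trip's value exactly.  End-to-end, the combined raster total equals the
fleet's summed landed value to within 1e-6 relative, for any tier mix.

## Comparison analyses

**Haul rasters.** Each observed haul is a start→end segment; every cell
the segment passes through gets value 1 (supercover traversal via the
segment's grid-line crossings).

**Footprint regression.** Per trip, a no-intercept OLS of the binary
haul indicator on the footprint cell value, with the predictor rescaled
by the haul-cell count so a footprint placing its mass uniformly on
exactly the haul cells scores slope 1 and one with no mass there scores
0.  The fleet mean slope then reads as a percent-like accuracy.  The
regression's exact variable roles and scaling are a documented choice
that reproduces the limiting cases; trips with a zero-variance predictor
are skipped with a warning.

**Intrusion analysis.** For each trip present in both products, dollars
per lease are computed from the point product (point-in-polygon on the
valued pings) and the footprint product (cell-centre zonal sums of the
valued footprint).  Differences are reported footprint-minus-points; a
trip "matches" when every per-lease difference is below $0.01.  Summary
statistics over differing trips use the per-trip total in-lease
difference, with the sample (n−1) SD convention.  When both products
conserve the trip's value, in-lease differences plus the outside-region
difference cancel exactly.

**Cell-value KDE.** Gaussian KDE with Scott's bandwidth over strictly
positive cells inside a lease.  Display thresholds (e.g. masking cells
below $500) are plotting options, not part of the statistic.

## Synthetic fleet

The generator is the package's study-conditions definition, not a test
convenience.  Each trip is a two-state semi-Markov trajectory at 1-minute
resolution:

* **fishing (dredging)**: speed N(4.5, 1) kn (inside the published
  2.5–6 kn dredge band), heading random walk with 20°/min SD,
  exponential dwell (mean 30 min, each run is one haul);
* **non-fishing**: steaming runs at N(9, 1) kn, near-straight (3°/min),
  interleaved after every haul with a slow "slack" run at N(3, 1) kn
  (gear handling, haul-back, drifting; mean 8 min, 25–30% of non-fishing
  time).  The slack behaviour is what makes a plain 5-knot rule fail
  realistically: on default fleets it mislabels ≳25% of vessel-minutes,
  because slow does not imply fishing.

Hauls per trip are 1 + Poisson(8); per-haul value N($2000, $600) floored
at $100, so a typical trip lands ~$18k.  Observer coverage is a 7%
Bernoulli draw over trips; 45% of vessels carry AIS (with 2% per-ping
dropout), and 60% of the remainder carry VMS (hourly polls, first ping
per bin), yielding a tier mix close to the AIS/VMS/VTR proportions seen
in real multi-source fleet censuses.  The VTR point is the first haul's
start position (reflecting how fishers report), and its footprint is an
isotropic Gaussian (SD 5 km, truncated at 4 SD, renormalised) — a
deliberately simple stand-in for operational footprint models, which are
out of scope.  Trip start times are spread uniformly over 2015–2018;
moon illumination follows the synodic cycle; bathymetry is a smooth
synthetic surface deepening offshore.

What the generator does **not** emulate: port geography and harbour
transits, currents, AIS transponder physics and message-level noise,
multi-gear fleets, and any spatial preference of fishing grounds beyond
the random walk.  Passing tests therefore demonstrate the pipeline's
correctness and the classifier's behaviour under controlled, realistic
kinematics — not field performance on any particular real fleet.

## Problem sizes and numerics

The test suite's recovery experiment uses five independent fleets of
2,000 trips (~140 observer-covered each, matching the 7% coverage rate),
tunes hyperparameters once on the first fleet (hyperparameters are a
property of the problem, not of the seed) and retrains per seed; the
acceptance script uses a single 1,000-trip fleet.  These sizes give
stable sampling distributions for the reported statistics while keeping
a full run in the minutes range on one CPU.

Numerical conventions collected in one place: sample SDs (ddof = 1)
throughout; heading differences in (−180, 180]; cells half-open with the
southern row first; footprint sum tolerance 1e-3; value conservation
asserted at 1e-6 relative; KDE integral checked at 1e-3; intrusion match
threshold $0.01.  All randomness descends from explicit integer seeds;
train/tune/predict are bit-reproducible for a fixed seed.

## Known limitations

* The classifier is binary (fishing vs not); harbour steaming, drifting
  and other states are folded into "non-fishing".
* The local equirectangular CRS is adequate for ~100 km study areas;
  continental-scale grids would need a proper projected CRS.
* Vincenty's inverse iteration does not converge for near-antipodal
  pairs; these fall back to the spherical great-circle distance (never
  relevant at study scale).
* The Gaussian footprint is a stand-in; analyses consuming real
  footprint rasters should read them in via the ASCII-grid interface.
* Moon illumination is treated as location-independent and daily.
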