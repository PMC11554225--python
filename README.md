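# effortmap

Fishing-effort classification and ex-vessel value exposure mapping from
vessel position tracks.

## The problem

Siting offshore wind developments requires knowing where fishing happens
and how much landed revenue is tied to each patch of ocean ("exposure":
the maximum revenue at risk inside a lease area).  The available
fishery-dependent data are awkward: trip reports (VTR) give one
self-reported point per trip, regulatory vessel polls (VMS) arrive every
30–60 minutes with no catch information, and high-resolution AIS tracks
(~1 ping/minute) cover only part of the fleet.  Worse, the common
practice of calling any slow vessel "fishing" (a 5-knot cutoff for
dredge gear) fails badly, because vessels also move slowly while hauling
gear, sorting catch, or drifting.

`effortmap` implements a pipeline for analysts working on marine spatial
planning and fisheries mitigation:

1. **Classify** fishing behaviour on AIS tracks with a random forest over
   rolling-window trajectory features, trained on observer-verified hauls.
2. **Fall back** per trip to VMS (speed cutoff) and then to a per-trip
   probability **footprint** around the reported VTR point, so every trip
   is represented by its best available source and counted exactly once.
3. **Attribute** each trip's landed ex-vessel value evenly over its
   fishing locations, rasterize to a 500 m grid, and sum within lease
   polygons.
4. **Compare** products: speed-cutoff accuracy against observer truth,
   per-trip footprint regressions against haul rasters, difference
   rasters, cell-value kernel densities, and a per-trip intrusion
   analysis of in-lease dollars.

A synthetic fleet generator (`effortmap.simulate`) emulates every input —
two-state semi-Markov dredge trajectories with overlapping speed
distributions, partial observer coverage, hourly VMS polls, biased
single-point trip reports, per-trip landings — so the whole pipeline is
testable end to end without confidential data.

## The model

For pings on a 1-minute resampled track, eleven candidate features are
engineered on a centred 15-minute window: mean and SD of speed over
ground, straight-line (geodesic) and cumulative distance, mean and SD of
depth, mean absolute consecutive course change, signed start-to-end
course change, moon illumination, month, and day of week.

The classifier is a standard random forest: for *k* = 1…K, draw a
bootstrap sample of size *N* from the training set and grow tree *T_k*,
at each node splitting on the best of *m* randomly chosen features until
the minimum node size; predict by majority vote over {*Ĉ_k(x)*}, with
ties resolved toward *fishing*.  Generalisation error is estimated
out-of-bag; hyperparameters (K, depth) are tuned by cross-validated AUC
with folds **grouped by trip** so near-duplicate adjacent pings never
straddle a fold boundary, and features may be pruned by recursive feature
elimination.

Value attribution is deliberately simple and conservative: a trip with
landed value *V* and *n* fishing locations puts *V/n* dollars at each;
a VTR-tier trip puts *V·p_c* in cell *c* of its normalised probability
footprint.  Totals are conserved to machine precision through triage,
rasterization and raster addition.

## Worked example

`examples/02_classify_fishing.py` trains the forest on a synthetic fleet
with 50% observer coverage and scores held-out trips:

```
training pings: 6,741 on 13 trips; held-out pings: 4,976 on 6 trips
forest OOB error:            0.053 (internal estimate from out-of-bag votes)
forest held-out accuracy:    0.935
forest balanced accuracy:    0.935
5-knot cutoff accuracy:      0.702
5-knot balanced accuracy:    0.701
```

The forest recovers fishing state on unseen trips far better than the
speed rule, and the OOB estimate agrees with the grouped held-out error.
`examples/03_exposure_mapping.py` then builds the tiered exposure raster:

```
landed value, all trips:  $1,062,664
combined raster total:    $1,062,664 (conserved across tiers)
```

and sums it inside lease polygons, while
`examples/04_compare_products.py` contrasts the point product with the
footprint product (fewer, hotter cells; per-trip in-lease differences).
Run them in order:

```bash
python examples/01_simulate_fleet.py
python examples/02_classify_fishing.py
python examples/03_exposure_mapping.py
python examples/04_compare_products.py
```

A thin CLI wraps the same calls (`effortmap simulate`, `effortmap run`,
plus `ingest`, `features`, `train`, `predict`, `evaluate`).

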