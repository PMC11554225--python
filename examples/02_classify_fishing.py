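"""Train the random-forest fishing classifier on observer-labelled AIS
pings and compare it with the 5-knot speed cutoff on held-out trips.

Features are computed on centred 15-minute windows of the 1-minute
resampled track (speed statistics, distances, course-change statistics,
depth, moon and calendar covariates); the label is whether the ping's
timestamp falls inside an observed haul.  Held-out trips never contribute
pings to training.
"""

import dataclasses

import numpy as np

from effortmap import classify, features, simulate, tracks

cfg = dataclasses.replace(
    simulate.FleetConfig(), n_vessels=25, trips_per_vessel=4,
    observer_coverage=0.5, seed=7,
)
fleet = simulate.simulate_fleet(cfg)

resampled = tracks.resample_tracks(fleet.ais)
feats = features.build_feature_table(
    resampled, bathymetry=fleet.bathymetry, moon=fleet.moon
)
observed = sorted(
    set(fleet.trips.loc[fleet.trips["observed"] & fleet.trips["has_ais"], "trip_id"])
)
lab = feats[feats["trip_id"].isin(observed) & feats["valid"]].copy()
lab["fishing"] = features.label_fishing(
    lab, fleet.hauls_observed[fleet.hauls_observed["trip_id"].isin(observed)]
).to_numpy()

rng = np.random.default_rng(0)
ids = np.array(observed)
rng.shuffle(ids)
test_ids = set(ids[: max(len(ids) // 3, 1)])
tr = lab[~lab["trip_id"].isin(test_ids)]
te = lab[lab["trip_id"].isin(test_ids)]

model = classify.train(tr, tr["fishing"], classify.ForestConfig(n_trees=150, seed=0))
pred, vote = classify.predict(model, te)
forest = classify.evaluate(pred, te["fishing"])
cutoff = classify.evaluate(classify.speed_cutoff(te["sog"]), te["fishing"])

print(f"training pings: {len(tr):,} on {len(observed) - len(test_ids)} trips; "
      f"held-out pings: {len(te):,} on {len(test_ids)} trips")
print(f"forest OOB error:            {model.oob_error:.3f} "
      "(internal estimate from out-of-bag votes)")
print(f"forest held-out accuracy:    {forest.accuracy:.3f}")
print(f"forest balanced accuracy:    {forest.balanced_accuracy:.3f}")
print(f"5-knot cutoff accuracy:      {cutoff.accuracy:.3f}")
print(f"5-knot balanced accuracy:    {cutoff.balanced_accuracy:.3f}")
print("\ntop features by importance:")
for name, w in sorted(model.feature_importances.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {name:16s} {w:.3f}")
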