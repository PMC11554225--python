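"""Compare the point-based exposure product against footprint-based
exposure: per-trip footprint regression, concentration of cell values,
and the intrusion analysis over lease areas.

The footprint product smooths each trip's value around one reported
location; the point product puts value only where the vessel actually
fished.  The analyses below quantify the consequences.
"""

import dataclasses
import warnings

import numpy as np
import pandas as pd

from effortmap import evaluate, exposure, simulate
from effortmap.raster import GridSpec, Raster

cfg = dataclasses.replace(
    simulate.FleetConfig(), n_vessels=20, trips_per_vessel=3,
    observer_coverage=0.5, seed=13,
)
fleet = simulate.simulate_fleet(cfg)
xmin, ymin = fleet.crs.to_xy(cfg.extent[1], cfg.extent[0])
xmax, ymax = fleet.crs.to_xy(cfg.extent[3], cfg.extent[2])
pad = 5 * cfg.footprint_sd_km * 1000
grid = GridSpec.from_bounds(xmin - pad, ymin - pad, xmax + pad, ymax + pad, 500.0)

# 1. how well does a footprint predict where hauls actually happened?
pairs = []
for trip in sorted(set(fleet.hauls_observed["trip_id"])):
    hr = evaluate.haul_raster(
        fleet.hauls_observed[fleet.hauls_observed["trip_id"] == trip], grid, fleet.crs
    )
    pairs.append((fleet.footprint(trip, grid), hr))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    mean_slope, n_used = evaluate.mean_footprint_ols(pairs)
print(f"footprint-vs-haul OLS mean slope over {n_used} observed trips: "
      f"{mean_slope:.3f}")
print("  (1.0 would mean footprints put their mass exactly on haul cells)")

# 2. concentration: positive-cell value distributions of the two products
values = fleet.trips.set_index("trip_id")["landed_value"]
pts_parts, fp_total = [], Raster(grid)
for trip in fleet.trips["trip_id"]:
    v = float(values[trip])
    src = fleet.truth[(fleet.truth["trip_id"] == trip) & fleet.truth["fishing"]]
    p, _ = exposure.distribute_value(v, src)
    pts_parts.append(p)
    fp_total.values += exposure.footprint_value(fleet.footprint(trip, grid), v).values
pts = pd.concat(pts_parts, ignore_index=True)
pt_raster, _ = exposure.rasterize_points(pts, grid, fleet.crs)
pos_pt = pt_raster.values[pt_raster.values > 0]
pos_fp = fp_total.values[fp_total.values > 0]
print(f"\npositive cells: point product {len(pos_pt):,}, "
      f"footprint product {len(pos_fp):,}")
print(f"90th-percentile cell value: point ${np.quantile(pos_pt, 0.9):,.0f} "
      f"vs footprint ${np.quantile(pos_fp, 0.9):,.0f}")
print("  the point product concentrates value in fewer, hotter cells.")

# 3. intrusion analysis: do the products agree on in-lease dollars per trip?
point_products, fp_products = {}, {}
for trip in fleet.trips["trip_id"]:
    v = float(values[trip])
    src = fleet.truth[(fleet.truth["trip_id"] == trip) & fleet.truth["fishing"]]
    point_products[trip], _ = exposure.distribute_value(v, src)
    fp_products[trip] = exposure.footprint_value(fleet.footprint(trip, grid), v)
table, summary = evaluate.intrusion_analysis(
    point_products, fp_products, fleet.leases, fleet.crs
)
print(f"\nintrusion analysis over {summary.n_trips} trips and "
      f"{len(fleet.leases)} leases:")
print(f"  trips with identical in-lease estimates: {summary.pct_same:.1f}%")
if summary.mean_diff is not None:
    print(f"  among differing trips (footprint minus point): "
          f"mean ${summary.mean_diff:,.0f}, median ${summary.median_diff:,.0f}, "
          f"SD ${summary.sd_diff:,.0f}")
print("  positive differences mean the footprint product attributes more "
      "value to leases than the vessel's actual fishing locations justify.")
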