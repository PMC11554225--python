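"""From fishing locations to dollars on a grid.

The exposure product attributes each trip's landed ex-vessel value to
fishing locations, using the best source available for that trip:

* **AIS tier** — forest-classified fishing pings; value split evenly.
* **VMS tier** — 5-knot speed-cutoff fishing polls; value split evenly.
* **VTR tier** — per-trip fishing-probability footprint raster times the
  trip's value.

Trips are triaged stepwise (AIS, else VMS, else VTR) so every trip
contributes through exactly one tier — the guard against double counting.
Point tiers are rasterized onto the 500 m analysis grid and added to the
footprint tier with plain raster math; dollars are conserved end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import raster as rastermod
from .geometry import LocalMetricCRS
from .raster import GridSpec, Raster

TIERS = ["AIS", "VMS", "VTR"]


def triage(availability: pd.DataFrame):
    """Assign each trip to its best available source.

    ``availability`` columns: trip_id, has_ais, has_vms, has_vtr.  Tier is
    AIS when available, else VMS, else VTR; a trip in no source raises
    ``ValueError`` listing its id.  Returns ``(tiers, coverage)`` where
    ``tiers`` is a Series indexed by trip_id and ``coverage`` the per-tier
    count/percent table (percent of total, rounded to 2 decimals).
    """
    av = availability.set_index("trip_id")
    none = ~(av["has_ais"] | av["has_vms"] | av["has_vtr"])
    if none.any():
        raise ValueError(f"trips in no source: {list(av.index[none])[:10]}")
    tier = np.where(av["has_ais"], "AIS", np.where(av["has_vms"], "VMS", "VTR"))
    tiers = pd.Series(tier, index=av.index, name="tier")
    return tiers, coverage_table(tiers)


def coverage_table(tiers: pd.Series) -> pd.DataFrame:
    """Count and percent of trips per tier (percent = count/total*100, 2 dp)."""
    counts = tiers.value_counts().reindex(TIERS, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "source": TIERS,
            "n_trips": counts.to_numpy(int),
            "percent": np.round(counts.to_numpy() / total * 100.0, 2),
        }
    )


def distribute_value(landed_value: float, fishing_pings: pd.DataFrame):
    """Split a trip's landed value evenly across its fishing locations.

    Returns ``(points, fallback)``: each of the n fishing pings gets
    ``landed_value / n`` dollars.  With zero fishing pings the result is
    empty and ``fallback`` is True — the caller should demote the trip to
    the next tier so its value is not lost.
    """
    n = len(fishing_pings)
    if n == 0:
        return (
            pd.DataFrame(columns=["trip_id", "lat", "lon", "dollars"]),
            True,
        )
    pts = fishing_pings[["lat", "lon"]].copy()
    pts["dollars"] = float(landed_value) / n
    if "trip_id" in fishing_pings.columns:
        pts.insert(0, "trip_id", fishing_pings["trip_id"].to_numpy())
    return pts.reset_index(drop=True), False


def footprint_value(footprint: Raster, trip_value: float) -> Raster:
    """Scale a fishing-probability footprint (summing to 1) by trip value.

    Probabilities summing outside ``1 +/- 1e-3`` mean a malformed footprint
    and raise ``ValueError``; the output is renormalised so it sums to the
    trip value exactly.
    """
    total = footprint.total()
    if not (1 - 1e-3) <= total <= (1 + 1e-3):
        raise ValueError(f"malformed footprint: probabilities sum to {total}")
    if (np.nan_to_num(footprint.values) < 0).any():
        raise ValueError("malformed footprint: negative probabilities")
    return Raster(footprint.spec,
                  np.nan_to_num(footprint.values) * float(trip_value) / total)


def rasterize_points(points: pd.DataFrame, spec: GridSpec, crs: LocalMetricCRS):
    """Sum valued points (lat/lon/dollars) into the metric analysis grid.

    Returns ``(raster, n_outside)`` — points falling off the grid extent
    are counted, not silently dropped.
    """
    x, y = crs.to_xy(points["lat"].to_numpy(float), points["lon"].to_numpy(float))
    return rastermod.rasterize_points(x, y, points["dollars"].to_numpy(float), spec)


combine = rastermod.combine


def lease_exposure(
    rasters: dict,
    leases: dict,
    crs: LocalMetricCRS,
) -> pd.DataFrame:
    """Sum raster dollars inside each lease polygon.

    ``rasters`` maps product name -> Raster (or year -> Raster); ``leases``
    maps lease id -> polygon in WGS84 lon/lat.  Cell membership is by cell
    centre.  When exactly two products are supplied, a difference column
    (first minus second) is appended.
    """
    from shapely.ops import transform as shp_transform

    rows = []
    names = list(rasters)
    projected = {
        lease: shp_transform(
            lambda lon, lat: tuple(reversed(crs.to_xy(lat, lon))), poly
        )
        for lease, poly in leases.items()
    }
    for lease, poly in projected.items():
        row = {"lease_id": lease}
        for name in names:
            row[str(name)] = rastermod.zonal_sum(rasters[name], poly)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(names) == 2:
        out["difference"] = out[str(names[0])] - out[str(names[1])]
    return out


@dataclass
class ExposureResult:
    """Everything the value-attribution stage produces."""

    combined: Raster
    by_tier: dict
    tiers: pd.Series
    coverage: pd.DataFrame
    points: pd.DataFrame  # AIS+VMS valued points
    n_outside: int
    demoted: list = field(default_factory=list)


def build_exposure(
    trips: pd.DataFrame,
    tiers: pd.Series,
    ais_fishing: pd.DataFrame,
    vms_pings: pd.DataFrame | None,
    footprints,
    spec: GridSpec,
    crs: LocalMetricCRS,
    speed_cutoff_kn: float = 5.0,
) -> ExposureResult:
    """Run the full tiered value attribution for a fleet.

    Parameters
    ----------
    trips : trip table with landed_value.
    tiers : initial triage assignment (trip_id -> tier).
    ais_fishing : AIS pings classified as fishing (trip_id, lat, lon).
    vms_pings : VMS polls (trip_id, lat, lon, sog) for fallback.
    footprints : callable ``trip_id -> Raster`` (probability footprint on
        ``spec``) or mapping; used for the VTR tier.
    spec, crs : the 500 m analysis grid and its metric CRS.

    AIS-tier trips with zero classified fishing pings are demoted to VMS
    (cutoff-delineated), then to VTR, so no landed value vanishes.  Returns
    the combined raster, per-tier rasters, the final tier assignment after
    demotions, and the valued points of the point tiers.
    """
    from .classify import speed_cutoff as cutoff_rule

    get_fp = footprints if callable(footprints) else footprints.get
    tiers = tiers.copy()
    trips = trips.set_index("trip_id")
    demoted = []
    point_parts = []
    vtr_raster = Raster(spec)

    for trip_id, tier in tiers.items():
        value = float(trips.loc[trip_id, "landed_value"])
        original = tier
        pts = None
        if tier == "AIS":
            pings = ais_fishing[ais_fishing["trip_id"] == trip_id]
            pts, fallback = distribute_value(value, pings)
            if fallback:
                tier, pts = "VMS", None
        if tier == "VMS" and pts is None:
            polls = (
                vms_pings[vms_pings["trip_id"] == trip_id]
                if vms_pings is not None
                else pd.DataFrame(columns=["trip_id", "lat", "lon", "sog"])
            )
            fishing = polls[cutoff_rule(polls["sog"], speed_cutoff_kn)]
            pts, fallback = distribute_value(value, fishing)
            if fallback:
                tier, pts = "VTR", None
        if pts is not None:
            if "trip_id" not in pts.columns:
                pts.insert(0, "trip_id", trip_id)
            point_parts.append(pts)
        else:  # VTR tier
            fp = get_fp(trip_id)
            if fp is None:
                raise ValueError(f"no footprint available for trip {trip_id}")
            vtr_raster = rastermod.combine([vtr_raster, footprint_value(fp, value)])
        if tier != original:
            demoted.append(trip_id)
        tiers.loc[trip_id] = tier

    points = (
        pd.concat(point_parts, ignore_index=True)
        if point_parts
        else pd.DataFrame(columns=["trip_id", "lat", "lon", "dollars"])
    )
    if len(points):
        point_raster, n_outside = rasterize_points(points, spec, crs)
    else:
        point_raster, n_outside = Raster(spec), 0
    combined = rastermod.combine([point_raster, vtr_raster])
    return ExposureResult(
        combined=combined,
        by_tier={"points": point_raster, "VTR": vtr_raster},
        tiers=tiers,
        coverage=coverage_table(tiers),
        points=points,
        n_outside=n_outside,
        demoted=demoted,
    )
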