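"""Rolling-window trajectory features, environmental covariates, and
observer labelling.

Eleven candidate predictors are engineered per ping on a centred 15-minute
window over the 1-minute resampled track:

====================  =========================================================
sog_avg, sog_std      mean / sample SD of speed over ground (kn) in the window
crow_flies_km         geodesic from the window's first to last position
total_dist_km         summed consecutive geodesics within the window
depth_avg, depth_std  mean / sample SD of bathymetric depth (m, positive down)
cog_avg_abs_d         mean absolute consecutive course change (deg)
d_cog_startend        signed course change, window start to end (deg)
moon                  percent of lunar disk illuminated on the ping's date
month, day_of_week    calendar covariates (1-12; Monday=0)
====================  =========================================================

Fishing labels come from observer haul intervals: a ping is fishing iff its
timestamp falls within [start, end] of any haul of its trip (closed
interval).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import geodesic_km, heading_change
from .raster import Raster

FEATURE_NAMES = [
    "sog_avg",
    "sog_std",
    "crow_flies_km",
    "total_dist_km",
    "depth_avg",
    "depth_std",
    "cog_avg_abs_d",
    "d_cog_startend",
    "moon",
    "month",
    "day_of_week",
]

DEFAULT_WINDOW_MIN = 15
DEFAULT_MIN_PINGS = 5


def depth_at(pings: pd.DataFrame, bathymetry: Raster, negate: bool = False):
    """Sample bathymetric depth (m, positive down) at each ping.

    Nearest-cell sampling on a lon/lat grid.  Pings outside the raster or in
    no-data cells get NaN (excluded from window statistics downstream).  Set
    ``negate`` for rasters stored negative-down.
    """
    d = bathymetry.sample(pings["lon"].to_numpy(float), pings["lat"].to_numpy(float))
    if negate:
        d = -d
    return pd.Series(d, index=pings.index, name="depth")


def attach_moon(pings: pd.DataFrame, moon: pd.Series):
    """Percent lunar illumination for each ping's UTC date (NaN if absent)."""
    dates = pd.to_datetime(pings["timestamp"], utc=True).dt.date
    return dates.map(moon).astype(float)


def _window_bounds(n: int, half: int):
    idx = np.arange(n)
    return np.maximum(idx - half, 0), np.minimum(idx + half, n - 1)


def window_features(
    trip_pings: pd.DataFrame,
    depths=None,
    moon: pd.Series | None = None,
    window_min: int = DEFAULT_WINDOW_MIN,
    min_pings: int = DEFAULT_MIN_PINGS,
    tz: str = "UTC",
) -> pd.DataFrame:
    """Compute the candidate feature set for every ping of one resampled trip.

    Windows are centred on the target ping (<= ``window_min // 2`` minutes
    either side) and clipped to segment bounds, so a window never spans an
    interpolation break.  Windows holding fewer than ``min_pings`` pings, or
    whose target ping has no depth, are flagged ``valid == False`` and meant
    to be excluded from training/prediction.

    Calendar features are evaluated in timezone ``tz`` (default UTC).
    """
    half = window_min // 2
    df = trip_pings.reset_index(drop=True)
    if depths is None:  # depth source absent: features 0, not invalidating
        depths = np.zeros(len(df))
    depths = np.asarray(depths, dtype=float)

    seg = df["segment"].to_numpy() if "segment" in df.columns else np.zeros(len(df), int)
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    sog = pd.Series(df["sog"].to_numpy(float))
    cog = df["cog"].to_numpy(float)

    out = {name: np.full(len(df), np.nan) for name in FEATURE_NAMES}
    valid = np.zeros(len(df), bool)

    for s in np.unique(seg):
        sel = np.where(seg == s)[0]
        n = len(sel)
        lo, hi = _window_bounds(n, half)
        a, b = sel[lo], sel[hi]  # absolute window start/end indices

        # consecutive step quantities within the segment
        step_km = np.zeros(n)
        abs_dcog = np.zeros(n)
        if n > 1:
            step_km[1:] = geodesic_km(lat[sel[:-1]], lon[sel[:-1]],
                                      lat[sel[1:]], lon[sel[1:]])
            abs_dcog[1:] = np.abs(heading_change(cog[sel[:-1]], cog[sel[1:]]))
        cum_step = np.concatenate([[0.0], np.cumsum(step_km)])
        cum_dcog = np.concatenate([[0.0], np.cumsum(abs_dcog)])

        roll = sog.iloc[sel].reset_index(drop=True).rolling(
            2 * half + 1, center=True, min_periods=1
        )
        out["sog_avg"][sel] = roll.mean().to_numpy()
        out["sog_std"][sel] = np.nan_to_num(roll.std(ddof=1).to_numpy())

        dep = pd.Series(depths[sel]).rolling(2 * half + 1, center=True, min_periods=1)
        out["depth_avg"][sel] = dep.mean().to_numpy()
        out["depth_std"][sel] = np.nan_to_num(dep.std(ddof=1).to_numpy())

        out["crow_flies_km"][sel] = geodesic_km(lat[a], lon[a], lat[b], lon[b])
        out["total_dist_km"][sel] = cum_step[hi + 1] - cum_step[lo + 1]
        nsteps = hi - lo
        with np.errstate(invalid="ignore"):
            out["cog_avg_abs_d"][sel] = np.where(
                nsteps > 0, (cum_dcog[hi + 1] - cum_dcog[lo + 1]) / np.maximum(nsteps, 1), 0.0
            )
        out["d_cog_startend"][sel] = heading_change(cog[a], cog[b])

        count = hi - lo + 1
        valid[sel] = (count >= min_pings) & np.isfinite(depths[sel])

    ts = pd.to_datetime(df["timestamp"], utc=True)
    local = ts.dt.tz_convert(tz) if tz != "UTC" else ts
    out["month"] = local.dt.month.to_numpy(float)
    out["day_of_week"] = local.dt.dayofweek.to_numpy(float)
    out["moon"] = (
        attach_moon(df, moon).to_numpy(float) if moon is not None else np.zeros(len(df))
    )

    feats = pd.DataFrame(out)
    feats["valid"] = valid & feats[FEATURE_NAMES].notna().all(axis=1)
    for col in ["trip_id", "vessel_id", "timestamp", "lat", "lon", "sog"]:
        if col in df.columns:
            feats[col] = df[col].to_numpy()
    return feats


def label_fishing(pings: pd.DataFrame, hauls: pd.DataFrame) -> pd.Series:
    """Boolean fishing label per ping from observer haul intervals.

    Fishing iff the ping's timestamp lies in the closed interval
    ``[start, end]`` of any haul of the ping's trip.  A haul referencing a
    trip absent from the pings raises ``ValueError``; pings of unobserved
    trips get ``False`` (call only on observer-covered trips).
    """
    known = set(pings["trip_id"].dropna().astype(str))
    unknown = set(hauls["trip_id"].astype(str)) - known
    if unknown:
        raise ValueError(f"hauls reference unknown trips: {sorted(unknown)[:5]}")
    fishing = np.zeros(len(pings), dtype=bool)
    ts = pd.to_datetime(pings["timestamp"], utc=True)
    trip_ids = pings["trip_id"].astype(str).to_numpy()
    for trip, grp in hauls.groupby("trip_id"):
        sel = trip_ids == str(trip)
        if not sel.any():
            continue
        t = ts[sel]
        hit = np.zeros(sel.sum(), dtype=bool)
        for _, h in grp.iterrows():
            hit |= ((t >= h["start"]) & (t <= h["end"])).to_numpy()
        fishing[sel] = hit
    return pd.Series(fishing, index=pings.index, name="fishing")


def build_feature_table(
    resampled: pd.DataFrame,
    bathymetry: Raster | None = None,
    moon: pd.Series | None = None,
    hauls: pd.DataFrame | None = None,
    window_min: int = DEFAULT_WINDOW_MIN,
    min_pings: int = DEFAULT_MIN_PINGS,
) -> pd.DataFrame:
    """Feature vectors for every trip in a resampled ping table.

    Convenience wrapper: samples depth, computes window features per trip,
    and (when ``hauls`` is given) attaches observer fishing labels.
    """
    parts = []
    for _, grp in resampled.groupby("trip_id", sort=True):
        depths = (
            depth_at(grp, bathymetry).to_numpy()
            if bathymetry is not None
            else None
        )
        parts.append(
            window_features(grp, depths=depths, moon=moon,
                            window_min=window_min, min_pings=min_pings)
        )
    feats = pd.concat(parts, ignore_index=True)
    if hauls is not None:
        feats["fishing"] = label_fishing(feats, hauls).to_numpy()
    return feats
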