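"""Track preparation: trip linking, spatial masking, and 1-minute resampling.

A "trip" is everything a vessel does between leaving and returning to port;
pings are linked to trips by vessel id and temporal containment.  Tracks are
then regularised onto an exact 60 s grid by linear interpolation (circular
for course over ground) so that rolling-window features see evenly spaced
observations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely

from .geometry import unwrap_headings, wrap_heading

DEFAULT_INTERVAL_S = 60
DEFAULT_MAX_GAP_S = 30 * 60  # interpolate across at most 30 min


def link_trips(pings: pd.DataFrame, trips: pd.DataFrame) -> pd.DataFrame:
    """Assign ``trip_id`` to pings inside a trip's [depart, return] window.

    Trips of one vessel must not overlap (boundary contact counts as
    overlap); violations raise ``ValueError`` naming the offending trips.
    Pings outside every trip keep an unset trip_id.
    """
    for vessel, grp in trips.groupby("vessel_id"):
        g = grp.sort_values("depart")
        bad = g["depart"].iloc[1:].to_numpy() <= g["return"].iloc[:-1].to_numpy()
        if bad.any():
            i = int(np.argmax(bad))
            pair = (g["trip_id"].iloc[i], g["trip_id"].iloc[i + 1])
            raise ValueError(f"overlapping trips for vessel {vessel}: {pair}")

    out = pings.copy()
    out["trip_id"] = pd.array([None] * len(out), dtype="string")
    for vessel, grp in trips.groupby("vessel_id"):
        sel = out["vessel_id"] == vessel
        if not sel.any():
            continue
        ts = out.loc[sel, "timestamp"]
        assigned = pd.Series(pd.array([None] * sel.sum(), dtype="string"),
                             index=ts.index)
        for _, trip in grp.iterrows():
            inside = (ts >= trip["depart"]) & (ts <= trip["return"])
            assigned[inside] = trip["trip_id"]
        out.loc[sel, "trip_id"] = assigned
    return out


def mask_exclusion_zone(pings: pd.DataFrame, polygons) -> pd.DataFrame:
    """Drop pings strictly inside any exclusion polygon (e.g. state waters).

    Points exactly on a polygon boundary are retained.  Accepts a mapping or
    iterable of shapely geometries in WGS84 lon/lat; invalid geometry raises
    ``ValueError``.
    """
    geoms = list(polygons.values()) if isinstance(polygons, dict) else list(polygons)
    if not geoms:
        return pings.copy()
    for g in geoms:
        if not g.is_valid:
            raise ValueError("invalid exclusion polygon geometry")
    inside = np.zeros(len(pings), dtype=bool)
    lon = pings["lon"].to_numpy(float)
    lat = pings["lat"].to_numpy(float)
    for g in geoms:
        # contains_xy is true only for interior points, so boundaries survive
        inside |= shapely.contains_xy(g, lon, lat)
    return pings.loc[~inside].copy()


def resample_trip(
    trip_pings: pd.DataFrame,
    interval_s: int = DEFAULT_INTERVAL_S,
    max_gap_s: int = DEFAULT_MAX_GAP_S,
) -> pd.DataFrame:
    """Resample one trip's pings onto an exact ``interval_s`` grid.

    lat, lon and sog are interpolated linearly in time; cog is unwrapped to
    a continuous angle first so interpolation crosses the 0/360 seam the
    short way.  Gaps longer than ``max_gap_s`` are never interpolated
    across: the track is split into segments (``segment`` column) and each
    segment gets its own grid anchored at its first observed timestamp.
    Observed timestamps that land on the grid keep their observed values and
    ``interpolated == False``.

    A single-ping trip is returned unchanged with a warning.
    """
    df = trip_pings.sort_values("timestamp")
    if len(df) == 1:
        warnings.warn("resample_trip: single ping, returned unchanged")
        out = df.copy()
        out["segment"] = 0
        return out.reset_index(drop=True)
    t = df["timestamp"].to_numpy()
    if (np.diff(t) <= np.timedelta64(0, "s")).any():
        raise ValueError("timestamps within a trip must be strictly increasing")

    epoch = df["timestamp"].astype("int64").to_numpy() / 1e9  # seconds
    gaps = np.diff(epoch)
    seg_id = np.concatenate([[0], np.cumsum(gaps > max_gap_s)])

    pieces = []
    for seg in np.unique(seg_id):
        sdf = df[seg_id == seg]
        se = epoch[seg_id == seg]
        t0, t1 = se[0], se[-1]
        # interpolate on segment-relative seconds: far better conditioned
        # than absolute epoch seconds
        rel = se - t0
        grid_rel = interval_s * np.arange(int(np.floor((t1 - t0) / interval_s)) + 1)
        grid = t0 + grid_rel
        lat = np.interp(grid_rel, rel, sdf["lat"].to_numpy(float))
        lon = np.interp(grid_rel, rel, sdf["lon"].to_numpy(float))
        sog = np.interp(grid_rel, rel, sdf["sog"].to_numpy(float))
        cog = wrap_heading(
            np.interp(grid_rel, rel, unwrap_headings(sdf["cog"].to_numpy(float)))
        )
        observed = np.isin(grid_rel, rel)
        piece = pd.DataFrame(
            {
                "vessel_id": sdf["vessel_id"].iloc[0],
                "trip_id": sdf["trip_id"].iloc[0]
                if "trip_id" in sdf.columns
                else None,
                "timestamp": pd.to_datetime(grid * 1e9, utc=True),
                "lat": lat,
                "lon": lon,
                "sog": sog,
                "cog": cog,
                "source": sdf["source"].iloc[0] if "source" in sdf.columns else "AIS",
                "interpolated": ~observed,
                "segment": int(seg),
            }
        )
        # exact grid hits keep observed values verbatim (kill float fuzz)
        hit = np.searchsorted(grid_rel, rel[np.isin(rel, grid_rel)])
        obs_rows = sdf[np.isin(rel, grid_rel)]
        for col in ["lat", "lon", "sog", "cog"]:
            piece.loc[piece.index[hit], col] = obs_rows[col].to_numpy(float)
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def resample_tracks(
    pings: pd.DataFrame,
    interval_s: int = DEFAULT_INTERVAL_S,
    max_gap_s: int = DEFAULT_MAX_GAP_S,
) -> pd.DataFrame:
    """Resample every linked trip in a ping table (unlinked pings dropped)."""
    linked = pings[pings["trip_id"].notna()]
    parts = [
        resample_trip(grp, interval_s=interval_s, max_gap_s=max_gap_s)
        for _, grp in linked.groupby("trip_id", sort=True)
    ]
    if not parts:
        return linked.copy()
    return pd.concat(parts, ignore_index=True)
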