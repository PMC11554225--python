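"""Readers and writers for the pipeline's tabular and vector inputs.

Tracks, trips, hauls, trip reports and the moon table are headered CSV;
polygons (lease areas, exclusion zones) are GeoJSON.  All timestamps are
parsed as UTC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

TRACK_COLUMNS = ["vessel_id", "timestamp", "lat", "lon", "sog", "cog"]

#: Column mapping for the public Marine Cadastre AIS archive dialect.
MARINECADASTRE_COLUMNS = {
    "MMSI": "vessel_id",
    "BaseDateTime": "timestamp",
    "LAT": "lat",
    "LON": "lon",
    "SOG": "sog",
    "COG": "cog",
}


@dataclass
class ReadReport:
    """Row-level accounting for a track read: what came in, what was kept,
    and why the rest was dropped."""

    n_rows: int = 0
    n_kept: int = 0
    n_duplicates: int = 0
    rejected: dict = field(default_factory=dict)

    def reject(self, reason: str, count: int):
        if count:
            self.rejected[reason] = self.rejected.get(reason, 0) + int(count)


def read_tracks(path, source: str = "AIS", column_map: dict | None = None):
    """Read a vessel-track CSV into a validated ping table.

    Parameters
    ----------
    path : file path or buffer
    source : "AIS" or "VMS", recorded per ping.
    column_map : optional mapping from file column names to the canonical
        ``vessel_id, timestamp, lat, lon, sog, cog`` (e.g.
        :data:`MARINECADASTRE_COLUMNS`).

    Returns ``(pings, report)``.  Pings are sorted by (vessel_id, timestamp);
    rows violating validity rules are dropped and counted; duplicate
    (vessel, timestamp) rows keep the first occurrence.  A missing required
    column raises ``ValueError``.
    """
    df = pd.read_csv(path, dtype={0: str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track file missing required columns: {missing}")
    df = df[TRACK_COLUMNS].copy()
    report = ReadReport(n_rows=len(df))

    df["vessel_id"] = df["vessel_id"].astype(str)
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="mixed")
    bad_ts = ts.isna()
    report.reject("unparseable_timestamp", bad_ts.sum())
    df["timestamp"] = ts

    for col in ["lat", "lon", "sog", "cog"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok = ~bad_ts
    bad = ok & ~df["lat"].between(-90, 90)
    report.reject("lat_out_of_range", bad.sum())
    ok &= ~bad
    bad = ok & ~df["lon"].between(-180, 180)
    report.reject("lon_out_of_range", bad.sum())
    ok &= ~bad
    bad = ok & ~(df["sog"] >= 0)
    report.reject("negative_or_missing_sog", bad.sum())
    ok &= ~bad
    # fold cog == 360 back to 0, reject anything else outside [0, 360)
    df.loc[df["cog"] == 360.0, "cog"] = 0.0
    bad = ok & ~(df["cog"].between(0, 360) & (df["cog"] < 360))
    report.reject("cog_out_of_range", bad.sum())
    ok &= ~bad

    df = df[ok]
    dup = df.duplicated(subset=["vessel_id", "timestamp"], keep="first")
    report.n_duplicates = int(dup.sum())
    df = df[~dup]

    df = df.sort_values(["vessel_id", "timestamp"], kind="mergesort")
    df["source"] = source
    df["interpolated"] = False
    df["trip_id"] = pd.array([None] * len(df), dtype="string")
    report.n_kept = len(df)
    return df.reset_index(drop=True), report


def write_tracks(pings: pd.DataFrame, path):
    out = pings[TRACK_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def _read_table(path, required, parse_utc=()):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in parse_utc:
        df[col] = pd.to_datetime(df[col], utc=True, format="mixed")
    return df


def read_trips(path) -> pd.DataFrame:
    """Trip table: trip_id, vessel_id, depart, return (UTC), landed_value."""
    df = _read_table(
        path,
        ["trip_id", "vessel_id", "depart", "return", "landed_value"],
        parse_utc=["depart", "return"],
    )
    df["trip_id"] = df["trip_id"].astype(str)
    df["vessel_id"] = df["vessel_id"].astype(str)
    if (df["depart"] >= df["return"]).any():
        bad = df.loc[df["depart"] >= df["return"], "trip_id"].tolist()
        raise ValueError(f"trips with depart >= return: {bad}")
    return df


def read_hauls(path) -> pd.DataFrame:
    """Observer haul table: trip_id, start, end, start/end lat/lon."""
    df = _read_table(
        path,
        ["trip_id", "start", "end", "start_lat", "start_lon", "end_lat", "end_lon"],
        parse_utc=["start", "end"],
    )
    df["trip_id"] = df["trip_id"].astype(str)
    if (df["start"] >= df["end"]).any():
        raise ValueError("hauls with start >= end")
    return df


def read_vtr(path) -> pd.DataFrame:
    """Trip reports: trip_id, reported_lat, reported_lon, landed_value."""
    df = _read_table(path, ["trip_id", "reported_lat", "reported_lon", "landed_value"])
    df["trip_id"] = df["trip_id"].astype(str)
    if df["trip_id"].duplicated().any():
        raise ValueError("multiple trip reports for one trip")
    return df


def read_moon(path) -> pd.Series:
    """Moon table: date, percent_illuminated -> Series keyed by date."""
    df = _read_table(path, ["date", "percent_illuminated"])
    idx = pd.to_datetime(df["date"]).dt.date
    return pd.Series(df["percent_illuminated"].to_numpy(float), index=idx)


def read_polygons(path) -> dict:
    """GeoJSON FeatureCollection -> {name: shapely geometry} (WGS84 lon/lat).

    Feature names come from properties ``lease_id``/``id``/``name`` in that
    order, else the feature index.  Invalid geometries raise ``ValueError``.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = {}
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        name = str(props.get("lease_id") or props.get("id") or props.get("name") or i)
        geom = shapely_shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid polygon geometry for feature {name!r}")
        out[name] = geom
    return out


def write_polygons(polys: dict, path):
    feats = [
        {
            "type": "Feature",
            "properties": {"lease_id": name},
            "geometry": json.loads(shapely.to_geojson(geom)),
        }
        for name, geom in polys.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_timestamps(df, cols):
    df = df.copy()
    for c in cols:
        df[c] = pd.to_datetime(df[c], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    return df
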