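"""Synthetic scallop-fleet generator.

Produces ground-truth vessel behaviour and every degraded observation
product the pipeline consumes — AIS tracks, VMS polls, single-point trip
reports with probability footprints, partial observer haul coverage, and
per-trip landings — so the whole pipeline is testable without confidential
data.

The behaviour model is a two-state semi-Markov trajectory per trip:

* **fishing (dredging)** — slow (default 4.5 +/- 1 kn) with a high turning
  rate, in exponential-dwell runs that *are* the trip's hauls;
* **non-fishing** — steaming runs (default 9 +/- 1 kn, near-straight)
  interleaved with slow "slack" runs (gear handling, haul-back, drifting;
  default 3 +/- 1 kn) after every haul.  The slack periods are what make a
  plain 5-knot speed rule fail in a realistic way: slow does not imply
  fishing.

Headings follow a correlated random walk with state-specific turn SD;
per-minute speeds are drawn per state.  The speed distributions straddle
the 5-knot dredge cutoff by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geometry import LocalMetricCRS, M_PER_MIN_PER_KNOT, wrap_heading
from .raster import GridSpec, Raster

SYNODIC_MONTH_DAYS = 29.530588
_NEW_MOON_REF = pd.Timestamp("2000-01-06", tz="UTC")


@dataclass
class FleetConfig:
    """Study conditions for the synthetic fleet.

    Speeds in knots, dwell times in minutes, values in USD.  The defaults
    describe a Southern-New-England-like dredge fleet: fishing at
    4.5 +/- 1 kn (inside the published 2.5-6 kn dredge band), steaming at
    9 +/- 1 kn, slack gear-handling at 3 +/- 1 kn, ~7% observer coverage,
    hourly VMS polls, and a trip report at the first haul location.
    """

    n_vessels: int = 20
    trips_per_vessel: int = 3

    transit_speed_mean: float = 9.0
    transit_speed_sd: float = 1.0
    transit_turn_sd: float = 3.0  # deg per minute

    slack_speed_mean: float = 3.0
    slack_speed_sd: float = 1.0
    slack_turn_sd: float = 25.0
    slack_dwell_min: float = 8.0

    fishing_speed_mean: float = 4.5
    fishing_speed_sd: float = 1.0
    fishing_turn_sd: float = 20.0
    fishing_dwell_min: float = 30.0

    transit_dwell_min: float = 12.0  # steaming run between hauls
    port_transit_min: float = 45.0  # steaming run at trip start/end
    hauls_per_trip_mean: float = 9.0  # 1 + Poisson(mean - 1)

    observer_coverage: float = 0.07
    vms_interval_min: int = 60
    vtr_rule: str = "first_haul"  # first_haul | last_haul | max_catch
    footprint_sd_km: float = 5.0

    haul_value_mean: float = 2000.0
    haul_value_sd: float = 600.0

    p_ais: float = 0.45  # vessel-level AIS carriage
    p_vms_given_no_ais: float = 0.6
    ais_dropout: float = 0.02  # per-ping transmission loss

    extent: tuple = (-71.5, 40.2, -70.0, 41.3)  # lon_min, lat_min, lon_max, lat_max
    exclusion_margin_deg: float = 0.0  # optional coastal strip at north edge
    start_date: str = "2015-01-01"
    end_date: str = "2018-12-31"
    seed: int = 0


@dataclass
class FleetData:
    """Everything :func:`simulate_fleet` produces.

    ``truth`` holds the full-resolution tracks of *all* vessels with the
    true per-ping behavioural state; the observation products (``ais``,
    ``vms``, ``vtr``, observed hauls) are degraded views of it.
    """

    config: FleetConfig
    crs: LocalMetricCRS
    grid: GridSpec
    truth: pd.DataFrame  # 1-min pings, all vessels, with `fishing` truth
    ais: pd.DataFrame
    vms: pd.DataFrame
    trips: pd.DataFrame  # + has_ais/has_vms/has_vtr availability flags
    hauls_all: pd.DataFrame
    hauls_observed: pd.DataFrame
    vtr: pd.DataFrame
    leases: dict
    bathymetry: Raster
    moon: pd.Series
    exclusion: dict = field(default_factory=dict)

    def footprint(self, trip_id: str, spec: GridSpec | None = None) -> Raster:
        """Per-trip fishing-probability footprint: an isotropic Gaussian
        around the reported VTR point, truncated at 4 SD, normalised to 1,
        on the analysis grid (or ``spec`` when given)."""
        row = self.vtr.set_index("trip_id").loc[trip_id]
        return gaussian_footprint(
            spec if spec is not None else self.grid, self.crs,
            float(row["reported_lat"]), float(row["reported_lon"]),
            self.config.footprint_sd_km,
        )


def gaussian_footprint(spec: GridSpec, crs: LocalMetricCRS, lat: float,
                       lon: float, sd_km: float) -> Raster:
    """Discretised isotropic Gaussian probability surface summing to 1."""
    x0, y0 = crs.to_xy(lat, lon)
    xs, ys = spec.centers()
    xg, yg = np.meshgrid(xs, ys)
    sd_m = sd_km * 1000.0
    d2 = (xg - x0) ** 2 + (yg - y0) ** 2
    p = np.exp(-0.5 * d2 / sd_m**2)
    p[d2 > (4 * sd_m) ** 2] = 0.0
    total = p.sum()
    if total == 0:  # reported point far outside the grid: nearest cell
        ix, iy = spec.cell_index(x0, y0)
        ix = int(np.clip(ix, 0, spec.nx - 1))
        iy = int(np.clip(iy, 0, spec.ny - 1))
        p[iy, ix] = 1.0
        total = 1.0
    return Raster(spec, p / total)


def default_leases(extent, n_leases: int = 10) -> dict:
    """Fixed layout of rectangular lease polygons across the study area."""
    lon_min, lat_min, lon_max, lat_max = extent
    dlon, dlat = lon_max - lon_min, lat_max - lat_min
    leases = {}
    for i in range(n_leases):
        cx = lon_min + dlon * (0.14 + 0.155 * (i % 5))
        cy = lat_min + dlat * (0.30 if i < 5 else 0.62)
        w, h = 0.10 * dlon, 0.13 * dlat
        leases[f"LEASE-{i + 1:02d}"] = box(cx - w / 2, cy - h / 2,
                                           cx + w / 2, cy + h / 2)
    return leases


def synthetic_bathymetry(extent, cell_deg: float = 0.01) -> Raster:
    """Smooth synthetic depth surface (m, positive down): deepens southward
    with mild along-shelf ripples."""
    lon_min, lat_min, lon_max, lat_max = extent
    spec = GridSpec.from_bounds(lon_min, lat_min, lon_max, lat_max, cell_deg)
    xs, ys = spec.centers()
    lon, lat = np.meshgrid(xs, ys)
    depth = (
        30.0
        + 45.0 * (lat_max - lat) / (lat_max - lat_min)
        + 4.0 * np.sin(lon * 40.0)
        + 3.0 * np.cos(lat * 55.0)
    )
    return Raster(spec, depth)


def synthetic_moon_table(start: str, end: str) -> pd.Series:
    """Date-keyed percent lunar illumination from the synodic cycle."""
    dates = pd.date_range(start, end, freq="D", tz="UTC")
    phase = 2 * np.pi * ((dates - _NEW_MOON_REF).days % SYNODIC_MONTH_DAYS) / SYNODIC_MONTH_DAYS
    illum = 50.0 * (1.0 - np.cos(phase))
    return pd.Series(illum, index=dates.date)


def _simulate_trip(rng, cfg: FleetConfig, crs: LocalMetricCRS, vessel_id,
                   trip_id, t0):
    """One trip's minute-resolution truth track plus its hauls/landings."""
    n_hauls = 1 + rng.poisson(max(cfg.hauls_per_trip_mean - 1.0, 0.0))
    runs = [("transit", cfg.port_transit_min)]
    for _ in range(n_hauls):
        runs.append(("fishing", cfg.fishing_dwell_min))
        runs.append(("slack", cfg.slack_dwell_min))
        runs.append(("transit", cfg.transit_dwell_min))
    runs[-1] = ("transit", cfg.port_transit_min)

    states = []
    for state, mean_dwell in runs:
        dur = max(int(np.ceil(rng.exponential(mean_dwell))), 2)
        states.extend([state] * dur)
    states = np.array(states)
    n = len(states)

    spd_mean = {"transit": cfg.transit_speed_mean, "slack": cfg.slack_speed_mean,
                "fishing": cfg.fishing_speed_mean}
    spd_sd = {"transit": cfg.transit_speed_sd, "slack": cfg.slack_speed_sd,
              "fishing": cfg.fishing_speed_sd}
    turn_sd = {"transit": cfg.transit_turn_sd, "slack": cfg.slack_turn_sd,
               "fishing": cfg.fishing_turn_sd}
    sog = np.clip(
        rng.normal([spd_mean[s] for s in states], [spd_sd[s] for s in states]),
        0.2, None,
    )
    turns = rng.normal(0.0, [turn_sd[s] for s in states])
    heading = wrap_heading(rng.uniform(0, 360) + np.concatenate([[0], np.cumsum(turns[:-1])]))

    lon_min, lat_min, lon_max, lat_max = cfg.extent
    start_lat = rng.uniform(lat_min + 0.1 * (lat_max - lat_min),
                            lat_max - 0.1 * (lat_max - lat_min))
    start_lon = rng.uniform(lon_min + 0.1 * (lon_max - lon_min),
                            lon_max - 0.1 * (lon_max - lon_min))
    x0, y0 = crs.to_xy(start_lat, start_lon)
    step = sog * M_PER_MIN_PER_KNOT
    dx = step * np.sin(np.radians(heading))
    dy = step * np.cos(np.radians(heading))
    x = x0 + np.concatenate([[0], np.cumsum(dx[:-1])])
    y = y0 + np.concatenate([[0], np.cumsum(dy[:-1])])
    # keep tracks inside the study area by folding at the extent walls
    xmin, ymin = crs.to_xy(lat_min, lon_min)
    xmax, ymax = crs.to_xy(lat_max, lon_max)
    x = _fold(x, xmin, xmax)
    y = _fold(y, ymin, ymax)
    lat, lon = crs.to_latlon(x, y)

    ts = pd.date_range(t0, periods=n, freq="60s", tz="UTC")
    pings = pd.DataFrame(
        {
            "vessel_id": vessel_id,
            "trip_id": trip_id,
            "timestamp": ts,
            "lat": lat,
            "lon": lon,
            "sog": sog,
            "cog": heading,
            "source": "AIS",
            "interpolated": False,
            "fishing": states == "fishing",
        }
    )

    # hauls = maximal fishing runs
    f = pings["fishing"].to_numpy()
    edges = np.flatnonzero(np.diff(np.concatenate([[0], f.view(np.int8), [0]])))
    hauls = []
    for s, e in zip(edges[::2], edges[1::2]):  # [s, e) run
        hauls.append(
            {
                "trip_id": trip_id,
                "start": ts[s],
                "end": ts[e - 1],
                "start_lat": lat[s],
                "start_lon": lon[s],
                "end_lat": lat[e - 1],
                "end_lon": lon[e - 1],
            }
        )
    hauls = pd.DataFrame(hauls)
    values = np.clip(
        rng.normal(cfg.haul_value_mean, cfg.haul_value_sd, len(hauls)), 100.0, None
    )
    hauls["value"] = values
    return pings, hauls


def _fold(v, lo, hi):
    """Reflect coordinates into [lo, hi] (triangle-wave folding)."""
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    return lo + np.where(v > span, 2 * span - v, v)


def degrade_to_vms(pings: pd.DataFrame, interval_min: int) -> pd.DataFrame:
    """Subsample a 1-minute track to VMS polls: the first ping of every
    ``interval_min`` bin (binned from each trip's first timestamp)."""
    parts = []
    for _, grp in pings.groupby("trip_id", sort=True):
        t = grp["timestamp"]
        mins = ((t - t.iloc[0]).dt.total_seconds() // 60).astype(int)
        keep = ~(mins // interval_min).duplicated()
        parts.append(grp[keep.to_numpy()])
    out = pd.concat(parts, ignore_index=True)
    out = out.copy()
    out["source"] = "VMS"
    return out


def simulate_fleet(config: FleetConfig | None = None,
                   grid_cell_m: float = 500.0) -> FleetData:
    """Generate the full synthetic study: truth plus all observation products.

    Deterministic for a fixed ``config.seed``.  Raises ``ValueError`` on a
    degenerate extent.
    """
    cfg = config or FleetConfig()
    lon_min, lat_min, lon_max, lat_max = cfg.extent
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError(f"degenerate extent {cfg.extent}")
    rng = np.random.default_rng(cfg.seed)
    crs = LocalMetricCRS.from_extent(*cfg.extent)
    xmin, ymin = crs.to_xy(lat_min, lon_min)
    xmax, ymax = crs.to_xy(lat_max, lon_max)
    grid = GridSpec.from_bounds(xmin, ymin, xmax, ymax, grid_cell_m)

    start = pd.Timestamp(cfg.start_date, tz="UTC")
    end = pd.Timestamp(cfg.end_date, tz="UTC")
    horizon_min = int((end - start).total_seconds() // 60)

    ping_parts, haul_parts, trip_rows = [], [], []
    for v in range(cfg.n_vessels):
        vessel_id = f"V{v + 1:04d}"
        has_ais = rng.random() < cfg.p_ais
        has_vms = bool(has_ais) or rng.random() < cfg.p_vms_given_no_ais
        starts = np.sort(rng.integers(0, max(horizon_min - 3000, 1),
                                      cfg.trips_per_vessel))
        prev_end = start - pd.Timedelta(minutes=1)
        for k in range(cfg.trips_per_vessel):
            trip_id = f"{vessel_id}-T{k + 1:02d}"
            t0 = max(start + pd.Timedelta(minutes=int(starts[k])),
                     prev_end + pd.Timedelta(minutes=60))
            pings, hauls = _simulate_trip(rng, cfg, crs, vessel_id, trip_id, t0)
            prev_end = pings["timestamp"].iloc[-1]
            ping_parts.append(pings)
            haul_parts.append(hauls)
            trip_rows.append(
                {
                    "trip_id": trip_id,
                    "vessel_id": vessel_id,
                    "depart": pings["timestamp"].iloc[0],
                    "return": pings["timestamp"].iloc[-1],
                    "landed_value": float(hauls["value"].sum()),
                    "has_ais": has_ais,
                    "has_vms": has_vms,
                    "has_vtr": True,
                }
            )

    truth = pd.concat(ping_parts, ignore_index=True)
    hauls_all = pd.concat(haul_parts, ignore_index=True)
    trips = pd.DataFrame(trip_rows)

    # observer coverage: random fraction of trips carries an observer
    observed_mask = rng.random(len(trips)) < cfg.observer_coverage
    trips["observed"] = observed_mask
    observed_ids = set(trips.loc[observed_mask, "trip_id"])
    hauls_observed = hauls_all[hauls_all["trip_id"].isin(observed_ids)].drop(
        columns="value"
    ).reset_index(drop=True)

    # AIS: per-ping dropout, AIS vessels only
    ais_trips = set(trips.loc[trips["has_ais"], "trip_id"])
    ais = truth[truth["trip_id"].isin(ais_trips)].copy()
    keep = rng.random(len(ais)) > cfg.ais_dropout
    # never drop a trip's first/last ping (trip extent must survive)
    first_last = ais.groupby("trip_id")["timestamp"].transform(
        lambda t: (t == t.iloc[0]) | (t == t.iloc[-1])
    )
    ais = ais[keep | first_last.to_numpy()].drop(columns="fishing").reset_index(drop=True)

    vms_trips = set(trips.loc[trips["has_vms"], "trip_id"])
    vms = degrade_to_vms(
        truth[truth["trip_id"].isin(vms_trips)], cfg.vms_interval_min
    ).drop(columns="fishing").reset_index(drop=True)

    # VTR: one reported point per trip, placed by the reporting rule
    vtr_rows = []
    for trip_id, grp in hauls_all.groupby("trip_id", sort=True):
        if cfg.vtr_rule == "first_haul":
            h = grp.iloc[0]
        elif cfg.vtr_rule == "last_haul":
            h = grp.iloc[-1]
        elif cfg.vtr_rule == "max_catch":
            h = grp.loc[grp["value"].idxmax()]
        else:
            raise ValueError(f"unknown vtr_rule {cfg.vtr_rule!r}")
        vtr_rows.append(
            {
                "trip_id": trip_id,
                "reported_lat": float(h["start_lat"]),
                "reported_lon": float(h["start_lon"]),
                "landed_value": float(grp["value"].sum()),
            }
        )
    vtr = pd.DataFrame(vtr_rows)

    exclusion = {}
    if cfg.exclusion_margin_deg > 0:
        exclusion["state-waters"] = box(
            lon_min, lat_max - cfg.exclusion_margin_deg, lon_max, lat_max
        )

    return FleetData(
        config=cfg,
        crs=crs,
        grid=grid,
        truth=truth,
        ais=ais,
        vms=vms,
        trips=trips,
        hauls_all=hauls_all.drop(columns="value"),
        hauls_observed=hauls_observed,
        vtr=vtr,
        leases=default_leases(cfg.extent),
        bathymetry=synthetic_bathymetry(cfg.extent),
        moon=synthetic_moon_table(cfg.start_date, cfg.end_date),
        exclusion=exclusion,
    )


def write_fleet(fleet: FleetData, outdir):
    """Write every product in the dialects the readers consume: track/trip/
    haul/VTR CSVs, lease GeoJSON, moon CSV, bathymetry ASCII grid."""
    import os

    from . import io as iomod
    from .raster import write_ascii

    os.makedirs(outdir, exist_ok=True)
    iomod.write_tracks(fleet.ais, os.path.join(outdir, "ais_tracks.csv"))
    iomod.write_tracks(fleet.vms, os.path.join(outdir, "vms_tracks.csv"))
    trips = iomod.write_timestamps(fleet.trips, ["depart", "return"])
    trips.to_csv(os.path.join(outdir, "trips.csv"), index=False)
    hauls = iomod.write_timestamps(fleet.hauls_observed, ["start", "end"])
    hauls.to_csv(os.path.join(outdir, "hauls_observed.csv"), index=False)
    fleet.vtr.to_csv(os.path.join(outdir, "vtr.csv"), index=False)
    pd.DataFrame(
        {"date": list(fleet.moon.index), "percent_illuminated": fleet.moon.to_numpy()}
    ).to_csv(os.path.join(outdir, "moon.csv"), index=False)
    iomod.write_polygons(fleet.leases, os.path.join(outdir, "leases.geojson"))
    if fleet.exclusion:
        iomod.write_polygons(fleet.exclusion, os.path.join(outdir, "exclusion.geojson"))
    write_ascii(fleet.bathymetry, os.path.join(outdir, "bathymetry.asc"))
    truth = iomod.write_timestamps(
        fleet.truth[["trip_id", "timestamp", "fishing"]], ["timestamp"]
    )
    truth.to_csv(os.path.join(outdir, "truth_labels.csv"), index=False)
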