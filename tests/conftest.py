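import dataclasses

import numpy as np
import pandas as pd
import pytest

from effortmap import simulate
from effortmap.geometry import LocalMetricCRS
from effortmap.raster import GridSpec


@pytest.fixture(scope="session")
def small_fleet():
    """A compact synthetic fleet with generous observer coverage, shared by
    read-only tests."""
    cfg = dataclasses.replace(
        simulate.FleetConfig(),
        n_vessels=12,
        trips_per_vessel=2,
        observer_coverage=0.5,
        seed=7,
    )
    return simulate.simulate_fleet(cfg)


@pytest.fixture(scope="session")
def metric_grid(small_fleet):
    """Analysis grid covering the fleet's full study area with footprint
    headroom, so dollars cannot fall off the edge."""
    cfg = small_fleet.config
    crs = small_fleet.crs
    xmin, ymin = crs.to_xy(cfg.extent[1], cfg.extent[0])
    xmax, ymax = crs.to_xy(cfg.extent[3], cfg.extent[2])
    pad = 5 * cfg.footprint_sd_km * 1000
    return GridSpec.from_bounds(xmin - pad, ymin - pad, xmax + pad, ymax + pad, 500.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_track(
    n=40,
    t0="2016-03-01T00:00:00Z",
    lat0=40.8,
    lon0=-70.9,
    sog=6.0,
    cog=45.0,
    vessel="V1",
    trip="V1-T01",
    step_min=1,
):
    """Straight constant-speed 1-minute track helper used across tests."""
    from effortmap.geometry import M_PER_MIN_PER_KNOT, LocalMetricCRS

    crs = LocalMetricCRS(lat0, lon0)
    step = np.atleast_1d(np.asarray(sog, float)) * M_PER_MIN_PER_KNOT
    if step.size == 1:
        step = np.full(n, step[0])
    head = np.atleast_1d(np.asarray(cog, float))
    if head.size == 1:
        head = np.full(n, head[0])
    dx = step * np.sin(np.radians(head))
    dy = step * np.cos(np.radians(head))
    x = np.concatenate([[0], np.cumsum(dx[:-1])])
    y = np.concatenate([[0], np.cumsum(dy[:-1])])
    lat, lon = crs.to_latlon(x, y)
    return pd.DataFrame(
        {
            "vessel_id": vessel,
            "trip_id": trip,
            "timestamp": pd.date_range(t0, periods=n, freq=f"{step_min}min", tz="UTC"),
            "lat": lat,
            "lon": lon,
            "sog": np.broadcast_to(np.asarray(sog, float), (n,)).copy(),
            "cog": head % 360.0,
            "source": "AIS",
            "interpolated": False,
            "segment": 0,
        }
    )
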