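"""Comparison analyses between data products.

Implements the evaluation battery used to judge the point-based product
against observer truth and against footprint rasters: speed-cutoff accuracy,
per-trip footprint regression against haul rasters, difference rasters,
kernel density summaries of cell values, and the per-trip intrusion
analysis over lease polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy.stats import gaussian_kde
from shapely.ops import transform as shp_transform

from . import raster as rastermod
from .classify import speed_cutoff
from .geometry import LocalMetricCRS
from .raster import GridSpec, Raster


def cutoff_accuracy(sog, labels, cutoff: float = 5.0) -> float:
    """Fraction of pings the speed-cutoff rule labels correctly."""
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("no labelled pings")
    return float((speed_cutoff(sog, cutoff) == labels).mean())


def haul_raster(hauls: pd.DataFrame, spec: GridSpec, crs: LocalMetricCRS) -> Raster:
    """Binary raster of cells intersected by any haul start->end segment."""
    values = np.zeros((spec.ny, spec.nx))
    for _, h in hauls.iterrows():
        xa, ya = crs.to_xy(h["start_lat"], h["start_lon"])
        xb, yb = crs.to_xy(h["end_lat"], h["end_lon"])
        cells = rastermod.supercover_cells(spec, xa, ya, xb, yb)
        ok = spec.contains_index(cells[:, 0], cells[:, 1])
        values[cells[ok, 1], cells[ok, 0]] = 1.0
    return Raster(spec, values)


def footprint_ols(footprint: Raster, hauls: Raster) -> float:
    """Slope of the no-intercept OLS of haul indicator on footprint density.

    Response: the binary haul-cell indicator.  Predictor: footprint cell
    probability rescaled by the haul-cell count, so a footprint placing its
    mass uniformly on exactly the haul cells scores 1 and a footprint with
    no mass on them scores 0; the fleet mean slope then reads as a percent
    accuracy.  A zero-variance predictor (empty footprint) is undefined and
    raises ``ValueError``.
    """
    if footprint.spec != hauls.spec:
        raise ValueError("footprint and haul raster grids differ")
    y = np.nan_to_num(hauls.values).ravel()
    x = np.nan_to_num(footprint.values).ravel()
    n_haul = y.sum()
    if x.max() == x.min():
        raise ValueError("zero-variance footprint predictor")
    if n_haul == 0:
        return 0.0
    x = x * n_haul  # uniform-on-hauls footprint -> predictor 1 on haul cells
    fit = sm.OLS(y, x[:, None]).fit()
    return float(fit.params[0])


def mean_footprint_ols(pairs):
    """Mean per-trip slope over ``(footprint, haul_raster)`` pairs.

    Trips with an undefined slope are skipped with a warning; returns
    ``(mean_slope, n_used)``.
    """
    slopes = []
    for fp, hr in pairs:
        try:
            slopes.append(footprint_ols(fp, hr))
        except ValueError as err:
            warnings.warn(f"footprint OLS skipped: {err}")
    if not slopes:
        raise ValueError("no trips with a defined footprint slope")
    return float(np.mean(slopes)), len(slopes)


def difference_raster(a: Raster, b: Raster) -> Raster:
    """Cellwise ``a - b`` on a shared grid (sign: first minus second)."""
    return rastermod.difference(a, b)


def cell_value_kde(raster: Raster, polygon, crs: LocalMetricCRS,
                   n_points: int = 256):
    """Gaussian KDE of positive cell values within a lease polygon.

    Scott's bandwidth rule; only strictly positive cells enter the
    estimate.  Returns ``(grid, density)`` with the density integrating to
    ~1 over the grid.  Fewer than 2 positive cells raises ``ValueError``.
    """
    poly_xy = shp_transform(
        lambda lon, lat: tuple(reversed(crs.to_xy(lat, lon))), polygon
    )
    xs, ys = raster.spec.centers()
    xg, yg = np.meshgrid(xs, ys)
    inside = shapely.intersects_xy(poly_xy, xg.ravel(), yg.ravel())
    vals = np.nan_to_num(raster.values).ravel()[inside]
    vals = vals[vals > 0]
    if len(vals) < 2:
        raise ValueError("need >= 2 positive cells inside the polygon")
    kde = gaussian_kde(vals, bw_method="scott")
    span = vals.max() - vals.min()
    pad = 3 * kde.factor * vals.std(ddof=1) + 1e-9 + 0.05 * span
    grid = np.linspace(vals.min() - pad, vals.max() + pad, n_points)
    return grid, kde(grid)


@dataclass
class IntrusionSummary:
    """How often two products agree on per-trip in-lease exposure, and how
    far apart they are when they do not."""

    n_trips: int
    n_same: int
    pct_same: float
    mean_diff: float | None
    median_diff: float | None
    sd_diff: float | None  # sample SD (n-1)


def _points_in_lease_value(points: pd.DataFrame, poly) -> float:
    if not len(points):
        return 0.0
    inside = shapely.intersects_xy(
        poly, points["lon"].to_numpy(float), points["lat"].to_numpy(float)
    )
    return float(points["dollars"].to_numpy(float)[inside].sum())


def intrusion_analysis(
    point_products: dict,
    footprint_products: dict,
    leases: dict,
    crs: LocalMetricCRS,
    match_tol: float = 0.01,
):
    """Per-trip comparison of in-lease exposure between two products.

    ``point_products`` maps trip_id -> valued points (lat, lon, dollars);
    ``footprint_products`` maps trip_id -> value raster (footprint x trip
    value) on the metric grid.  For every trip present in both, dollars per
    lease are computed for each product and the difference reported as
    footprint minus points (VTR minus AIS).  Trips whose per-lease
    differences are all below ``match_tol`` dollars in magnitude count as
    matching; summary statistics (mean/median/sample SD of the per-trip
    total in-lease difference) cover only the differing trips.

    Returns ``(per_trip_lease, summary)``: a tidy frame with columns
    trip_id, lease_id, ais_usd, vtr_usd, diff_usd, and an
    :class:`IntrusionSummary`.
    """
    lease_xy = {
        name: shp_transform(
            lambda lon, lat: tuple(reversed(crs.to_xy(lat, lon))), poly
        )
        for name, poly in leases.items()
    }
    trips = sorted(set(point_products) & set(footprint_products))
    rows = []
    per_trip_diff = {}
    for trip in trips:
        pts = point_products[trip]
        fp = footprint_products[trip]
        total = 0.0
        for lease, poly in leases.items():
            ais_usd = _points_in_lease_value(pts, poly)
            vtr_usd = rastermod.zonal_sum(fp, lease_xy[lease])
            diff = vtr_usd - ais_usd
            rows.append(
                {
                    "trip_id": trip,
                    "lease_id": lease,
                    "ais_usd": ais_usd,
                    "vtr_usd": vtr_usd,
                    "diff_usd": diff,
                }
            )
            total += diff
        per_trip_diff[trip] = total

    table = pd.DataFrame(rows)
    if len(table):
        max_abs = table.groupby("trip_id")["diff_usd"].apply(
            lambda s: s.abs().max()
        )
    else:
        max_abs = pd.Series(dtype=float)
    same = max_abs[max_abs < match_tol].index
    differing = [per_trip_diff[t] for t in trips if t not in set(same)]
    n = len(trips)
    summary = IntrusionSummary(
        n_trips=n,
        n_same=len(same),
        pct_same=round(100.0 * len(same) / n, 2) if n else 0.0,
        mean_diff=float(np.mean(differing)) if differing else None,
        median_diff=float(np.median(differing)) if differing else None,
        sd_diff=float(np.std(differing, ddof=1)) if len(differing) > 1 else None,
    )
    return table, summary
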