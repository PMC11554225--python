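"""Lightweight single-band rasters on regular grids.

A :class:`GridSpec` is either a projected metric grid (500 m analysis cells,
coordinates from :class:`~effortmap.geometry.LocalMetricCRS`) or a geographic
lon/lat grid (bathymetry).  Cells are half-open: cell ``(ix, iy)`` covers
``[x0 + ix*cell, x0 + (ix+1)*cell) x [y0 + iy*cell, y0 + (iy+1)*cell)`` with
row 0 at the southern edge.

Rasters are written/read as Esri ASCII grid (``.asc``), a plain-text format
any GIS opens directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely


@dataclass(frozen=True)
class GridSpec:
    """Origin (lower-left corner), square cell size, and shape of a grid."""

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    @classmethod
    def from_bounds(cls, xmin, ymin, xmax, ymax, cell) -> "GridSpec":
        """Smallest grid covering the bounds, origin snapped to a multiple
        of the cell size so grids built from different extents align."""
        x0 = np.floor(xmin / cell) * cell
        y0 = np.floor(ymin / cell) * cell
        nx = int(np.ceil((xmax - x0) / cell))
        ny = int(np.ceil((ymax - y0) / cell))
        return cls(float(x0), float(y0), float(cell), max(nx, 1), max(ny, 1))

    def cell_index(self, x, y):
        """Column/row of the cell containing each point (may be out of range)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.x0) / self.cell).astype(int)
        iy = np.floor((y - self.y0) / self.cell).astype(int)
        return ix, iy

    def contains_index(self, ix, iy):
        return (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)

    def centers(self):
        """1-D arrays of cell-centre x and y coordinates."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell
        return xs, ys

    @property
    def xmax(self):
        return self.x0 + self.nx * self.cell

    @property
    def ymax(self):
        return self.y0 + self.ny * self.cell


class Raster:
    """A :class:`GridSpec` plus a float array of shape ``(ny, nx)``.

    ``values[iy, ix]`` with ``iy`` counted from the southern row.
    """

    def __init__(self, spec: GridSpec, values: np.ndarray | None = None):
        self.spec = spec
        if values is None:
            values = np.zeros((spec.ny, spec.nx))
        values = np.asarray(values, dtype=float)
        if values.shape != (spec.ny, spec.nx):
            raise ValueError(
                f"values shape {values.shape} != grid shape {(spec.ny, spec.nx)}"
            )
        self.values = values

    def total(self) -> float:
        return float(np.nansum(self.values))

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy())

    def sample(self, x, y, nodata=np.nan):
        """Nearest-cell (containing-cell) values at points; ``nodata`` outside."""
        ix, iy = self.spec.cell_index(x, y)
        ok = self.spec.contains_index(ix, iy)
        out = np.full(np.shape(ix), float(nodata))
        out[ok] = self.values[iy[ok], ix[ok]]
        return out


def rasterize_points(x, y, weights, spec: GridSpec):
    """Sum point weights into their containing cells.

    Returns ``(raster, n_outside)``; points outside the extent are dropped
    and counted, never silently folded into edge cells.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    ix, iy = spec.cell_index(x, y)
    ok = spec.contains_index(ix, iy)
    values = np.zeros((spec.ny, spec.nx))
    np.add.at(values, (iy[ok], ix[ok]), w[ok])
    return Raster(spec, values), int((~ok).sum())


def _check_same_grid(a: Raster, b: Raster):
    if a.spec != b.spec:
        raise ValueError(f"grid mismatch: {a.spec} vs {b.spec}")


def combine(rasters) -> Raster:
    """Cellwise sum of rasters on one grid; NaN (no-data) counts as 0."""
    rasters = list(rasters)
    if not rasters:
        raise ValueError("no rasters to combine")
    out = Raster(rasters[0].spec)
    for r in rasters:
        _check_same_grid(out, r)
        out.values += np.nan_to_num(r.values)
    return out


def difference(a: Raster, b: Raster) -> Raster:
    """Cellwise ``a - b`` (no-data as 0)."""
    _check_same_grid(a, b)
    return Raster(a.spec, np.nan_to_num(a.values) - np.nan_to_num(b.values))


def supercover_cells(spec: GridSpec, xa, ya, xb, yb):
    """All cells a closed segment passes through (supercover traversal).

    Walks the segment's crossings of grid lines and records the cell at the
    midpoint of every inter-crossing interval, so cells are found regardless
    of direction or slope.  Returns an ``(n, 2)`` int array of ``(ix, iy)``
    including cells outside the grid extent; filter with
    ``spec.contains_index`` if needed.
    """
    xa, ya, xb, yb = (float(v) for v in (xa, ya, xb, yb))
    ts = [0.0, 1.0]
    for p0, p1, o in ((xa, xb, spec.x0), (ya, yb, spec.y0)):
        if p1 != p0:
            k0 = np.ceil((min(p0, p1) - o) / spec.cell)
            k1 = np.floor((max(p0, p1) - o) / spec.cell)
            if k1 >= k0:
                lines = o + np.arange(k0, k1 + 1) * spec.cell
                ts.extend(((lines - p0) / (p1 - p0)).tolist())
    ts = np.unique(np.clip(ts, 0.0, 1.0))
    mids = (ts[:-1] + ts[1:]) / 2.0
    if mids.size == 0:  # degenerate: point segment
        mids = np.array([0.0])
    mx = xa + mids * (xb - xa)
    my = ya + mids * (yb - ya)
    ix, iy = spec.cell_index(mx, my)
    return np.unique(np.column_stack([ix, iy]), axis=0)


def zonal_sum(raster: Raster, polygon) -> float:
    """Sum of values of cells whose centres fall in the polygon.

    Membership uses ``shapely covers`` (a centre exactly on the boundary
    counts as inside).  The polygon must be in the raster's coordinate
    system.
    """
    xs, ys = raster.spec.centers()
    xg, yg = np.meshgrid(xs, ys)
    # for points, intersects == covers (interior or boundary)
    inside = shapely.intersects_xy(polygon, xg.ravel(), yg.ravel())
    return float(np.nansum(raster.values.ravel()[inside]))


def write_ascii(raster: Raster, path, nodata=-9999.0):
    """Write as Esri ASCII grid (text).  NaN becomes the nodata value."""
    v = np.where(np.isnan(raster.values), nodata, raster.values)
    header = (
        f"ncols {raster.spec.nx}\n"
        f"nrows {raster.spec.ny}\n"
        f"xllcorner {raster.spec.x0!r}\n"
        f"yllcorner {raster.spec.y0!r}\n"
        f"cellsize {raster.spec.cell!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grid rows run north -> south
        np.savetxt(fh, v[::-1], fmt="%.10g")


def read_ascii(path) -> Raster:
    """Read an Esri ASCII grid; nodata cells become NaN."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    spec = GridSpec(
        header["xllcorner"],
        header["yllcorner"],
        header["cellsize"],
        int(header["ncols"]),
        int(header["nrows"]),
    )
    nodata = header.get("nodata_value")
    values = data[::-1]
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return Raster(spec, values)
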