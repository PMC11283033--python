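"""Introduction-pressure surface: planar kernel density of store points.

Propagule pressure is proxied by the spatial density of aquarium stores,
estimated with the quartic (biweight) kernel used by planar GIS density
tools:

    density(c) = sum_i 3/(pi h^2) * (1 - (d_i/h)^2)^2   for d_i < h,

in points per square meter, where d_i is the planar distance from cell
center c to point i (longitude degrees scaled by cos latitude) and h is the
bandwidth.  The finite kernel support makes total mass exactly the point
count when no point sits within h of the extent boundary.  The surface is
then linearly rescaled to [0, 1] before entering the risk product.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .rasters import GridHeader, M_PER_DEG, Raster

logger = logging.getLogger("invasionrisk")


def default_bandwidth_m(pts) -> float:
    """Silverman-style reference bandwidth for planar point patterns.

    h = 0.9 * min(SD, sqrt(1/ln 2) * Dm) * n^(-0.2), where SD is the
    standard distance of the pattern about its mean center and Dm the median
    distance to the mean center, both in meters (the default rule of the
    common GIS density tools, stated here explicitly so runs are
    reproducible).  Degenerate patterns (all points coincident) fall back to
    1000 m.
    """
    df = pts.to_frame()
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    mlat = M_PER_DEG
    mlon = M_PER_DEG * math.cos(math.radians(lat.mean()))
    x = (lon - lon.mean()) * mlon
    y = (lat - lat.mean()) * mlat
    d2 = x * x + y * y
    sd = math.sqrt(d2.mean())
    dm = float(np.median(np.sqrt(d2)))
    n = len(df)
    h = 0.9 * min(sd, math.sqrt(1.0 / math.log(2.0)) * dm) * n ** (-0.2)
    if not h > 0:
        h = 1000.0
    logger.info("kde: default bandwidth_m=%.1f (n=%d)", h, n)
    return h


def kernel_density(pts, grid: GridHeader, bandwidth_m: float | None = None) -> Raster:
    """Quartic-kernel density raster of a point set, in points per m^2."""
    df = pts.to_frame()
    if len(df) == 0:
        raise ValueError("kernel density of an empty point set is undefined")
    if bandwidth_m is None:
        bandwidth_m = default_bandwidth_m(pts)
    if bandwidth_m <= 0:
        raise ValueError(f"bandwidth_m must be > 0, got {bandwidth_m}")
    h = float(bandwidth_m)
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)

    out = np.zeros((grid.nrows, grid.ncols))
    lat_rows = grid.row_latitudes()
    col_lons = grid.xllcorner + (np.arange(grid.ncols) + 0.5) * grid.cellsize
    norm = 3.0 / (math.pi * h * h)
    for i in range(grid.nrows):
        mlon = M_PER_DEG * math.cos(math.radians(lat_rows[i]))
        dy = (lat_rows[i] - lat) * M_PER_DEG
        near = np.abs(dy) < h
        if not near.any():
            continue
        dx = (col_lons[:, None] - lon[None, near]) * mlon
        d2 = dx * dx + dy[near][None, :] ** 2
        u2 = d2 / (h * h)
        k = np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0)
        out[i] = norm * k.sum(axis=1)
    return Raster(values=out, header=grid, name="store_density")


def minmax_normalize(raster: Raster) -> Raster:
    """Linear [0, 1] rescale over valid cells; nodata preserved.

    A constant raster cannot be normalized and raises.
    """
    v = raster.values
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("raster has no valid cells")
    lo = float(np.nanmin(v))
    hi = float(np.nanmax(v))
    if hi == lo:
        raise ValueError(
            f"degenerate normalization: raster '{raster.name}' is constant ({lo})")
    out = (v - lo) / (hi - lo)
    return Raster(values=out, header=raster.header, name=f"{raster.name}_norm")
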