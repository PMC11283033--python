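"""Gridded surfaces and predictor preprocessing.

The raster model is deliberately minimal: single-band grids on a plain
geographic (longitude/latitude) coordinate system, exchanged as ESRI ASCII
grids.  Internally, nodata cells are represented as NaN; the header's nodata
sentinel is applied only at I/O time.

Conventions used throughout the package:

* Array row 0 is the *northernmost* row (file order of the ASCII format).
* Cells are half-open intervals ``[x0 + j*s, x0 + (j+1)*s)`` horizontally and
  ``[y0 + i*s, y0 + (i+1)*s)`` vertically, indexed row-major from the
  lower-left origin.  Points exactly on the top or right boundary of the
  extent belong to the last cell.
* Distances in meters use per-row scaling: one degree of latitude is
  ``M_PER_DEG`` meters and one degree of longitude is ``M_PER_DEG * cos(lat)``
  meters at the row's center latitude.  At the sub-kilometer radii used here
  the error versus full geodesics is negligible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("invasionrisk")

#: meters per degree of latitude (spherical earth, radius 6371 km)
M_PER_DEG = 111_194.93


class RasterError(ValueError):
    """Malformed raster, header, or grid-algebra argument."""


# ---------------------------------------------------------------------------
# Headers and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridHeader:
    """Georeferencing header of an ESRI ASCII grid.

    Parameters
    ----------
    ncols, nrows : int
        Grid dimensions.
    xllcorner, yllcorner : float
        Coordinates of the lower-left corner of the lower-left cell, in
        decimal degrees.
    cellsize : float
        Cell side length in decimal degrees (square cells).
    nodata : float
        Sentinel written for missing cells.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols <= 0 or self.nrows <= 0:
            raise RasterError(f"non-positive grid dimensions {self.nrows}x{self.ncols}")
        if not self.cellsize > 0:
            raise RasterError(f"cellsize must be > 0, got {self.cellsize}")

    # -- extent ------------------------------------------------------------
    @property
    def xmax(self) -> float:
        return self.xllcorner + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize

    def contains(self, lon, lat):
        """Vectorized point-in-extent test (closed on all boundaries)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.xllcorner) & (lon <= self.xmax)
            & (lat >= self.yllcorner) & (lat <= self.ymax)
        )

    def cell_of(self, lon, lat):
        """Map coordinates to (array_row, col) under the half-open convention.

        Points on the top/right extent boundary are clamped into the last
        cell.  Caller is responsible for dropping out-of-extent points.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        row_b = np.floor((lat - self.yllcorner) / self.cellsize).astype(int)
        col = np.clip(col, 0, self.ncols - 1)
        row_b = np.clip(row_b, 0, self.nrows - 1)
        return (self.nrows - 1 - row_b), col

    def cell_center(self, row, col):
        """Coordinates of the center of array cell (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (self.nrows - 1 - row + 0.5) * self.cellsize
        return lon, lat

    def row_latitudes(self) -> np.ndarray:
        """Center latitude of every array row (row 0 = northernmost)."""
        rows = np.arange(self.nrows)
        return self.yllcorner + (self.nrows - 1 - rows + 0.5) * self.cellsize


@dataclass
class Raster:
    """A single-band grid. ``values`` uses NaN for nodata internally."""

    values: np.ndarray
    header: GridHeader
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.header.nrows, self.header.ncols):
            raise RasterError(
                f"raster '{self.name}': shape {self.values.shape} does not match "
                f"header {self.header.nrows}x{self.header.ncols}"
            )

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "Raster":
        return Raster(values=np.asarray(values, dtype=float), header=self.header,
                      name=self.name if name is None else name)


@dataclass
class RasterStack:
    """Co-registered rasters keyed by variable name.

    A cell is jointly valid only if it carries data in every layer.
    """

    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        headers = {r.header for r in self.layers.values()}
        if len(headers) > 1:
            raise RasterError("stack layers do not share an identical header")

    @property
    def header(self) -> GridHeader:
        if not self.layers:
            raise RasterError("empty stack has no header")
        return next(iter(self.layers.values())).header

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def add(self, raster: Raster) -> None:
        if self.layers and raster.header != self.header:
            raise RasterError(f"layer '{raster.name}' header mismatch")
        self.layers[raster.name] = raster

    def valid_mask(self) -> np.ndarray:
        mask = np.ones((self.header.nrows, self.header.ncols), dtype=bool)
        for r in self.layers.values():
            mask &= r.valid
        return mask

    def subset(self, names) -> "RasterStack":
        return RasterStack({n: self.layers[n] for n in names})

    def table(self, rows, cols) -> pd.DataFrame:
        """Layer values at the given array cells, one column per layer."""
        return pd.DataFrame({n: r.values[rows, cols] for n, r in self.layers.items()})


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path, name: str | None = None) -> Raster:
    """Read an ESRI ASCII grid (.asc): six header lines, then rows of numbers.

    The first data row of the file is the northernmost row.  Malformed
    headers or row/column mismatches raise :class:`RasterError` naming the
    offending line.
    """
    path = str(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 7:
        raise RasterError(f"{path}: expected 6 header lines plus data")
    header_vals: dict[str, float] = {}
    for lineno, (key, line) in enumerate(zip(_HEADER_KEYS, lines), start=1):
        parts = line.split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise RasterError(f"{path}: line {lineno}: expected '{key} <value>', got {line!r}")
        try:
            header_vals[key] = float(parts[1])
        except ValueError as exc:
            raise RasterError(f"{path}: line {lineno}: non-numeric value {parts[1]!r}") from exc
    header = GridHeader(
        ncols=int(header_vals["ncols"]),
        nrows=int(header_vals["nrows"]),
        xllcorner=header_vals["xllcorner"],
        yllcorner=header_vals["yllcorner"],
        cellsize=header_vals["cellsize"],
        nodata=header_vals["nodata_value"],
    )
    data_lines = [ln for ln in lines[6:] if ln.strip()]
    if len(data_lines) != header.nrows:
        raise RasterError(
            f"{path}: expected {header.nrows} data rows, found {len(data_lines)}"
        )
    rows = []
    for i, ln in enumerate(data_lines):
        vals = ln.split()
        if len(vals) != header.ncols:
            raise RasterError(
                f"{path}: data line {i + 7}: expected {header.ncols} columns, found {len(vals)}"
            )
        rows.append([float(v) for v in vals])
    values = np.array(rows, dtype=float)
    values[values == header.nodata] = np.nan
    if name is None:
        import os
        name = os.path.splitext(os.path.basename(path))[0]
    return Raster(values=values, header=header, name=name)


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips through float()."""
    x = float(x)
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid; numbers printed at full round-trip precision."""
    h = raster.header
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = h.nodata
    with open(str(path), "w") as fh:
        fh.write(f"ncols {h.ncols}\n")
        fh.write(f"nrows {h.nrows}\n")
        fh.write(f"xllcorner {_fmt(h.xllcorner)}\n")
        fh.write(f"yllcorner {_fmt(h.yllcorner)}\n")
        fh.write(f"cellsize {_fmt(h.cellsize)}\n")
        fh.write(f"nodata_value {_fmt(h.nodata)}\n")
        for row in vals:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(raster: Raster, target: GridHeader, method: str = "bilinear") -> Raster:
    """Resample a raster onto a target grid.

    ``nearest`` and ``bilinear`` look up / interpolate from valid source
    cells only; ``mean-aggregate`` averages all source cells whose centers
    fall in each target cell and yields nodata if any contributor is nodata.
    """
    if method not in ("bilinear", "nearest", "mean-aggregate"):
        raise RasterError(f"unknown resampling method {method!r}")
    src = raster.header
    if (src.xmax <= target.xllcorner or target.xmax <= src.xllcorner
            or src.ymax <= target.yllcorner or target.ymax <= src.yllcorner):
        raise RasterError("source and target extents are disjoint")

    trows = np.arange(target.nrows)
    tcols = np.arange(target.ncols)
    cgrid, rgrid = np.meshgrid(tcols, trows)
    lon, lat = target.cell_center(rgrid, cgrid)

    out = np.full((target.nrows, target.ncols), np.nan)

    if method == "mean-aggregate":
        # bin source cell centers into target cells
        srows, scols = np.meshgrid(np.arange(src.nrows), np.arange(src.ncols),
                                   indexing="ij")
        slon, slat = src.cell_center(srows.ravel(), scols.ravel())
        inside = target.contains(slon, slat)
        tr, tc = target.cell_of(slon[inside], slat[inside])
        sval = raster.values[srows.ravel()[inside], scols.ravel()[inside]]
        flat = tr * target.ncols + tc
        sums = np.bincount(flat, weights=np.nan_to_num(sval), minlength=target.nrows * target.ncols)
        counts = np.bincount(flat, minlength=target.nrows * target.ncols)
        bad = np.bincount(flat, weights=(~np.isfinite(sval)).astype(float),
                          minlength=target.nrows * target.ncols)
        with np.errstate(invalid="ignore"):
            mean = sums / counts
        mean[(counts == 0) | (bad > 0)] = np.nan
        out = mean.reshape(target.nrows, target.ncols)
        return Raster(values=out, header=target, name=raster.name)

    inside = src.contains(lon, lat)
    if method == "nearest":
        sr, sc = src.cell_of(lon[inside], lat[inside])
        out[inside] = raster.values[sr, sc]
        return Raster(values=out, header=target, name=raster.name)

    # bilinear between the four surrounding source cell centers
    fx = (lon - (src.xllcorner + 0.5 * src.cellsize)) / src.cellsize
    fy = ((src.yllcorner + (src.nrows - 0.5) * src.cellsize) - lat) / src.cellsize
    x0 = np.clip(np.floor(fx).astype(int), 0, src.ncols - 1)
    y0 = np.clip(np.floor(fy).astype(int), 0, src.nrows - 1)
    x1 = np.clip(x0 + 1, 0, src.ncols - 1)
    y1 = np.clip(y0 + 1, 0, src.nrows - 1)
    wx = np.clip(fx - x0, 0.0, 1.0)
    wy = np.clip(fy - y0, 0.0, 1.0)
    corners = [
        (raster.values[y0, x0], (1 - wx) * (1 - wy)),
        (raster.values[y0, x1], wx * (1 - wy)),
        (raster.values[y1, x0], (1 - wx) * wy),
        (raster.values[y1, x1], wx * wy),
    ]
    num = np.zeros_like(out)
    den = np.zeros_like(out)
    for v, w in corners:
        ok = np.isfinite(v)
        num += np.where(ok, v * w, 0.0)
        den += np.where(ok, w, 0.0)
    with np.errstate(invalid="ignore"):
        interp = num / den
    interp[den == 0] = np.nan
    interp[~inside] = np.nan
    return Raster(values=interp, header=target, name=raster.name)


# ---------------------------------------------------------------------------
# Organic-soil reclassification and focal density
# ---------------------------------------------------------------------------

def organic_layer(percent: Raster, threshold: float = 50.0) -> Raster:
    """Binary organic-soil layer: 1 where organic-matter % >= threshold.

    The threshold is inclusive; nodata propagates.
    """
    if not 0.0 <= threshold <= 100.0:
        raise RasterError(f"threshold must be in [0, 100], got {threshold}")
    v = percent.values
    finite = np.isfinite(v)
    if np.any((v[finite] < 0) | (v[finite] > 100)):
        raise RasterError("organic percentage values outside [0, 100]")
    out = np.where(v >= threshold, 1.0, 0.0)
    out[~finite] = np.nan
    return Raster(values=out, header=percent.header, name=f"{percent.name}_organic")


def focal_density(binary: Raster, radius_m: float = 500.0) -> Raster:
    """Fraction of 1-cells among valid cells within a metric radius.

    Distances between cell centers are planar, with longitude degrees scaled
    by cos(latitude) of the evaluation row.  Cells with no valid neighbor
    (including themselves) become nodata.  Output is in [0, 1].
    """
    if radius_m <= 0:
        raise RasterError(f"radius_m must be > 0, got {radius_m}")
    v = binary.values
    finite = np.isfinite(v)
    uniq = np.unique(v[finite])
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise RasterError("focal_density expects a binary (0/1/nodata) raster")

    h = binary.header
    ones = np.where(finite, v, 0.0)
    valid = finite.astype(float)
    out = np.full_like(v, np.nan)
    lat_rows = h.row_latitudes()
    cs_lat_m = h.cellsize * M_PER_DEG
    dr_max = int(math.floor(radius_m / cs_lat_m))
    for i in range(h.nrows):
        cs_lon_m = h.cellsize * M_PER_DEG * math.cos(math.radians(lat_rows[i]))
        num = np.zeros(h.ncols)
        den = np.zeros(h.ncols)
        for di in range(-dr_max, dr_max + 1):
            ii = i + di
            if ii < 0 or ii >= h.nrows:
                continue
            dy = di * cs_lat_m
            rem = radius_m * radius_m - dy * dy
            if rem < 0:
                continue
            dc_max = int(math.floor(math.sqrt(rem) / cs_lon_m))
            for dj in range(-dc_max, dc_max + 1):
                lo, hi = max(0, -dj), min(h.ncols, h.ncols - dj)
                num[lo:hi] += ones[ii, lo + dj:hi + dj]
                den[lo:hi] += valid[ii, lo + dj:hi + dj]
        with np.errstate(invalid="ignore"):
            frac = num / den
        frac[den == 0] = np.nan
        frac[~finite[i]] = np.nan
        out[i] = frac
    return Raster(values=out, header=h, name=f"{binary.name}_density")


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def extract(stack: RasterStack, points) -> pd.DataFrame:
    """Look up layer values at point locations (cell-center indexing).

    ``points`` is anything with ``lon``/``lat`` columns (a DataFrame, an
    occurrence or point set with ``.to_frame()``).  Rows falling outside the
    extent or on any nodata layer are dropped; counts are logged, not raised.
    """
    if hasattr(points, "to_frame") and not isinstance(points, pd.DataFrame):
        df = points.to_frame()
    else:
        df = pd.DataFrame(points)
    h = stack.header
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    inside = h.contains(lon, lat)
    n_outside = int((~inside).sum())
    if n_outside:
        logger.info("extract: dropped points_outside_extent=%d", n_outside)
    rows, cols = h.cell_of(lon[inside], lat[inside])
    table = stack.table(rows, cols)
    table.insert(0, "lat", lat[inside])
    table.insert(0, "lon", lon[inside])
    table["_row"] = rows
    table["_col"] = cols
    layer_cols = stack.names
    ok = np.isfinite(table[layer_cols].to_numpy()).all(axis=1)
    n_nodata = int((~ok).sum())
    if n_nodata:
        logger.info("extract: dropped points_on_nodata=%d", n_nodata)
    return table.loc[ok].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Correlation-based variable pruning
# ---------------------------------------------------------------------------

def correlation_prune(stack: RasterStack, threshold: float = 0.7,
                      sample_n: int = 10_000, seed: int = 0):
    """Greedy removal of collinear predictors until max pairwise |r| <= threshold.

    Pearson correlations are computed over a seeded random sample of jointly
    valid cells (all of them if fewer than ``sample_n``).  While any pair
    exceeds the threshold (strictly), the member of the worst pair with the
    larger mean absolute correlation to the remaining variables is dropped;
    ties break alphabetically (the later name goes).  Returns the retained
    names in stack order and the full correlation matrix as a DataFrame.
    """
    names = stack.names
    if len(names) < 2:
        raise RasterError("correlation_prune needs at least 2 layers")
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    if rows.size < 10:
        raise RasterError(f"only {rows.size} jointly valid cells; need >= 10")
    rng = np.random.default_rng(seed)
    if rows.size > sample_n:
        idx = rng.choice(rows.size, size=sample_n, replace=False)
        rows, cols = rows[idx], cols[idx]
    data = np.column_stack([stack[n].values[rows, cols] for n in names])
    sd = data.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        for n in np.array(names)[zero_var]:
            logger.warning("correlation_prune: layer '%s' has zero variance in sample", n)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=names, columns=names)

    # removal triggers only strictly above the threshold; the tiny absolute
    # tolerance keeps a pair constructed at exactly the threshold from being
    # split by floating-point rounding of the correlation
    keep = list(names)
    while len(keep) > 1:
        sub = corr_df.loc[keep, keep].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= threshold + 1e-10:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        # mean |r| of each candidate against all other retained variables
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        if mean_i > mean_j:
            drop = keep[i]
        elif mean_j > mean_i:
            drop = keep[j]
        else:
            drop = max(keep[i], keep[j])  # alphabetical tie-break
        logger.info("correlation_prune: dropping '%s' (max |r|=%.3f)", drop, sub[i, j])
        keep.remove(drop)
    retained = [n for n in names if n in keep]
    return retained, corr_df
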