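"""Synthetic landscapes, occurrences, store points, and protected areas.

Everything downstream of raw data ingestion can be exercised on generated
inputs with known structure: spatially autocorrelated predictor fields, a
presence process that follows a known log-linear suitability surface,
clustered introduction points, and small named polygons.  All generators are
pure functions of their seed and arguments.

The generating suitability model is a Gibbs field over grid cells,

    eta(x) = intercept + sum_j beta_j * z_j(x),

where z_j is the j-th predictor standardized over the grid and a stated
fraction of the beta_j (default one half) is exactly zero, so that variable
pruning and permutation-importance machinery can be tested against known
irrelevant predictors.  Presences are sampled at cell resolution with
probability proportional to exp(eta), then jittered uniformly within the
cell; sub-cell position carries no signal, matching the analysis resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from .occurrences import OccurrenceSet
from .rasters import GridHeader, Raster, RasterStack

#: default fraction of generating coefficients that are exactly zero
NULL_FRACTION = 0.5


@dataclass
class LandscapeTruth:
    """The generating model of a synthetic landscape.

    ``true_coefficients[name]`` weights the standardized predictor ``name``
    in the log-linear suitability eta; predictors absent from the mapping
    (or with weight 0) are irrelevant by construction.
    """

    predictor_names: list[str]
    true_coefficients: np.ndarray
    intercept: float
    grid: GridHeader

    def __post_init__(self) -> None:
        self.true_coefficients = np.asarray(self.true_coefficients, dtype=float)
        if len(self.true_coefficients) != len(self.predictor_names):
            raise ValueError("one coefficient per predictor is required")
        if self.grid.nrows < 10 or self.grid.ncols < 10:
            raise ValueError("grid must be at least 10x10")

    def eta(self, stack: RasterStack) -> np.ndarray:
        """The true linear predictor over the grid (NaN where any layer is)."""
        out = np.full((self.grid.nrows, self.grid.ncols), self.intercept)
        for name, beta in zip(self.predictor_names, self.true_coefficients):
            v = stack[name].values
            z = (v - np.nanmean(v)) / np.nanstd(v)
            out = out + beta * z
        return out


def _smooth_field(rng: np.random.Generator, rows: int, cols: int,
                  autocorrelation_range: int) -> np.ndarray:
    """White noise smoothed by a square moving-average window, re-standardized.

    Window side = autocorrelation_range cells; a range of 1 is the identity
    (no spatial autocorrelation).
    """
    noise = rng.standard_normal((rows, cols))
    if autocorrelation_range > 1:
        noise = ndimage.uniform_filter(noise, size=autocorrelation_range,
                                       mode="reflect")
    sd = noise.std()
    return (noise - noise.mean()) / (sd if sd > 0 else 1.0)


def make_landscape(seed: int, rows: int = 50, cols: int = 50,
                   n_predictors: int = 4, autocorrelation_range: int = 5,
                   organic_band: bool = False,
                   null_fraction: float = NULL_FRACTION,
                   beta_scale: float = 1.5,
                   cellsize: float = 0.01,
                   origin: tuple[float, float] = (-9.0, 39.0)):
    """Generate co-registered predictor rasters plus the generating truth.

    The first two predictors are rescaled to a temperature-like band
    (mean 15 C, sd 5) and a precipitation-like band (mean 800 mm, sd 250,
    floored at 0); the rest stay standardized.  Coefficients are drawn with
    |beta| in [0.5, 1] * beta_scale and sign +/- at random, then a
    ``null_fraction`` of them (rounded down, chosen at random) is zeroed.

    Returns ``(stack, truth)``.
    """
    if rows < 10 or cols < 10:
        raise ValueError("rows and cols must be >= 10")
    if n_predictors < 2:
        raise ValueError("n_predictors must be >= 2")
    if autocorrelation_range < 1:
        raise ValueError("autocorrelation_range must be >= 1")
    rng = np.random.default_rng(seed)
    header = GridHeader(ncols=cols, nrows=rows, xllcorner=origin[0],
                        yllcorner=origin[1], cellsize=cellsize)

    stack = RasterStack()
    names = []
    for j in range(n_predictors):
        z = _smooth_field(rng, rows, cols, autocorrelation_range)
        if j == 0:
            name, vals = "temp_warmest", 15.0 + 5.0 * z
        elif j == 1:
            name, vals = "precip_annual", np.maximum(800.0 + 250.0 * z, 0.0)
        else:
            name, vals = f"env_{j}", z
        names.append(name)
        stack.add(Raster(values=vals, header=header, name=name))

    if organic_band:
        z = _smooth_field(rng, rows, cols, autocorrelation_range)
        organic = 100.0 / (1.0 + np.exp(-1.5 * z))
        stack.add(Raster(values=organic, header=header, name="organic_pct"))

    betas = rng.uniform(0.5, 1.0, size=n_predictors) * beta_scale
    betas *= rng.choice([-1.0, 1.0], size=n_predictors)
    n_null = int(np.floor(null_fraction * n_predictors))
    if n_null > 0:
        null_idx = rng.choice(n_predictors, size=n_null, replace=False)
        betas[null_idx] = 0.0
    truth = LandscapeTruth(predictor_names=names, true_coefficients=betas,
                           intercept=0.0, grid=header)
    return stack, truth


def sample_occurrences(truth: LandscapeTruth, stack: RasterStack,
                       n_presence: int, seed: int,
                       year_range: tuple[int, int] = (1995, 2023),
                       uncertainty_range_m: tuple[float, float] = (10.0, 30_000.0)
                       ) -> OccurrenceSet:
    """Sample presences from the Gibbs field exp(eta) over valid cells.

    Cells are drawn with replacement with probability proportional to
    exp(eta), then each record gets a uniform jitter inside its cell.  Years
    and coordinate uncertainties are drawn log-uniformly over ranges that
    deliberately extend below/above the default cleaning cutoffs, so the
    cleaning stage has realistic work to do.
    """
    if n_presence < 1:
        raise ValueError("n_presence must be >= 1")
    grid = truth.grid
    if stack.header != grid:
        raise ValueError("stack grid does not match the truth grid")
    eta = truth.eta(stack)
    valid = stack.valid_mask() & np.isfinite(eta)
    if not valid.any():
        raise ValueError("all cells are nodata; cannot sample presences")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(valid)
    w = np.exp(eta[rows, cols] - eta[rows, cols].max())
    p = w / w.sum()
    draws = rng.choice(rows.size, size=n_presence, replace=True, p=p)
    r, c = rows[draws], cols[draws]
    lon0 = grid.xllcorner + c * grid.cellsize
    lat0 = grid.yllcorner + (grid.nrows - 1 - r) * grid.cellsize
    lon = lon0 + rng.uniform(0, grid.cellsize, size=n_presence)
    lat = lat0 + rng.uniform(0, grid.cellsize, size=n_presence)
    years = rng.integers(year_range[0], year_range[1] + 1, size=n_presence)
    lo, hi = uncertainty_range_m
    unc = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_presence))
    df = pd.DataFrame({
        "id": [f"occ_{i}" for i in range(n_presence)],
        "lon": lon, "lat": lat, "year": years,
        "coord_uncertainty_m": np.round(unc, 1),
    })
    occ = OccurrenceSet(records=df)
    occ.log("simulated", n_presence, 0)
    return occ


@dataclass
class PointSet:
    """Introduction points (aquarium stores): plain (lon, lat) with names."""

    points: pd.DataFrame  # columns: name, lon, lat

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.points)
        if "name" not in df.columns:
            df.insert(0, "name", [f"pt_{i}" for i in range(len(df))])
        self.points = df[["name", "lon", "lat"]].reset_index(drop=True)
        coords = self.points[["lon", "lat"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("non-finite point coordinates")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return self.points.copy()


def read_points(path, sep: str = ",") -> PointSet:
    return PointSet(points=pd.read_csv(path, sep=sep))


def write_points(pts: PointSet, path, sep: str = ",") -> None:
    pts.points.to_csv(path, sep=sep, index=False)


def sample_stores(n_points: int, n_clusters: int, cluster_sd: float,
                  grid: GridHeader, seed: int) -> PointSet:
    """Gaussian-cluster point pattern inside the grid extent.

    Cluster centers are uniform over the extent; each point is assigned a
    cluster uniformly and displaced by isotropic Gaussian noise with the
    given sd (degrees).  Points landing outside the extent are resampled.
    """
    if n_points < 1 or n_clusters < 1:
        raise ValueError("n_points and n_clusters must be >= 1")
    if cluster_sd <= 0:
        raise ValueError("cluster_sd must be > 0")
    rng = np.random.default_rng(seed)
    cx = rng.uniform(grid.xllcorner, grid.xmax, size=n_clusters)
    cy = rng.uniform(grid.yllcorner, grid.ymax, size=n_clusters)
    lon = np.empty(n_points)
    lat = np.empty(n_points)
    for i in range(n_points):
        k = int(rng.integers(n_clusters))
        while True:
            x = cx[k] + rng.normal(0, cluster_sd)
            y = cy[k] + rng.normal(0, cluster_sd)
            if grid.contains(x, y):
                lon[i], lat[i] = x, y
                break
    df = pd.DataFrame({"name": [f"store_{i}" for i in range(n_points)],
                       "lon": lon, "lat": lat})
    return PointSet(points=df)


@dataclass
class ProtectedArea:
    name: str
    designation: str  # RNAP | RN2000 | other
    geometry: Polygon


def make_protected_areas(grid: GridHeader, n_polygons: int, seed: int,
                         min_cells: int = 4) -> list[ProtectedArea]:
    """Random axis-aligned rectangles inside the extent, each >= min_cells cells.

    Designations alternate RNAP / RN2000 so zonal reports exercise both tags.
    """
    if n_polygons < 1:
        raise ValueError("n_polygons must be >= 1")
    rng = np.random.default_rng(seed)
    cs = grid.cellsize
    areas = []
    for i in range(n_polygons):
        w_cells = int(rng.integers(2, max(3, grid.ncols // 3)))
        h_cells = int(rng.integers(max(2, min_cells // w_cells + 1),
                                   max(3, grid.nrows // 3)))
        x0 = grid.xllcorner + float(rng.integers(0, grid.ncols - w_cells + 1)) * cs
        y0 = grid.yllcorner + float(rng.integers(0, grid.nrows - h_cells + 1)) * cs
        poly = Polygon([(x0, y0), (x0 + w_cells * cs, y0),
                        (x0 + w_cells * cs, y0 + h_cells * cs),
                        (x0, y0 + h_cells * cs)])
        areas.append(ProtectedArea(
            name=f"PA_{i + 1}",
            designation="RNAP" if i % 2 == 0 else "RN2000",
            geometry=poly,
        ))
    return areas
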