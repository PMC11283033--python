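"""Occurrence-record cleaning and one-per-cell spatial thinning.

Raw presence records (GBIF-style rows with coordinates, observation year and
a coordinate-uncertainty radius in meters) are filtered for usability and
then thinned so that at most one record remains per grid cell, which reduces
the effect of spatially uneven sampling effort on the suitability model.
Every filter appends a count to the set's provenance trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import GridHeader, RasterError

logger = logging.getLogger("invasionrisk")

COLUMNS = ["id", "lon", "lat", "year", "coord_uncertainty_m"]


@dataclass
class OccurrenceSet:
    """An ordered table of presence records plus an audit trail.

    ``records`` is a DataFrame with columns id, lon, lat, year,
    coord_uncertainty_m (year and uncertainty may be missing).  ``provenance``
    is a list of "step: kept=<k> removed=<r>" strings.
    """

    records: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.records = df[COLUMNS].reset_index(drop=True)
        lon = self.records["lon"]
        lat = self.records["lat"]
        if ((lon.dropna().abs() > 180).any()) or ((lat.dropna().abs() > 90).any()):
            raise ValueError("coordinates outside [-180,180] x [-90,90]")
        unc = self.records["coord_uncertainty_m"].dropna()
        if (unc < 0).any():
            raise ValueError("negative coordinate uncertainty")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()

    def log(self, step: str, kept: int, removed: int) -> None:
        entry = f"{step}: kept={kept} removed={removed}"
        self.provenance.append(entry)
        logger.info("occurrences %s", entry)


def read_occurrences(path, sep: str = ",") -> OccurrenceSet:
    """Read a delimited text table with the GBIF-style columns."""
    df = pd.read_csv(path, sep=sep)
    return OccurrenceSet(records=df)


def write_occurrences(occ: OccurrenceSet, path, sep: str = ",") -> None:
    occ.records.to_csv(path, sep=sep, index=False)


def clean_records(raw: OccurrenceSet, min_year: int = 2000,
                  max_uncertainty_m: float = 10_000.0) -> OccurrenceSet:
    """Apply the record-usability filters, in a fixed order.

    Removes, in sequence: records missing either coordinate; records dated
    before ``min_year`` (records with no year are kept); records whose
    coordinate uncertainty exceeds ``max_uncertainty_m`` (missing uncertainty
    is kept); exact duplicates on (lon, lat), keeping the first.  Each step's
    removal count is recorded in the provenance.  An empty result is legal.
    """
    df = raw.records
    out = OccurrenceSet(records=df, provenance=list(raw.provenance))

    n0 = len(df)
    df = df[df["lon"].notna() & df["lat"].notna()]
    out.log("missing_coordinates", len(df), n0 - len(df))

    n0 = len(df)
    year = pd.to_numeric(df["year"], errors="coerce")
    df = df[year.isna() | (year >= min_year)]
    out.log(f"year_before_{min_year}", len(df), n0 - len(df))

    n0 = len(df)
    unc = pd.to_numeric(df["coord_uncertainty_m"], errors="coerce")
    df = df[unc.isna() | (unc <= max_uncertainty_m)]
    out.log("coordinate_uncertainty", len(df), n0 - len(df))

    n0 = len(df)
    df = df.drop_duplicates(subset=["lon", "lat"], keep="first")
    out.log("duplicate_coordinates", len(df), n0 - len(df))

    out.records = df.reset_index(drop=True)
    return out


def thin_to_grid(recs: OccurrenceSet, grid: GridHeader, seed: int = 0) -> OccurrenceSet:
    """Retain one uniformly chosen record per occupied grid cell.

    Records outside the grid extent are dropped first (count logged).  The
    survivor of each cell is chosen by a seeded RNG; output rows are ordered
    by row-major cell index from the lower-left origin, so the result is a
    deterministic function of the input set and the seed.
    """
    if not grid.cellsize > 0:
        raise RasterError("grid cellsize must be positive")
    df = recs.records
    out = OccurrenceSet(records=df, provenance=list(recs.provenance))

    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    inside = grid.contains(lon, lat)
    n_dropped = int((~inside).sum())
    df = df[inside].reset_index(drop=True)
    out.log("outside_extent", len(df), n_dropped)

    rows, cols = grid.cell_of(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
    # row-major index from the lower-left origin
    cell_idx = (grid.nrows - 1 - rows) * grid.ncols + cols

    rng = np.random.default_rng(seed)
    chosen: dict[int, int] = {}
    # reservoir-free selection: group positions per cell, draw one uniformly.
    order = np.argsort(cell_idx, kind="stable")
    sorted_cells = cell_idx[order]
    start = 0
    for end in range(1, len(order) + 1):
        if end == len(order) or sorted_cells[end] != sorted_cells[start]:
            group = order[start:end]
            chosen[int(sorted_cells[start])] = int(rng.choice(group))
            start = end
    keep_pos = [chosen[c] for c in sorted(chosen)]
    n0 = len(df)
    out.records = df.iloc[keep_pos].reset_index(drop=True)
    out.log("thin_one_per_cell", len(out.records), n0 - len(out.records))
    return out
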