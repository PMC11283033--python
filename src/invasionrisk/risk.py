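"""Invasion-risk surface and zonal summaries over protected areas.

Risk is the cellwise product of environmental suitability and normalized
introduction pressure, both in [0, 1]; the product is therefore bounded by
each factor and is 0 wherever either component vanishes.  Zonal summaries
assign a cell to a polygon iff the cell center lies inside it (even-odd
rule), the raster-GIS convention.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .rasters import Raster, RasterError
from .synthetic import ProtectedArea


def combine(suitability: Raster, pressure: Raster) -> Raster:
    """Cellwise suitability x pressure; nodata if either input is nodata."""
    if suitability.header != pressure.header:
        raise RasterError("suitability and pressure rasters have different headers")
    for r in (suitability, pressure):
        v = r.values[np.isfinite(r.values)]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise RasterError(f"raster '{r.name}' has values outside [0, 1]")
    out = suitability.values * pressure.values
    return Raster(values=out, header=suitability.header, name="invasion_risk")


def zonal_summary(risk: Raster, zones: list[ProtectedArea],
                  hotspot_threshold: float = 0.5) -> pd.DataFrame:
    """Per-polygon mean, max, hotspot fraction and valid-cell count.

    The hotspot fraction is the share of a polygon's valid cells whose risk
    is >= the threshold.  Polygons covering no valid cell are kept in the
    report with ``no_cells = True`` rather than dropped.
    """
    if not zones:
        raise ValueError("empty polygon set")
    h = risk.header
    rows, cols = np.meshgrid(np.arange(h.nrows), np.arange(h.ncols), indexing="ij")
    lon, lat = h.cell_center(rows.ravel(), cols.ravel())
    vals = risk.values.ravel()

    records = []
    for pa in zones:
        inside = shapely.contains_xy(pa.geometry, lon, lat)
        zvals = vals[inside]
        zvals = zvals[np.isfinite(zvals)]
        if zvals.size == 0:
            records.append({"name": pa.name, "designation": pa.designation,
                            "mean_risk": np.nan, "max_risk": np.nan,
                            "hotspot_fraction": np.nan, "cell_count": 0,
                            "no_cells": True})
        else:
            records.append({
                "name": pa.name, "designation": pa.designation,
                "mean_risk": float(zvals.mean()),
                "max_risk": float(zvals.max()),
                "hotspot_fraction": float((zvals >= hotspot_threshold).mean()),
                "cell_count": int(zvals.size),
                "no_cells": False,
            })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Polygon I/O (GeoJSON)
# ---------------------------------------------------------------------------

def write_protected_areas(zones: list[ProtectedArea], path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature",
             "properties": {"name": pa.name, "designation": pa.designation},
             "geometry": mapping(pa.geometry)}
            for pa in zones
        ],
    }
    with open(str(path), "w") as fh:
        json.dump(doc, fh, indent=1)


def read_protected_areas(path) -> list[ProtectedArea]:
    with open(str(path)) as fh:
        doc = json.load(fh)
    zones = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        zones.append(ProtectedArea(
            name=props.get("name", f"zone_{len(zones)}"),
            designation=props.get("designation", "other"),
            geometry=shape(feat["geometry"]),
        ))
    names = [z.name for z in zones]
    if len(set(names)) != len(names):
        raise ValueError("polygon names are not unique")
    return zones
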