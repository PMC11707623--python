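"""Pipeline artifact I/O.

Formats are deliberately plain text: telemetry/labels/coefficients as
CSV, utilization distributions as ESRI ASCII grids, contour regions and
MCPs as GeoJSON.  Coordinates must already be planar meters (a projected
CRS); geographic latitude/longitude input is rejected rather than
silently projected, because kernel bandwidths are metric.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .data import COLUMNS, COVARIATES, TelemetryDataset, ValidationError
from .grid import GridSpec
from .utilization import CellSet, UDRaster


class SchemaError(ValueError):
    pass


class ContractError(ValueError):
    pass


# ---------------------------------------------------------------------------
# telemetry CSV

def read_telemetry(path, schema: dict | None = None) -> TelemetryDataset:
    """Read a telemetry CSV.

    ``schema`` optionally maps required column names to the file's column
    names.  Rows with missing coordinates or covariates are rejected and
    reported on the returned dataset's ``rejected`` frame; out-of-range
    covariates or unknown reproductive classes are validation errors.
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    raw = raw[list(COLUMNS)].copy()
    raw["timestamp"] = pd.to_datetime(raw["timestamp"])
    essential = ["x", "y", *COVARIATES]
    bad = raw[essential].isna().any(axis=1)
    rejected = raw[bad].copy()
    if len(rejected):
        rejected["reason"] = "missing coordinates or covariates"
    kept = raw[~bad].reset_index(drop=True)
    xy = kept[["x", "y"]].to_numpy(float)
    if np.all(np.abs(xy[:, 0]) <= 180) and np.all(np.abs(xy[:, 1]) <= 90) \
            and len(kept) > 1 and np.ptp(xy, axis=0).max() < 10:
        raise ValidationError(
            "coordinates look like geographic lat/lon degrees; "
            "supply planar meters (projected CRS)")
    return TelemetryDataset(obs=kept, rejected=rejected)


def write_telemetry(data: TelemetryDataset, path) -> None:
    data.obs.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid

def write_ascii_grid(grid: GridSpec, values: np.ndarray, path) -> None:
    """Write any gridded surface as an ESRI ASCII grid; NaN -> NODATA.

    Values go out at full double precision so a read-back reproduces them
    to < 1e-10.
    """
    nodata = -9999.0
    vals = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n"
                 f"nrows {grid.nrows}\n"
                 f"xllcorner {grid.x0!r}\n"
                 f"yllcorner {grid.y0!r}\n"
                 f"cellsize {grid.cellsize!r}\n"
                 f"NODATA_value {nodata!r}\n")
        for i in range(grid.nrows - 1, -1, -1):  # ASCII rows run north->south
            fh.write(" ".join(repr(float(v)) for v in vals[i]) + "\n")


def write_raster(ud: UDRaster, path) -> None:
    """Write a normalized UD as an ESRI ASCII grid (density per m^2)."""
    if not ud.is_normalized(tol=1e-6):
        raise ContractError("refusing to write an unnormalized UD raster")
    write_ascii_grid(ud.grid, ud.density, path)


def read_raster(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid back into (GridSpec, density); NODATA -> NaN."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        rows = [np.fromstring(line, sep=" ") for line in fh if line.strip()]
    dens = np.vstack(rows)[::-1]                 # back to row 0 = south
    nodata = header.get("nodata_value", -9999.0)
    dens = np.where(dens == nodata, np.nan, dens)
    grid = GridSpec(x0=header["xllcorner"], y0=header["yllcorner"],
                    cellsize=header["cellsize"], nrows=int(header["nrows"]),
                    ncols=int(header["ncols"]))
    if dens.shape != grid.shape:
        raise SchemaError("grid body does not match header dimensions")
    return grid, dens


# ---------------------------------------------------------------------------
# GeoJSON regions

def region_geometry(cells: CellSet):
    """Union of the member cells' squares as a shapely (Multi)Polygon."""
    if len(cells.members) == 0:
        raise ContractError("empty cell set has no region geometry")
    g = cells.grid
    rows, cols = np.unravel_index(np.sort(cells.members), g.shape)
    squares = [box(g.x0 + c * g.cellsize, g.y0 + r * g.cellsize,
                   g.x0 + (c + 1) * g.cellsize, g.y0 + (r + 1) * g.cellsize)
               for r, c in zip(rows, cols)]
    return unary_union(squares)


def write_region(cells: CellSet, path, properties: dict | None = None) -> None:
    """Write a cell set as a single-feature GeoJSON (dataset CRS units)."""
    geom = region_geometry(cells)
    feature = {"type": "Feature",
               "properties": {"isopleth": cells.isopleth,
                              "area_m2": cells.area,
                              **(properties or {})},
               "geometry": mapping(geom)}
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def read_region(path):
    """Read the first feature's geometry of a GeoJSON file (shapely)."""
    with open(path) as fh:
        doc = json.load(fh)
    return shape(doc["features"][0]["geometry"])


def write_mcp_geojson(polys: dict, path) -> None:
    """All season MCPs as one GeoJSON FeatureCollection."""
    features = []
    for (animal, season), poly in polys.items():
        features.append({
            "type": "Feature",
            "properties": {"animal_id": animal, "season_id": season,
                           "percent": poly.percent, "area_m2": poly.area},
            "geometry": mapping(poly.polygon())})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
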