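"""Plain-text I/O: GeoJSON crowns, ESRI ASCII grid rasters, CSV tables.

Crowns travel as a GeoJSON FeatureCollection of circular polygons with
``id`` and ``crown_area_m2`` properties (plus any estimate columns);
rasters as single-band ESRI ASCII grids (mm yr⁻¹ for rainfall, Mg C ha⁻¹
for density); destructive-sampling sets and image catalogs as CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .allometry import AllometricComponentModel, FieldSampleSet, COMPONENTS
from .geo import RainfallField, NODATA

__all__ = [
    "crowns_to_geojson",
    "write_crowns_geojson",
    "read_crowns_geojson",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_field_samples_csv",
    "read_field_samples_csv",
    "write_models_json",
    "read_models_json",
]

_CROWN_PROPERTY_COLUMNS = (
    "rainfall", "zone", "mass_w_kg", "mass_f_kg", "mass_r_kg",
    "mass_total_kg", "carbon_kg",
)


def _circle_coords(x: float, y: float, area: float, n_seg: int = 32) -> list:
    # tolerate malformed areas so invalid inputs can still be serialised
    # for the validator to diagnose
    r = math.sqrt(max(area, 0.0) / math.pi)
    ang = np.linspace(0.0, 2.0 * math.pi, n_seg + 1)
    xs = np.round(x + r * np.cos(ang), 3)
    ys = np.round(y + r * np.sin(ang), 3)
    xs[-1], ys[-1] = xs[0], ys[0]
    return [[float(a), float(b)] for a, b in zip(xs, ys)]


def crowns_to_geojson(crowns: pd.DataFrame) -> dict:
    """Crown table → GeoJSON FeatureCollection (circular polygon geometry)."""
    features = []
    for row in crowns.itertuples():
        props = {"id": int(row.id), "crown_area_m2": float(row.crown_area_m2)}
        for col in _CROWN_PROPERTY_COLUMNS:
            if hasattr(row, col):
                v = getattr(row, col)
                props[col] = v if isinstance(v, str) else (
                    None if v is None or (isinstance(v, float) and math.isnan(v))
                    else float(v)
                )
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [_circle_coords(row.x, row.y, row.crown_area_m2)],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_crowns_geojson(crowns: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(crowns_to_geojson(crowns), sort_keys=True, separators=(",", ":"))
    )


def read_crowns_geojson(path: str | Path) -> pd.DataFrame:
    """GeoJSON FeatureCollection → crown table (centroid from geometry)."""
    fc = json.loads(Path(path).read_text())
    rows = []
    for feat in fc.get("features", []):
        props = dict(feat.get("properties", {}))
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        # shoelace centroid of the polygon ring (closed)
        x, y = ring[:-1, 0], ring[:-1, 1]
        rows.append({"x": float(x.mean()), "y": float(y.mean()), **props})
    df = pd.DataFrame(rows)
    if len(df):
        df["id"] = df["id"].astype(int)
    return df


def write_ascii_grid(
    grid: np.ndarray, x_origin: float, y_origin: float, cell_size: float,
    path: str | Path, nodata: float = NODATA,
) -> None:
    """Write a north-up grid (top-left origin) as an ESRI ASCII raster."""
    grid = np.asarray(grid, dtype=float)
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {x_origin:.6f}\nyllcorner {y_origin - nrows * cell_size:.6f}\n"
        f"cellsize {cell_size:.6f}\nNODATA_value {nodata:.6f}\n"
    )
    body = "\n".join(" ".join(f"{v:.10f}" for v in row) for row in grid)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> RainfallField:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    grid = np.loadtxt(lines[i:])
    grid = np.atleast_2d(grid)
    nrows, cs = int(hdr["nrows"]), hdr["cellsize"]
    return RainfallField(
        grid=grid,
        x_origin=hdr["xllcorner"],
        y_origin=hdr["yllcorner"] + nrows * cs,
        cell_size=cs,
        nodata=hdr.get("nodata_value", NODATA),
    )


def write_field_samples_csv(
    samples: Mapping[str, FieldSampleSet], path: str | Path
) -> None:
    frames = [
        pd.DataFrame(
            {"component": s.component, "crown_area_m2": s.areas, "mass_kg": s.masses}
        )
        for s in samples.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_field_samples_csv(path: str | Path) -> dict[str, FieldSampleSet]:
    df = pd.read_csv(path)
    out = {}
    for comp, grp in df.groupby("component"):
        out[str(comp)] = FieldSampleSet(
            str(comp),
            grp["crown_area_m2"].to_numpy(dtype=float),
            grp["mass_kg"].to_numpy(dtype=float),
        )
    return out


def write_models_json(
    models: Mapping[str, AllometricComponentModel], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps({c: asdict(m) for c, m in models.items()}, indent=2, sort_keys=True)
    )


def read_models_json(path: str | Path) -> dict[str, AllometricComponentModel]:
    raw = json.loads(Path(path).read_text())
    return {c: AllometricComponentModel(**d) for c, d in raw.items()}
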