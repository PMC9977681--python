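"""Rainfall processing, zone classification and carbon aggregation.

The study domain is stratified by mean annual precipitation into four
zones — hyper-arid [0, 150), arid [150, 300), semi-arid [300, 600) and dry
sub-humid [600, 1000] mm yr⁻¹ — with rainfall above 1000 mm yr⁻¹ masked as
out of domain.  Per-tree carbon stocks are aggregated to per-hectare
density grids (trees assigned to cells by centroid) and to per-zone
summaries: mean stock per tree, carbon density in Mg C ha⁻¹, per-tree
percentiles and each zone's share of the total carbon.

Rasters are plain row-major grids with a north-up geotransform: ``x_origin``
/ ``y_origin`` give the top-left corner, ``cell_size`` the square cell edge
in the (metric) CRS of the crowns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RainfallField",
    "ZoneDefinition",
    "DEFAULT_ZONES",
    "ZoneSummary",
    "OUT_OF_DOMAIN",
    "mean_annual_rainfall",
    "extract_rainfall",
    "classify_zone",
    "classify_zones",
    "carbon_density_grid",
    "zonal_summary",
    "percentile_profile",
]

logger = logging.getLogger(__name__)

NODATA = -9999.0

#: Zone label for rainfall beyond the study domain's upper bound.
OUT_OF_DOMAIN = "out-of-domain"


@dataclass
class RainfallField:
    """Gridded mean annual precipitation (mm yr⁻¹) with a geotransform."""

    grid: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("rainfall grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        valid = self.grid != self.nodata
        if np.any(self.grid[valid] < 0):
            raise ValueError("rainfall values must be >= 0 or nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        nrows, ncols = self.grid.shape
        return (
            self.x_origin,
            self.y_origin - nrows * self.cell_size,
            self.x_origin + ncols * self.cell_size,
            self.y_origin,
        )


@dataclass(frozen=True)
class ZoneDefinition:
    """Ordered rainfall zones as half-open intervals, upper bound inclusive.

    The printed zone limits share endpoints (0–150, 150–300, ...); the
    convention here is half-open ``[lo, hi)`` intervals with the final upper
    bound (the study domain limit) inclusive.  Rainfall beyond the last
    bound is :data:`OUT_OF_DOMAIN`.
    """

    names: tuple[str, ...] = ("hyper-arid", "arid", "semi-arid", "sub-humid")
    bounds: tuple[float, ...] = (0.0, 150.0, 300.0, 600.0, 1000.0)

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.names) + 1:
            raise ValueError("need len(names)+1 bounds")
        if any(b2 <= b1 for b1, b2 in zip(self.bounds, self.bounds[1:])):
            raise ValueError("zone bounds must be strictly increasing")

    @property
    def upper_limit(self) -> float:
        return self.bounds[-1]


DEFAULT_ZONES = ZoneDefinition()


@dataclass
class ZoneSummary:
    """Aggregate statistics for one rainfall zone."""

    zone: str
    n_trees: int
    mean_carbon_kg: float
    carbon_density_mg_ha: float
    total_carbon_kg: float
    carbon_share_pct: float
    mean_crown_area_m2: float
    land_area_ha: float
    carbon_percentiles_kg: dict[int, float] = field(default_factory=dict)


def mean_annual_rainfall(
    stack: np.ndarray | Sequence[np.ndarray],
    monthly: bool = False,
    nodata: float = NODATA,
) -> np.ndarray:
    """Mean annual precipitation grid from a multi-year stack.

    ``stack`` has shape ``(n_grids, rows, cols)``: annual totals if
    ``monthly`` is False, otherwise consecutive monthly grids that must
    cover whole years (12 per year).  Monthly grids are summed to annual
    totals first, then averaged across years.  Cells that are nodata in any
    input stay nodata.
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("stack must be (n, rows, cols) with n >= 1")
    bad = np.any(arr == nodata, axis=0)
    if monthly:
        if arr.shape[0] % 12:
            missing = 12 - arr.shape[0] % 12
            raise ValueError(
                f"incomplete final year: {arr.shape[0] % 12} months present, "
                f"{missing} missing"
            )
        arr = arr.reshape(arr.shape[0] // 12, 12, *arr.shape[1:]).sum(axis=1)
    out = arr.mean(axis=0)
    out[bad] = nodata
    return out


def extract_rainfall(
    rainfall: RainfallField, points: Sequence[tuple[float, float]] | np.ndarray
) -> np.ndarray:
    """Bilinear rainfall at each (x, y) point, interpolating cell centres.

    Points outside the raster rectangle get the nodata sentinel, as does any
    point whose four surrounding cell centres include a nodata cell.  Points
    between the boundary and the outermost cell centres are clamped to the
    edge centres (constant extrapolation over that half-cell fringe).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    grid, cs = rainfall.grid, rainfall.cell_size
    nrows, ncols = grid.shape
    xmin, ymin, xmax, ymax = rainfall.bounds

    out = np.full(pts.shape[0], rainfall.nodata)
    inside = (
        (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
        & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
    )
    if not np.any(inside):
        return out

    # fractional position in cell-centre coordinates
    cx = (pts[inside, 0] - rainfall.x_origin) / cs - 0.5
    cy = (rainfall.y_origin - pts[inside, 1]) / cs - 0.5
    cx = np.clip(cx, 0, ncols - 1)
    cy = np.clip(cy, 0, nrows - 1)
    c0 = np.floor(cx).astype(int)
    r0 = np.floor(cy).astype(int)
    c1 = np.minimum(c0 + 1, ncols - 1)
    r1 = np.minimum(r0 + 1, nrows - 1)
    fx = cx - c0
    fy = cy - r0

    q = (
        grid[r0, c0] * (1 - fx) * (1 - fy)
        + grid[r0, c1] * fx * (1 - fy)
        + grid[r1, c0] * (1 - fx) * fy
        + grid[r1, c1] * fx * fy
    )
    any_nodata = (
        (grid[r0, c0] == rainfall.nodata) | (grid[r0, c1] == rainfall.nodata)
        | (grid[r1, c0] == rainfall.nodata) | (grid[r1, c1] == rainfall.nodata)
    )
    q[any_nodata] = rainfall.nodata
    out[inside] = q
    n_out = int((~inside).sum())
    if n_out:
        logger.info("%d points outside rainfall raster bounds -> nodata", n_out)
    return out


def classify_zone(p: float, zones: ZoneDefinition = DEFAULT_ZONES) -> str:
    """Zone name for one rainfall value; OUT_OF_DOMAIN above the study limit."""
    if p < 0:
        raise ValueError("rainfall must be non-negative")
    if p > zones.upper_limit:
        return OUT_OF_DOMAIN
    if p == zones.upper_limit:  # domain limit is inclusive
        return zones.names[-1]
    i = np.searchsorted(zones.bounds, p, side="right") - 1
    return zones.names[int(i)]


def classify_zones(p: np.ndarray, zones: ZoneDefinition = DEFAULT_ZONES) -> np.ndarray:
    """Vectorised :func:`classify_zone`; nodata-safe (nodata → OUT_OF_DOMAIN)."""
    p = np.asarray(p, dtype=float)
    if np.any(p[p != NODATA] < 0):
        raise ValueError("rainfall must be non-negative")
    idx = np.searchsorted(zones.bounds, p, side="right") - 1
    idx = np.where(p == zones.upper_limit, len(zones.names) - 1, idx)
    names = np.array(list(zones.names) + [OUT_OF_DOMAIN], dtype=object)
    out = names[np.clip(idx, 0, len(zones.names))]
    out = np.where((p > zones.upper_limit) | (p == NODATA) | (p < 0), OUT_OF_DOMAIN, out)
    return out


def carbon_density_grid(
    crowns: pd.DataFrame,
    bounds: tuple[float, float, float, float],
    cell_size: float = 100.0,
    carbon_column: str = "carbon_kg",
) -> tuple[np.ndarray, float, float]:
    """Carbon density raster (Mg C ha⁻¹) over ``bounds`` at ``cell_size`` m.

    Trees are assigned to cells by centroid; each cell's value is the summed
    carbon (kg) converted to Mg and divided by the cell area in hectares.
    Returns ``(grid, x_origin, y_origin)`` with a north-up geotransform.
    """
    if len(crowns) and carbon_column not in crowns:
        raise ValueError(f"crowns lack a {carbon_column!r} column; run allometry first")
    if len(crowns) and crowns[carbon_column].isna().any():
        bad = crowns.loc[crowns[carbon_column].isna(), "id"].tolist()
        raise ValueError(f"missing carbon estimates for crown ids {bad[:10]}")
    xmin, ymin, xmax, ymax = bounds
    ncols = int(np.ceil((xmax - xmin) / cell_size))
    nrows = int(np.ceil((ymax - ymin) / cell_size))
    grid = np.zeros((nrows, ncols))
    if len(crowns):
        col = np.clip(((crowns["x"] - xmin) // cell_size).astype(int), 0, ncols - 1)
        row = np.clip(((ymax - crowns["y"]) // cell_size).astype(int), 0, nrows - 1)
        np.add.at(grid, (row, col), crowns[carbon_column].to_numpy(dtype=float))
    cell_ha = cell_size**2 / 1e4
    grid = grid / 1000.0 / cell_ha  # kg -> Mg, per hectare
    return grid, xmin, ymax


PERCENTILES = (5, 10, 25, 75, 90, 95)


def zonal_summary(
    crowns: pd.DataFrame,
    zones: ZoneDefinition = DEFAULT_ZONES,
    zone_land_area_ha: dict[str, float] | None = None,
    percentiles: Sequence[int] = PERCENTILES,
) -> list[ZoneSummary]:
    """Per-zone carbon statistics for classified, estimated crowns.

    ``zone_land_area_ha`` gives each zone's land area for the density
    denominator (e.g. counted from the rainfall raster); zones without an
    entry get NaN density.  Percentiles use linear interpolation between
    order statistics.  Carbon shares are percentages of the total carbon of
    in-domain trees and sum to 100 when every zone is present.
    """
    if "zone" not in crowns:
        raise ValueError("crowns must carry a 'zone' column; classify them first")
    in_domain = crowns[crowns["zone"].isin(zones.names)]
    grand_total = float(in_domain["carbon_kg"].sum()) if len(in_domain) else 0.0
    out = []
    for name in zones.names:
        sub = in_domain[in_domain["zone"] == name]
        n = len(sub)
        land_ha = (zone_land_area_ha or {}).get(name, float("nan"))
        total_kg = float(sub["carbon_kg"].sum()) if n else 0.0
        if n == 0:
            logger.warning("zone %r has no trees; means undefined", name)
        out.append(
            ZoneSummary(
                zone=name,
                n_trees=n,
                mean_carbon_kg=float(sub["carbon_kg"].mean()) if n else float("nan"),
                carbon_density_mg_ha=(total_kg / 1000.0 / land_ha)
                if land_ha and np.isfinite(land_ha) else float("nan"),
                total_carbon_kg=total_kg,
                carbon_share_pct=100.0 * total_kg / grand_total if grand_total else 0.0,
                mean_crown_area_m2=float(sub["crown_area_m2"].mean()) if n else float("nan"),
                land_area_ha=land_ha,
                carbon_percentiles_kg={
                    int(q): float(np.percentile(sub["carbon_kg"], q)) if n else float("nan")
                    for q in percentiles
                },
            )
        )
    return out


def zone_land_areas(
    rainfall: RainfallField, zones: ZoneDefinition = DEFAULT_ZONES
) -> dict[str, float]:
    """Hectares of each zone within a rainfall raster (cell-count based)."""
    z = classify_zones(rainfall.grid.ravel(), zones)
    cell_ha = rainfall.cell_size**2 / 1e4
    return {name: float(np.sum(z == name)) * cell_ha for name in zones.names}


def percentile_profile(
    crowns: pd.DataFrame,
    value_column: str = "carbon_kg",
    bin_width: float = 25.0,
    percentiles: Sequence[int] = PERCENTILES,
) -> pd.DataFrame:
    """Percentile curves of a per-tree quantity along the rainfall gradient.

    Bins trees into ``bin_width`` mm yr⁻¹ rainfall bins and returns a tidy
    frame (bin_centre_mm, percentile, value) plus the bin mean
    (percentile = -1 row encodes the mean).
    """
    sub = crowns.dropna(subset=["rainfall"])
    if not len(sub):
        return pd.DataFrame(columns=["bin_centre_mm", "percentile", "value"])
    bins = (sub["rainfall"] // bin_width).astype(int)
    rows = []
    for b, grp in sub.groupby(bins):
        centre = (b + 0.5) * bin_width
        rows.append({"bin_centre_mm": centre, "percentile": -1,
                     "value": float(grp[value_column].mean())})
        for q in percentiles:
            rows.append({"bin_centre_mm": centre, "percentile": q,
                         "value": float(np.percentile(grp[value_column], q))})
    return pd.DataFrame(rows)


__all__.append("zone_land_areas")
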