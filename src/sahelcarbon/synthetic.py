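"""Synthetic dryland landscapes, field allometry samples and fixtures.

Real inputs to the pipeline come from satellite crown mapping, rain-gauge
calibrated precipitation products and destructive-sampling campaigns.  The
generators here emulate their statistical structure so that every
downstream stage can be exercised and validated offline:

* a rectangular landscape with a linear west–east rainfall gradient,
  rainfall-zone dependent tree densities and truncated-lognormal crown
  sizes (disjoint circular crowns);
* destructive-sampling sets drawn from known power laws with
  multiplicative lognormal noise, so fitted parameters have a known truth;
* evaluation plots with planted commission/omission errors whose rates are
  recovered exactly by the evaluation stage;
* image catalogs spanning months, view geometries and cloud conditions.

Every generator is a pure function of its configuration, including the
seed: identical configs give byte-identical serialised outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .allometry import COMPONENTS, FieldSampleSet, MIN_CROWN_AREA_M2
from .crown_eval import EvaluationPlot
from .geo import RainfallField, DEFAULT_ZONES, ZoneDefinition, classify_zone, extract_rainfall

__all__ = [
    "LandscapeConfig",
    "FieldSampleConfig",
    "DEFAULT_ZONE_DENSITY",
    "DEFAULT_ZONE_CROWN_MEAN",
    "DEFAULT_CROWN_SIGMA",
    "NOISE_SIGMA_DEFAULT",
    "gen_landscape",
    "gen_field_samples",
    "gen_eval_fixture",
    "gen_image_catalog",
]

#: Trees per hectare by rainfall zone: each zone's reported carbon density
#: divided by its reported mean per-tree stock (e.g. 0.54 Mg ha⁻¹ / 63 kg).
DEFAULT_ZONE_DENSITY = {
    "hyper-arid": 0.6,
    "arid": 8.6,
    "semi-arid": 21.0,
    "sub-humid": 38.0,
}

#: Mean crown area (m²) by zone, matching the reported zone averages.
DEFAULT_ZONE_CROWN_MEAN = {
    "hyper-arid": 15.1,
    "arid": 18.4,
    "semi-arid": 20.9,
    "sub-humid": 28.1,
}

#: Log-scale σ of the lognormal crown-size law.  With the zone means above
#: this puts ≈88% of crowns below 50 m² and well under 1% above 200 m².
DEFAULT_CROWN_SIGMA = 0.85

#: Multiplicative lognormal noise σ on field masses; calibrated by
#: simulation so the 80/20 subsampling uncertainty procedure on default
#: sample sizes yields a mean relative allometric uncertainty near 19.5%.
NOISE_SIGMA_DEFAULT = 0.70


@dataclass(frozen=True)
class LandscapeConfig:
    """Synthetic landscape: extent, rainfall gradient, per-zone tree laws."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 20000.0, 500.0)
    rainfall_west: float = 0.0
    rainfall_east: float = 1000.0
    zone_density: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_ZONE_DENSITY)
    )
    zone_crown_mean: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_ZONE_CROWN_MEAN)
    )
    zone_crown_sigma: Mapping[str, float] | float = DEFAULT_CROWN_SIGMA
    min_crown_area: float = MIN_CROWN_AREA_M2
    rainfall_cell_size: float = 100.0
    zones: ZoneDefinition = DEFAULT_ZONES
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must have positive area")
        if min(self.rainfall_west, self.rainfall_east) < 0:
            raise ValueError("rainfall endpoints must be non-negative")
        for z, d in self.zone_density.items():
            if d < 0:
                raise ValueError(f"negative tree density for zone {z!r}")
        for z, m in self.zone_crown_mean.items():
            if m <= self.min_crown_area:
                raise ValueError(
                    f"zone {z!r} mean crown area must exceed min_crown_area"
                )

    def sigma_for(self, zone: str) -> float:
        if isinstance(self.zone_crown_sigma, Mapping):
            return float(self.zone_crown_sigma[zone])
        return float(self.zone_crown_sigma)


@dataclass(frozen=True)
class FieldSampleConfig:
    """Destructive-sampling emulation: true power laws plus noise."""

    true_models: Mapping[str, tuple[float, float]] = dc_field(
        default_factory=lambda: {
            "wood": (3.9448, 1.1068),
            "foliage": (0.2693, 0.9441),
            "root": (0.8339, 1.1730),
        }
    )
    n_per_component: Mapping[str, int] = dc_field(
        default_factory=lambda: {"wood": 698, "foliage": 900, "root": 26}
    )
    noise_sigma: float = NOISE_SIGMA_DEFAULT
    area_range: tuple[float, float] = (3.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for comp, n in self.n_per_component.items():
            if n < 2:
                raise ValueError(f"need at least 2 samples per component ({comp!r})")
        lo, hi = self.area_range
        if not (0 < lo < hi):
            raise ValueError("area_range must be positive and increasing")


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _lognormal_mu_for_truncated_mean(mean: float, sigma: float, lower: float) -> float:
    """Location μ of a lognormal whose mean *conditional on X > lower* is ``mean``.

    The zone averages describe observed crowns, which are all above the
    detection threshold, so the truncated mean is what must match.  The
    conditional mean ``exp(μ+σ²/2)·Φ(σ−z)/Φ(−z)`` with ``z=(ln L−μ)/σ`` is
    strictly increasing in μ; solved by bisection.
    """
    def tmean(mu: float) -> float:
        z = (math.log(lower) - mu) / sigma
        denom = 1.0 - _phi(z)
        if denom <= 0:
            return lower
        return math.exp(mu + sigma**2 / 2.0) * (1.0 - _phi(z - sigma)) / denom

    lo = math.log(lower) - 8.0 * sigma
    hi = math.log(mean) + sigma
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if tmean(mid) < mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, n: int, lower: float,
    upper: float | None = None,
) -> np.ndarray:
    """Lognormal(μ, σ) truncated by rejection sampling."""
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - out.size) + 16)
        draw = draw[draw > lower]
        if upper is not None:
            draw = draw[draw <= upper]
        out = np.concatenate([out, draw])
    return out[:n]


def _rainfall_grid(config: LandscapeConfig) -> RainfallField:
    xmin, ymin, xmax, ymax = config.extent
    cs = config.rainfall_cell_size
    ncols = int(math.ceil((xmax - xmin) / cs))
    nrows = int(math.ceil((ymax - ymin) / cs))
    xc = xmin + (np.arange(ncols) + 0.5) * cs
    frac = (xc - xmin) / (xmax - xmin)
    row = config.rainfall_west + frac * (config.rainfall_east - config.rainfall_west)
    grid = np.tile(row, (nrows, 1))
    return RainfallField(grid=grid, x_origin=xmin, y_origin=ymax, cell_size=cs)


class _CircleHash:
    """Uniform-grid spatial hash for disjoint circle placement."""

    def __init__(self, cell: float = 40.0) -> None:
        self.cell = cell
        self.buckets: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def overlaps(self, x: float, y: float, r: float) -> bool:
        ci, cj = int(x // self.cell), int(y // self.cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for ox, oy, orad in self.buckets.get((ci + di, cj + dj), ()):
                    if (x - ox) ** 2 + (y - oy) ** 2 < (r + orad) ** 2:
                        return True
        return False

    def add(self, x: float, y: float, r: float) -> None:
        self.buckets.setdefault((int(x // self.cell), int(y // self.cell)), []).append(
            (x, y, r)
        )


def gen_landscape(config: LandscapeConfig) -> tuple[RainfallField, pd.DataFrame]:
    """Generate a rainfall raster and a crown table for a synthetic landscape.

    The rainfall field is linear along x between the configured endpoints.
    Within each rainfall zone's x-band, ``round(density × band hectares)``
    trees are placed uniformly at random with truncated-lognormal crown
    areas; crowns are disjoint circles (placements overlapping an existing
    crown are re-sampled up to a retry cap).

    Returns the field and a crown table with columns
    ``id, x, y, crown_area_m2, rainfall, zone``; each crown's zone is the
    zone of the rainfall extracted at its centroid.
    """
    rng = np.random.default_rng(config.seed)
    rainfall = _rainfall_grid(config)
    xmin, ymin, xmax, ymax = config.extent
    width, height = xmax - xmin, ymax - ymin
    rw, re = config.rainfall_west, config.rainfall_east

    records: list[tuple[float, float, float]] = []
    occupancy = _CircleHash()
    zones = config.zones
    for zi, zone in enumerate(zones.names):
        density = float(config.zone_density.get(zone, 0.0))
        if density <= 0:
            continue
        lo, hi = zones.bounds[zi], zones.bounds[zi + 1]
        if re == rw:
            if not (lo <= rw < hi):
                continue
            x_lo, x_hi = xmin, xmax
        else:
            # x-interval of this rainfall band under the linear gradient
            f_lo = (lo - rw) / (re - rw)
            f_hi = (hi - rw) / (re - rw)
            f_lo, f_hi = min(f_lo, f_hi), max(f_lo, f_hi)
            x_lo = xmin + max(0.0, f_lo) * width
            x_hi = xmin + min(1.0, f_hi) * width
        if x_hi <= x_lo:
            continue
        band_ha = (x_hi - x_lo) * height / 1e4
        n = int(round(density * band_ha))
        if n == 0:
            continue
        sigma = config.sigma_for(zone)
        mu = _lognormal_mu_for_truncated_mean(
            config.zone_crown_mean[zone], sigma, config.min_crown_area
        )
        areas = _truncated_lognormal(rng, mu, sigma, n, config.min_crown_area)
        for a in areas:
            r = math.sqrt(a / math.pi)
            for _ in range(50):
                x = rng.uniform(x_lo, x_hi)
                y = rng.uniform(ymin, ymax)
                if not occupancy.overlaps(x, y, r):
                    break
            occupancy.add(x, y, r)
            records.append((x, y, float(a)))

    if records:
        arr = np.array(records)
        crowns = pd.DataFrame(
            {"id": np.arange(len(records)), "x": arr[:, 0], "y": arr[:, 1],
             "crown_area_m2": arr[:, 2]}
        )
        crowns["rainfall"] = extract_rainfall(rainfall, arr[:, :2])
        crowns["zone"] = [classify_zone(p, zones) for p in crowns["rainfall"]]
    else:
        crowns = pd.DataFrame(
            columns=["id", "x", "y", "crown_area_m2", "rainfall", "zone"]
        )
    return rainfall, crowns


def gen_field_samples(config: FieldSampleConfig) -> dict[str, FieldSampleSet]:
    """Draw destructive-sampling sets from the configured power laws.

    Crown areas are log-uniform over ``area_range``; masses are
    ``a·A^b × exp(σ·ε)`` with standard-normal ε — multiplicative lognormal
    noise, the residual model implied by a log–log least-squares fit.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.area_range
    out = {}
    for comp in COMPONENTS:
        a, b = config.true_models[comp]
        n = config.n_per_component[comp]
        areas = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
        noise = (
            np.exp(config.noise_sigma * rng.standard_normal(n))
            if config.noise_sigma > 0 else np.ones(n)
        )
        out[comp] = FieldSampleSet(comp, areas, a * np.power(areas, b) * noise)
    return out


def gen_eval_fixture(
    n_true: int,
    commission_rate: float,
    omission_rate: float,
    seed: int = 0,
    crown_area_mean: float = 20.0,
    crown_area_sigma: float = DEFAULT_CROWN_SIGMA,
) -> list[EvaluationPlot]:
    """Evaluation plot(s) with exactly planted commission/omission errors.

    Exactly ``round(n_true × commission_rate)`` spurious predictions and
    ``round(n_true × omission_rate)`` unpredicted labelled crowns are
    planted; every other labelled crown has an exactly matching prediction.
    Crowns sit on a lattice with spacing chosen so all circles are disjoint,
    which makes the planted rates recoverable exactly by the matcher.
    """
    if not (0 <= commission_rate < 1 and 0 <= omission_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if commission_rate + omission_rate >= 1:
        raise ValueError("commission + omission rates must sum below 1")
    if n_true <= 0:
        raise ValueError("n_true must be positive")
    rng = np.random.default_rng(seed)
    n_com = int(round(n_true * commission_rate))
    n_om = int(round(n_true * omission_rate))

    area_cap = 200.0
    areas = _truncated_lognormal(
        rng, math.log(crown_area_mean) - crown_area_sigma**2 / 2.0,
        crown_area_sigma, n_true + n_com, MIN_CROWN_AREA_M2, upper=area_cap,
    )
    r_cap = math.sqrt(area_cap / math.pi)
    spacing = 2 * r_cap + 1.0
    side = int(math.ceil(math.sqrt(n_true + n_com)))
    sites = [( (k % side) * spacing, (k // side) * spacing)
             for k in range(n_true + n_com)]

    def circle(x: float, y: float, a: float):
        return Point(x, y).buffer(math.sqrt(a / math.pi), quad_segs=16)

    labelled = {
        i: circle(*sites[i], areas[i]) for i in range(n_true)
    }
    omitted = set(rng.choice(n_true, size=n_om, replace=False).tolist())
    predicted = {i: labelled[i] for i in range(n_true) if i not in omitted}
    for k in range(n_com):
        pid = n_true + k
        predicted[pid] = circle(*sites[pid], areas[pid])

    return [EvaluationPlot(plot_id=0, labelled=labelled, predicted=predicted)]


def gen_image_catalog(n: int, seed: int = 0, n_tiles: int | None = None) -> pd.DataFrame:
    """Random image-catalog table spanning the relevant metadata ranges.

    Months cover 1–12, off-nadir angles −45°…45°, cloud cover 0–100%
    (skewed low, as archives mostly hold usable scenes), sun elevation
    20°–70°, acquisition years 2002–2020.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(
            columns=["image_id", "tile_id", "year", "month", "cloud_pct",
                     "sun_elev_deg", "off_nadir_deg"]
        )
    n_tiles = n_tiles or max(1, n // 5)
    return pd.DataFrame(
        {
            "image_id": [f"img{k:06d}" for k in range(n)],
            "tile_id": [f"tile{t:04d}" for t in rng.integers(0, n_tiles, size=n)],
            "year": rng.integers(2002, 2021, size=n),
            "month": rng.integers(1, 13, size=n),
            "cloud_pct": np.round(100.0 * rng.beta(1.0, 6.0, size=n), 2),
            "sun_elev_deg": np.round(rng.uniform(20.0, 70.0, size=n), 2),
            "off_nadir_deg": np.round(rng.uniform(-45.0, 45.0, size=n), 2),
        }
    )
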