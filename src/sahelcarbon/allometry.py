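"""Crown-area allometry: power-law dry-mass models and carbon conversion.

Dryland field campaigns relate the horizontal projected crown area ``A``
(m²) of a tree to the oven-dry mass of its wood, foliage and roots through
power laws ``mass = a * A**b`` fitted by ordinary least squares in log–log
space on destructive-sampling data.  Summing the three components and
multiplying by a fixed carbon concentration converts a mapped crown polygon
into a per-tree carbon stock in kg C.

Very large crowns are usually clumps of several individuals, so areas above
200 m² are split into 100 m² pieces (plus a remainder) before the power laws
are applied; with exponents slightly above 1 this caps the superlinear
extrapolation of single-tree allometry to clumped canopies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AllometricComponentModel",
    "CarbonEstimate",
    "FieldSampleSet",
    "TreeCrown",
    "COMPONENTS",
    "CARBON_FRACTION",
    "SPLIT_THRESHOLD_M2",
    "SPLIT_PIECE_M2",
    "MIN_CROWN_AREA_M2",
    "DEFAULT_MODELS",
    "default_models",
    "CrownBelowThreshold",
    "predict_component_mass",
    "split_crown",
    "estimate_tree_carbon",
    "add_carbon_estimates",
    "fit_component_model",
]

COMPONENTS = ("wood", "foliage", "root")

#: Carbon concentration of dry biomass (kg C per kg dry mass).
CARBON_FRACTION = 0.47

#: Crowns larger than this are treated as clumped canopies and split.
SPLIT_THRESHOLD_M2 = 200.0
#: Piece size used when splitting a clumped canopy.
SPLIT_PIECE_M2 = 100.0

#: Detection threshold: a tree is a green crown larger than this.
MIN_CROWN_AREA_M2 = 3.0


class CrownBelowThreshold(Exception):
    """Raised when a crown area is at or below the detection threshold.

    Distinct from :class:`ValueError` so callers can treat "this crown is
    filtered out by the tree definition" differently from a malformed input.
    """


@dataclass(frozen=True)
class AllometricComponentModel:
    """One fitted power law ``mass = a * A**b`` for a dry-mass component.

    Parameters
    ----------
    component
        One of ``"wood"``, ``"foliage"``, ``"root"``.
    a
        Multiplicative coefficient, kg at A = 1 m².
    b
        Dimensionless scaling exponent.
    n
        Number of destructively sampled trees behind the fit.
    """

    component: str
    a: float
    b: float
    n: int = 0

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if not (self.a > 0 and self.b > 0):
            raise ValueError("power-law parameters a, b must be positive")

    def predict(self, area):
        return predict_component_mass(self, area)


def default_models() -> dict[str, AllometricComponentModel]:
    """The Sahelian destructive-sampling power laws (kg dry mass, A in m²)."""
    return {
        "wood": AllometricComponentModel("wood", 3.9448, 1.1068, 698),
        "foliage": AllometricComponentModel("foliage", 0.2693, 0.9441, 900),
        "root": AllometricComponentModel("root", 0.8339, 1.1730, 26),
    }


DEFAULT_MODELS: Mapping[str, AllometricComponentModel] = default_models()


@dataclass(frozen=True)
class CarbonEstimate:
    """Per-tree dry-mass components and carbon stock, all in kg."""

    mass_w: float
    mass_f: float
    mass_r: float
    mass_total: float
    carbon: float
    split_areas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if min(self.mass_w, self.mass_f, self.mass_r) < 0:
            raise ValueError("component masses must be non-negative")


@dataclass
class TreeCrown:
    """A single detected tree crown.

    ``rainfall`` and ``zone`` are filled in once the crown has been located
    on a precipitation field; ``estimate`` once allometry has been applied.
    """

    id: int
    crown_area: float
    centroid: tuple[float, float]
    rainfall: float | None = None
    zone: str | None = None
    estimate: CarbonEstimate | None = None


@dataclass
class FieldSampleSet:
    """Destructive-sampling records for one component: crown areas and masses."""

    component: str
    areas: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.areas.shape != self.masses.shape or self.areas.ndim != 1:
            raise ValueError("areas and masses must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.areas.size


def predict_component_mass(model: AllometricComponentModel, area):
    """Evaluate ``a * area**b`` (kg dry mass) for scalar or array crown area.

    Raises
    ------
    ValueError
        If any area is non-positive: the power law has no meaning there.
    """
    arr = np.asarray(area, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("crown area must be positive")
    out = model.a * np.power(arr, model.b)
    return float(out) if np.isscalar(area) or arr.ndim == 0 else out


def split_crown(area: float) -> list[float]:
    """Split a clumped canopy into 100 m² pieces plus a remainder.

    Areas up to 200 m² are returned unchanged.  Above that, the crown is cut
    into ``floor(A/100)`` pieces of 100 m² and one remainder piece if the
    remainder is non-zero.  The pieces always sum to the input area.
    """
    if area <= 0:
        raise ValueError("crown area must be positive")
    if area <= SPLIT_THRESHOLD_M2:
        return [area]
    n_full = int(math.floor(area / SPLIT_PIECE_M2))
    remainder = area - n_full * SPLIT_PIECE_M2
    pieces = [SPLIT_PIECE_M2] * n_full
    if remainder > 0:
        pieces.append(remainder)
    return pieces


def estimate_tree_carbon(
    area: float,
    models: Mapping[str, AllometricComponentModel] = DEFAULT_MODELS,
    carbon_fraction: float = CARBON_FRACTION,
    min_crown_area: float = MIN_CROWN_AREA_M2,
) -> CarbonEstimate:
    """Estimate wood/foliage/root dry mass and carbon for one crown.

    The splitting rule is applied to the area first; each component power
    law is then summed over the pieces, so all three components see the same
    decomposition.  Split fragments below the detection threshold still
    receive allometry — the threshold is a property of detected crowns, not
    of fragments.

    Raises
    ------
    CrownBelowThreshold
        If ``area <= min_crown_area`` — the object is not a tree under the
        mapping definition (filtered, not an error in the input).
    """
    if area <= 0:
        raise ValueError("crown area must be positive")
    if area <= min_crown_area:
        raise CrownBelowThreshold(
            f"crown area {area:g} m² is at or below the {min_crown_area:g} m² "
            "detection threshold"
        )
    pieces = split_crown(area)
    mass = {}
    for comp in COMPONENTS:
        model = models[comp]
        mass[comp] = float(sum(predict_component_mass(model, p) for p in pieces))
    total = mass["wood"] + mass["foliage"] + mass["root"]
    return CarbonEstimate(
        mass_w=mass["wood"],
        mass_f=mass["foliage"],
        mass_r=mass["root"],
        mass_total=total,
        carbon=carbon_fraction * total,
        split_areas=tuple(pieces),
    )


def _component_mass_with_split(model: AllometricComponentModel, areas: np.ndarray) -> np.ndarray:
    """Vectorised split-then-predict for one component over many crowns."""
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("crown areas must be positive")
    out = model.a * np.power(areas, model.b)
    big = areas > SPLIT_THRESHOLD_M2
    if np.any(big):
        n_full = np.floor(areas[big] / SPLIT_PIECE_M2)
        remainder = areas[big] - n_full * SPLIT_PIECE_M2
        piece_mass = model.a * SPLIT_PIECE_M2**model.b
        rem_mass = np.where(
            remainder > 0, model.a * np.power(np.maximum(remainder, 1e-300), model.b), 0.0
        )
        out[big] = n_full * piece_mass + rem_mass
    return out


def add_carbon_estimates(
    crowns: pd.DataFrame,
    models: Mapping[str, AllometricComponentModel] = DEFAULT_MODELS,
    carbon_fraction: float = CARBON_FRACTION,
    area_column: str = "crown_area_m2",
) -> pd.DataFrame:
    """Append per-tree mass and carbon columns to a crown table.

    Adds ``mass_w_kg``, ``mass_f_kg``, ``mass_r_kg``, ``mass_total_kg`` and
    ``carbon_kg``.  Operates vectorised; equivalent to calling
    :func:`estimate_tree_carbon` per row.
    """
    areas = crowns[area_column].to_numpy(dtype=float)
    out = crowns.copy()
    comp_cols = {"wood": "mass_w_kg", "foliage": "mass_f_kg", "root": "mass_r_kg"}
    total = np.zeros(len(out))
    for comp, col in comp_cols.items():
        m = _component_mass_with_split(models[comp], areas) if len(out) else np.zeros(0)
        out[col] = m
        total = total + m
    out["mass_total_kg"] = total
    out["carbon_kg"] = carbon_fraction * total
    return out


def fit_component_model(
    samples: FieldSampleSet | None = None,
    areas: Sequence[float] | None = None,
    masses: Sequence[float] | None = None,
    component: str | None = None,
) -> AllometricComponentModel:
    """Fit ``mass = a * A**b`` by OLS on (log A, log mass).

    The affine fit ``log mass = log a + b log A`` uses natural logs (the
    base is immaterial to the back-transformed parameters).  No smearing /
    back-transform bias correction is applied: the coefficient is the direct
    exponential of the fitted intercept.

    Accepts either a :class:`FieldSampleSet` or explicit area/mass arrays.
    """
    if samples is not None:
        areas, masses, component = samples.areas, samples.masses, samples.component
    A = np.asarray(areas, dtype=float)
    y = np.asarray(masses, dtype=float)
    if A.size < 2:
        raise ValueError("need at least 2 samples to fit a power law")
    if np.any(A <= 0) or np.any(y <= 0):
        raise ValueError("areas and masses must be positive for a log–log fit")
    logA = np.log(A)
    if np.ptp(logA) == 0:
        raise ValueError("degenerate design: all crown areas identical")
    b, loga = np.polyfit(logA, np.log(y), 1)
    return AllometricComponentModel(
        component=component or "wood", a=float(np.exp(loga)), b=float(b), n=int(A.size)
    )
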