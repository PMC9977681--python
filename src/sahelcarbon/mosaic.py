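"""Mosaic image selection and NDVI.

A wall-to-wall mosaic must pick exactly one acquisition per tile so that no
tree is counted twice.  Candidate images are ranked in two rounds:

* round 1 scores image quality — lower cloud cover, then higher sun
  elevation, then view angle closest to nadir;
* round 2 assigns a seasonal/geometry priority class, favouring early
  dry-season months (November–January) at near-nadir angles:

  =====  ====================  ==================
  class  months                |off-nadir| angle
  =====  ====================  ==================
  1      Nov, Dec, Jan         < 15°
  2      Nov, Dec, Jan         15°–30°
  3      Feb, Mar              < 15°
  4      Feb, Mar              15°–30°
  =====  ====================  ==================

  Other months, or angles beyond 30°, are ineligible.

The tile winner is the eligible image with the best (lowest) priority
class, ties broken by the round-1 quality keys, then by later acquisition
year, then by image id — a total, input-order-independent ordering.

NDVI is the standard normalized difference (NIR − red) / (NIR + red), used
to separate photosynthetically active tree crowns from senescent herbaceous
background in early dry-season scenes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageRecord",
    "ndvi",
    "priority_class",
    "rank_round1",
    "select_tile_image",
    "select_catalog",
]

EARLY_DRY_SEASON = (11, 12, 1)
LATE_DRY_SEASON = (2, 3)
NADIR_LIMIT_DEG = 15.0
OFFNADIR_LIMIT_DEG = 30.0


@dataclass(frozen=True)
class ImageRecord:
    """Catalog metadata for one acquisition of one mosaic tile."""

    image_id: str
    tile_id: str
    year: int
    month: int
    cloud_pct: float
    sun_elev_deg: float
    off_nadir_deg: float
    sensor: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} out of range")
        if abs(self.off_nadir_deg) > 90:
            raise ValueError("off-nadir angle beyond ±90°")


def ndvi(red, nir):
    """Normalized difference vegetation index, (NIR − red)/(NIR + red).

    Accepts scalars or arrays of non-negative reflectances.  Where both
    bands are zero the index is 0 by convention (no signal, no vegetation).
    Always lies in [−1, 1].
    """
    r = np.asarray(red, dtype=float)
    n = np.asarray(nir, dtype=float)
    if np.any(r < 0) or np.any(n < 0):
        raise ValueError("reflectances must be non-negative")
    denom = n + r
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (n - r) / np.where(denom > 0, denom, 1.0), 0.0)
    if np.isscalar(red) and np.isscalar(nir):
        return float(out)
    return out


def priority_class(record: ImageRecord) -> int | None:
    """Round-2 priority class 1–4, or None if the image is ineligible."""
    off = abs(record.off_nadir_deg)
    if off > OFFNADIR_LIMIT_DEG:
        return None
    if record.month in EARLY_DRY_SEASON:
        return 1 if off < NADIR_LIMIT_DEG else 2
    if record.month in LATE_DRY_SEASON:
        return 3 if off < NADIR_LIMIT_DEG else 4
    return None


def _round1_key(r: ImageRecord):
    return (r.cloud_pct, -r.sun_elev_deg, abs(r.off_nadir_deg), -r.year, r.image_id)


def rank_round1(records: Sequence[ImageRecord]) -> list[ImageRecord]:
    """Round-1 quality ranking: cloud ↑, sun elevation ↓, |off-nadir| ↑.

    The trailing keys (later year first, then image id) make the ordering
    total and therefore independent of input order.
    """
    if not records:
        raise ValueError("no records to rank")
    return sorted(records, key=_round1_key)


def select_tile_image(records: Sequence[ImageRecord]) -> ImageRecord | None:
    """Choose the mosaic image for one tile, or None if nothing is eligible.

    Among eligible records (priority class defined), picks the minimal
    (class, round-1 key).  Deterministic and input-order invariant.
    """
    tiles = {r.tile_id for r in records}
    if len(tiles) > 1:
        raise ValueError(f"records span multiple tiles: {sorted(tiles)}")
    eligible = [(priority_class(r), r) for r in records]
    eligible = [(c, r) for c, r in eligible if c is not None]
    if not eligible:
        return None
    return min(eligible, key=lambda cr: (cr[0], _round1_key(cr[1])))[1]


def select_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Select one image per tile from a catalog table.

    Expects columns image_id, tile_id, year, month, cloud_pct, sun_elev_deg,
    off_nadir_deg.  Returns one row per tile with the chosen image and its
    priority class; tiles with no eligible image are reported with a null
    image id.
    """
    rows = []
    for tile_id, grp in catalog.groupby("tile_id", sort=True):
        records = [
            ImageRecord(
                image_id=str(r.image_id), tile_id=str(r.tile_id), year=int(r.year),
                month=int(r.month), cloud_pct=float(r.cloud_pct),
                sun_elev_deg=float(r.sun_elev_deg),
                off_nadir_deg=float(r.off_nadir_deg),
            )
            for r in grp.itertuples()
        ]
        chosen = select_tile_image(records)
        rows.append(
            {
                "tile_id": tile_id,
                "image_id": chosen.image_id if chosen else None,
                "priority_class": priority_class(chosen) if chosen else None,
                "n_candidates": len(records),
            }
        )
    return pd.DataFrame(rows)
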