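"""Crown-mapping accuracy assessment: matching, error rates, plot sampling.

Predicted crown polygons are compared with hand-labelled truth by a greedy
one-to-one matching in descending overlap-area order.  Unmatched labelled
crowns are omission errors (missed trees); unmatched predictions are
commission errors (spurious crowns).  A prediction that covers several
labelled crowns (clumping) matches only the one with the largest overlap;
the remaining labels count as omissions.

Error rates are pooled across evaluation plots and broken down by crown-
area class (0–15, 15–50, 50–200, >200 m²).  Both rates are expressed
relative to the number of evaluated (labelled) trees, with commissions /
predictions reported as a secondary figure; the net detection uncertainty
is the signed difference commission − omission.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, Point
from shapely.strtree import STRtree

__all__ = [
    "AREA_CLASSES",
    "area_class",
    "EvaluationPlot",
    "MatchingResult",
    "ErrorRates",
    "match_crowns",
    "error_rates",
    "area_rmse",
    "sample_eval_plots",
]

logger = logging.getLogger(__name__)

#: Crown-area classes (m²), half-open, as (label, lo, hi).
AREA_CLASSES = (
    ("0-15", 0.0, 15.0),
    ("15-50", 15.0, 50.0),
    ("50-200", 50.0, 200.0),
    (">200", 200.0, math.inf),
)


def area_class(area: float) -> str:
    """Crown-area class label for an area in m²."""
    for label, lo, hi in AREA_CLASSES:
        if lo <= area < hi:
            return label
    raise ValueError(f"area {area} outside all classes")


@dataclass
class EvaluationPlot:
    """One evaluation area: labelled truth crowns vs predicted crowns."""

    plot_id: int
    labelled: dict[int, Polygon]
    predicted: dict[int, Polygon]
    rainfall: float | None = None

    def __post_init__(self) -> None:
        for crowns in (self.labelled, self.predicted):
            for cid, geom in crowns.items():
                if not geom.is_valid or geom.area <= 0:
                    raise ValueError(f"crown {cid} has invalid or zero-area geometry")


@dataclass
class MatchingResult:
    """One-to-one crown matching with per-class error counts."""

    pairs: list[tuple[int, int, float]]  # (labelled_id, predicted_id, overlap m²)
    omissions: list[int]
    commissions: list[int]
    labelled_areas: dict[int, float]
    predicted_areas: dict[int, float]
    per_class_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_labelled(self) -> int:
        return len(self.labelled_areas)

    @property
    def n_predicted(self) -> int:
        return len(self.predicted_areas)


@dataclass
class ErrorRates:
    """Pooled commission/omission rates (fractions of evaluated trees)."""

    n_labelled: int
    n_predicted: int
    n_commission: int
    n_omission: int
    commission_rate: float
    omission_rate: float
    net_rate: float
    commission_rate_predicted: float
    per_class: dict[str, dict[str, float | int | None]] = field(default_factory=dict)


def match_crowns(
    labelled: Mapping[int, Polygon],
    predicted: Mapping[int, Polygon],
    min_iou: float = 0.0,
) -> MatchingResult:
    """Greedily match predicted to labelled crowns by overlap area.

    Candidate pairs are all label/prediction pairs with intersection-over-
    union strictly above ``min_iou`` (default: any positive overlap).  Pairs
    are taken in descending overlap-area order (ties: smaller labelled id,
    then smaller predicted id), each crown used at most once.
    """
    lab_ids = sorted(labelled)
    pred_ids = sorted(predicted)
    lab_geoms = [labelled[i] for i in lab_ids]
    pred_geoms = [predicted[i] for i in pred_ids]
    for geoms, ids in ((lab_geoms, lab_ids), (pred_geoms, pred_ids)):
        for g, i in zip(geoms, ids):
            if not g.is_valid:
                raise ValueError(f"invalid geometry for crown {i}")

    candidates = []
    if lab_geoms and pred_geoms:
        tree = STRtree(pred_geoms)
        for li, lgeom in zip(lab_ids, lab_geoms):
            for j in tree.query(lgeom):
                pgeom = pred_geoms[j]
                inter = lgeom.intersection(pgeom).area
                if inter <= 0:
                    continue
                iou = inter / (lgeom.area + pgeom.area - inter)
                if iou > min_iou:
                    candidates.append((inter, li, pred_ids[j]))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_lab: set[int] = set()
    used_pred: set[int] = set()
    pairs = []
    for inter, li, pi in candidates:
        if li in used_lab or pi in used_pred:
            continue
        pairs.append((li, pi, inter))
        used_lab.add(li)
        used_pred.add(pi)

    omissions = [i for i in lab_ids if i not in used_lab]
    commissions = [i for i in pred_ids if i not in used_pred]
    lab_areas = {i: labelled[i].area for i in lab_ids}
    pred_areas = {i: predicted[i].area for i in pred_ids}

    per_class = {
        label: {"n_labelled": 0, "n_commission": 0, "n_omission": 0}
        for label, *_ in AREA_CLASSES
    }
    for i in lab_ids:
        per_class[area_class(lab_areas[i])]["n_labelled"] += 1
    for i in omissions:
        per_class[area_class(lab_areas[i])]["n_omission"] += 1
    for i in commissions:
        per_class[area_class(pred_areas[i])]["n_commission"] += 1

    return MatchingResult(
        pairs=pairs,
        omissions=omissions,
        commissions=commissions,
        labelled_areas=lab_areas,
        predicted_areas=pred_areas,
        per_class_counts=per_class,
    )


def error_rates(matchings: Iterable[MatchingResult]) -> ErrorRates:
    """Pooled commission/omission error rates over evaluation plots.

    Counts are pooled (micro-averaged) across plots.  Rates are fractions
    of the evaluated labelled trees; ``commission_rate_predicted`` divides
    by the prediction count instead.  Classes with no labelled tree get
    ``None`` rates (undefined).
    """
    matchings = list(matchings)
    if not matchings:
        raise ValueError("need at least one matching")
    n_lab = sum(m.n_labelled for m in matchings)
    n_pred = sum(m.n_predicted for m in matchings)
    n_com = sum(len(m.commissions) for m in matchings)
    n_om = sum(len(m.omissions) for m in matchings)
    if n_lab == 0:
        raise ValueError("no labelled trees in any plot")

    per_class: dict[str, dict] = {}
    for label, *_ in AREA_CLASSES:
        c = {k: sum(m.per_class_counts[label][k] for m in matchings)
             for k in ("n_labelled", "n_commission", "n_omission")}
        if c["n_labelled"]:
            c["commission_rate"] = c["n_commission"] / c["n_labelled"]
            c["omission_rate"] = c["n_omission"] / c["n_labelled"]
        else:
            c["commission_rate"] = c["omission_rate"] = None
        per_class[label] = c

    return ErrorRates(
        n_labelled=n_lab,
        n_predicted=n_pred,
        n_commission=n_com,
        n_omission=n_om,
        commission_rate=n_com / n_lab,
        omission_rate=n_om / n_lab,
        net_rate=(n_com - n_om) / n_lab,
        commission_rate_predicted=n_com / n_pred if n_pred else float("nan"),
        per_class=per_class,
    )


def area_rmse(matching: MatchingResult) -> float:
    """Per-tree RMSE of predicted crown area (m²) over labelled crowns.

    Matched pairs contribute the area difference; missed trees contribute
    their full labelled area as the error.  Commissions do not enter (the
    reference population is the labelled trees).
    """
    if matching.n_labelled == 0:
        raise ValueError("area RMSE undefined without labelled crowns")
    errs = [
        matching.predicted_areas[pi] - matching.labelled_areas[li]
        for li, pi, _ in matching.pairs
    ]
    errs += [matching.labelled_areas[i] for i in matching.omissions]
    return float(np.sqrt(np.mean(np.square(errs))))


def _circle(x: float, y: float, area: float) -> Polygon:
    return Point(x, y).buffer(math.sqrt(area / math.pi), quad_segs=16)


def sample_eval_plots(
    rainfall,
    crowns: pd.DataFrame,
    n_plots: int,
    plot_size: tuple[float, float] = (256.0, 128.0),
    wet_bias: float = 0.8,
    rain_threshold: float = 200.0,
    seed: int | None = None,
    drop_empty: bool = True,
) -> list[EvaluationPlot]:
    """Randomly place evaluation plots, biased towards the wetter region.

    Each plot is drawn on the wet side (rainfall ≥ ``rain_threshold``) with
    probability ``wet_bias``, mirroring evaluation designs that oversample
    where the trees are.  Plots devoid of vegetation are dropped when
    ``drop_empty`` (the returned list may then be shorter than ``n_plots``).
    If the landscape lies entirely on one side of the threshold the bias
    degrades gracefully to sampling the available side.

    The labelled crowns of a plot are the landscape crowns whose centroids
    fall inside it; predictions start as perfect copies (callers or fixture
    generators plant errors on top).
    """
    if n_plots <= 0:
        raise ValueError("n_plots must be positive")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = rainfall.bounds
    w, h = plot_size

    from .geo import extract_rainfall  # local import to avoid cycle at import time

    plots = []
    n_dropped = 0
    for pid in range(n_plots):
        want_wet = rng.random() < wet_bias
        centre = None
        for _ in range(200):
            x = rng.uniform(xmin + w / 2, xmax - w / 2)
            y = rng.uniform(ymin + h / 2, ymax - h / 2)
            p = float(extract_rainfall(rainfall, [(x, y)])[0])
            if p == rainfall.nodata:
                continue
            if (p >= rain_threshold) == want_wet:
                centre = (x, y, p)
                break
        if centre is None:
            # landscape has no cells on the requested side: degrade gracefully
            logger.warning(
                "no location with rainfall %s %g mm found; sampling unbiased",
                ">=" if want_wet else "<", rain_threshold,
            )
            x = rng.uniform(xmin + w / 2, xmax - w / 2)
            y = rng.uniform(ymin + h / 2, ymax - h / 2)
            centre = (x, y, float(extract_rainfall(rainfall, [(x, y)])[0]))
        x, y, p = centre
        inside = crowns[
            (crowns["x"] >= x - w / 2) & (crowns["x"] < x + w / 2)
            & (crowns["y"] >= y - h / 2) & (crowns["y"] < y + h / 2)
        ]
        if drop_empty and not len(inside):
            n_dropped += 1
            continue
        labelled = {
            int(r.id): _circle(r.x, r.y, r.crown_area_m2)
            for r in inside.itertuples()
        }
        plots.append(
            EvaluationPlot(
                plot_id=pid,
                labelled=labelled,
                predicted=dict(labelled),
                rainfall=p,
            )
        )
    if n_dropped:
        logger.info("dropped %d evaluation plots devoid of vegetation", n_dropped)
    return plots
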