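"""Uncertainty budget for crown-area carbon accounting.

Two independent error sources are combined in quadrature:

* **allometric uncertainty** — how well the power laws predict mass on data
  they were not fitted to, measured by repeated 80/20 random subsampling of
  the destructive-sampling sets: fit on 80%, compare mean observed vs mean
  predicted mass on the held-out 20%, combine the three component errors in
  quadrature, normalise by the held-out mean total mass, and average over
  repetitions (δ̄_allometric);
* **crown-area mapping uncertainty** (δ_area) — the relative error of the
  segmentation's total predicted crown area against hand-labelled truth.

The total relative uncertainty is ``δ = sqrt(δ_area² + δ̄_allometric²)``,
which treats the two sources as independent multiplicative perturbations
and neglects the interaction term.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .allometry import FieldSampleSet, fit_component_model, predict_component_mass

__all__ = [
    "UncertaintyReport",
    "subsample_component_delta",
    "component_quadrature",
    "allometric_uncertainty",
    "crown_area_relative_error",
    "crown_area_relative_error_per_plot",
    "total_uncertainty",
]

logger = logging.getLogger(__name__)


@dataclass
class UncertaintyReport:
    """Result of the subsampling uncertainty procedure (fractions, not %)."""

    delta_w: float = float("nan")
    delta_f: float = float("nan")
    delta_r: float = float("nan")
    delta_allometric_abs: float = float("nan")
    mu_mass: float = float("nan")
    delta_allometric_rel_per_rep: list = field(default_factory=list)
    delta_allometric_rel_mean: float = float("nan")
    delta_area: float = float("nan")
    delta_total: float = float("nan")
    n_reps: int = 0
    seed: int | None = None

    def with_area_error(self, delta_area: float) -> "UncertaintyReport":
        """Return a copy completed with δ_area and the combined δ."""
        out = UncertaintyReport(**asdict(self))
        out.delta_area = float(delta_area)
        out.delta_total = total_uncertainty(delta_area, self.delta_allometric_rel_mean)
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def summary(self) -> str:
        lines = [
            "Carbon uncertainty budget",
            f"  allometric (mean of {self.n_reps} reps): "
            f"{100 * self.delta_allometric_rel_mean:.1f}%",
        ]
        if np.isfinite(self.delta_area):
            lines.append(f"  crown-area mapping:             {100 * self.delta_area:.1f}%")
            lines.append(f"  combined (quadrature):          {100 * self.delta_total:.1f}%")
        return "\n".join(lines)


def subsample_component_delta(
    samples: FieldSampleSet,
    train_fraction: float = 0.8,
    rng: np.random.Generator | int | None = None,
    warn_small: bool = True,
) -> tuple[float, float]:
    """One 80/20 subsampling round for a single component.

    Fits the power law on a random ``train_fraction`` of the records and, on
    the held-out validation records, returns ``(Δ, μ)`` where ``μ`` is the
    mean observed mass, ``μ̂`` the mean predicted mass from the refitted
    model, and ``Δ = |μ − μ̂|`` the absolute error in kg.
    """
    n = len(samples)
    if n < 5:
        raise ValueError(f"need at least 5 samples for an 80/20 split, got {n}")
    rng = np.random.default_rng(rng)
    idx = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 2), n - 1)  # keep both splits non-empty
    train, val = idx[:n_train], idx[n_train:]
    if val.size < 8 and warn_small:
        logger.warning(
            "component %r: only %d validation samples this repetition",
            samples.component, val.size,
        )
    model = fit_component_model(
        areas=samples.areas[train], masses=samples.masses[train],
        component=samples.component,
    )
    mu = float(np.mean(samples.masses[val]))
    mu_hat = float(np.mean(predict_component_mass(model, samples.areas[val])))
    return abs(mu - mu_hat), mu


def component_quadrature(delta_f: float, delta_w: float, delta_r: float) -> float:
    """Combine the three absolute component errors assuming independence."""
    if min(delta_f, delta_w, delta_r) < 0:
        raise ValueError("absolute errors must be non-negative")
    return float(np.sqrt(delta_f**2 + delta_w**2 + delta_r**2))


def allometric_uncertainty(
    wood: FieldSampleSet,
    foliage: FieldSampleSet,
    root: FieldSampleSet,
    n_reps: int = 10,
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> UncertaintyReport:
    """Repeated-subsampling estimate of the relative allometric uncertainty.

    Per repetition each component set is split 80/20 independently, giving
    absolute errors Δ_w, Δ_f, Δ_r and validation means μ_w, μ_f, μ_r.  The
    repetition's relative uncertainty is
    ``sqrt(Δ_f² + Δ_w² + Δ_r²) / (μ_w + μ_f + μ_r)`` and the report carries
    the per-repetition values and their mean δ̄_allometric.

    A single master seed drives one stream of splits, so the first
    repetitions of runs with the same seed coincide regardless of ``n_reps``.
    """
    rng = np.random.default_rng(seed)
    rel = []
    last = {}
    for rep in range(n_reps):
        deltas, mus = {}, {}
        for s in (wood, foliage, root):
            deltas[s.component], mus[s.component] = subsample_component_delta(
                s, train_fraction=train_fraction, rng=rng, warn_small=rep == 0
            )
        d_abs = component_quadrature(deltas["foliage"], deltas["wood"], deltas["root"])
        mu_mass = mus["wood"] + mus["foliage"] + mus["root"]
        rel.append(d_abs / mu_mass)
        last = {"deltas": deltas, "d_abs": d_abs, "mu_mass": mu_mass}
    return UncertaintyReport(
        delta_w=last["deltas"]["wood"],
        delta_f=last["deltas"]["foliage"],
        delta_r=last["deltas"]["root"],
        delta_allometric_abs=last["d_abs"],
        mu_mass=last["mu_mass"],
        delta_allometric_rel_per_rep=[float(r) for r in rel],
        delta_allometric_rel_mean=float(np.mean(rel)),
        n_reps=n_reps,
        seed=seed,
    )


def crown_area_relative_error(labelled_total: float, predicted_total: float) -> float:
    """Relative crown-area mapping error from pooled area totals (m²)."""
    if labelled_total <= 0:
        raise ValueError("labelled total area must be positive")
    return abs(predicted_total - labelled_total) / labelled_total


def crown_area_relative_error_per_plot(
    labelled_totals: Sequence[float], predicted_totals: Sequence[float]
) -> float:
    """Mean over plots of the per-plot relative crown-area error.

    Alternative estimator to the pooled-totals one: weights every evaluation
    plot equally instead of every m² of crown.
    """
    lab = np.asarray(labelled_totals, dtype=float)
    pred = np.asarray(predicted_totals, dtype=float)
    if lab.shape != pred.shape or lab.ndim != 1 or lab.size == 0:
        raise ValueError("need equal-length non-empty per-plot totals")
    if np.any(lab <= 0):
        raise ValueError("labelled plot totals must be positive")
    return float(np.mean(np.abs(pred - lab) / lab))


def total_uncertainty(delta_area: float, delta_allometric: float) -> float:
    """Combined relative carbon uncertainty: quadrature of the two sources."""
    if delta_area < 0 or delta_allometric < 0:
        raise ValueError("relative uncertainties must be non-negative")
    return float(np.sqrt(delta_area**2 + delta_allometric**2))
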