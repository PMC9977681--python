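"""End-to-end orchestration: generate/ingest → allometry → zonation →
aggregation → evaluation → uncertainty → image selection.

The pipeline is configured by a single declarative :class:`PipelineConfig`
(loadable from YAML).  When input paths are given, crowns/rainfall/field
samples/catalog are read from disk; otherwise the synthetic generators
produce them from the configured seeds, so a complete run works offline.

Every run writes the per-tree, per-cell and per-zone products plus a
machine-readable ``report.json`` whose numbers are all re-derivable from
the written files; identical configs (and seeds) reproduce every output
byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import allometry, crown_eval, geo, io, mosaic, synthetic, uncertainty

__all__ = ["PipelineConfig", "PipelineError", "validate_inputs", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run.

    Leave the input paths as None to generate synthetic inputs from the
    seeds; set them to ingest real data products.
    """

    out_dir: str = "sahelcarbon_out"
    # inputs (None -> synthetic)
    crowns_path: str | None = None
    rainfall_path: str | None = None
    field_samples_path: str | None = None
    catalog_path: str | None = None
    # synthetic generation
    seed: int = 0
    landscape: dict = field(default_factory=dict)
    field_samples: dict = field(default_factory=dict)
    catalog_size: int = 500
    # allometry
    use_fitted_models: bool = False
    carbon_fraction: float = allometry.CARBON_FRACTION
    min_crown_area: float = allometry.MIN_CROWN_AREA_M2
    # aggregation
    cell_size: float = 100.0
    # evaluation fixture
    eval_n_true: int = 1000
    eval_commission_rate: float = 0.049
    eval_omission_rate: float = 0.027
    # uncertainty
    n_reps: int = 10
    train_fraction: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def validate_inputs(config: PipelineConfig) -> list[dict[str, str]]:
    """Pre-flight checks; returns diagnostics, each 'warning' or 'fatal'."""
    diags: list[dict[str, str]] = []
    for name in ("crowns_path", "rainfall_path", "field_samples_path", "catalog_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            diags.append({"level": "fatal", "message": f"{name} does not exist: {p}"})
    if config.crowns_path and Path(config.crowns_path).exists():
        crowns = io.read_crowns_geojson(config.crowns_path)
        bad = crowns[crowns["crown_area_m2"] <= 0] if len(crowns) else crowns
        for cid in (bad["id"].tolist() if len(bad) else []):
            diags.append(
                {"level": "fatal", "message": f"crown feature id {cid} has non-positive area"}
            )
    if config.rainfall_path and Path(config.rainfall_path).exists():
        text = Path(config.rainfall_path).read_text().lower()
        if "nodata_value" not in text:
            diags.append(
                {"level": "warning",
                 "message": "rainfall raster has no NODATA_value tag; "
                            f"assuming sentinel {geo.NODATA}"}
            )
    if config.field_samples_path and Path(config.field_samples_path).exists():
        cols = set(pd.read_csv(config.field_samples_path, nrows=0).columns)
        missing = {"component", "crown_area_m2", "mass_kg"} - cols
        if missing:
            diags.append(
                {"level": "fatal",
                 "message": f"field sample CSV missing columns {sorted(missing)}"}
            )
    if not float(config.seed) == int(config.seed):
        diags.append({"level": "fatal", "message": "seed must be an integer"})
    return diags


def _stage(name: str):
    """Log a stage's wall time; re-raise its errors tagged with the stage."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs", name, dt)
                if not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Returns the report also written to ``report.json``.
    """
    diags = validate_inputs(config)
    fatal = [d for d in diags if d["level"] == "fatal"]
    if fatal:
        raise PipelineError("validate", "; ".join(d["message"] for d in fatal))
    for d in diags:
        logger.warning("%s", d["message"])

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    with _stage("ingest"):
        if config.rainfall_path:
            rainfall = io.read_ascii_grid(config.rainfall_path)
        else:
            rainfall = None
        if config.crowns_path:
            crowns = io.read_crowns_geojson(config.crowns_path)
            if rainfall is None:
                raise ValueError("crowns ingested without a rainfall raster")
        else:
            ls_cfg = synthetic.LandscapeConfig(
                seed=int(seeds[0]), **config.landscape
            )
            rainfall, crowns = synthetic.gen_landscape(ls_cfg)
        if config.field_samples_path:
            samples = io.read_field_samples_csv(config.field_samples_path)
        else:
            fs_cfg = synthetic.FieldSampleConfig(
                seed=int(seeds[1]), **config.field_samples
            )
            samples = synthetic.gen_field_samples(fs_cfg)
        if config.catalog_path:
            catalog = pd.read_csv(config.catalog_path)
        else:
            catalog = synthetic.gen_image_catalog(config.catalog_size, seed=int(seeds[2]))

    with _stage("fit"):
        fitted = {c: allometry.fit_component_model(s) for c, s in samples.items()}
        models = fitted if config.use_fitted_models else allometry.default_models()
        io.write_models_json(fitted, out / "models_fitted.json")
        io.write_models_json(models, out / "models_used.json")
        io.write_field_samples_csv(samples, out / "field_samples.csv")

    with _stage("allometry"):
        crowns = crowns[crowns["crown_area_m2"] > config.min_crown_area].copy()
        crowns = allometry.add_carbon_estimates(
            crowns, models=models, carbon_fraction=config.carbon_fraction
        )

    with _stage("zonation"):
        if "rainfall" not in crowns or crowns["rainfall"].isna().all():
            pts = crowns[["x", "y"]].to_numpy() if len(crowns) else np.empty((0, 2))
            crowns["rainfall"] = geo.extract_rainfall(rainfall, pts)
            crowns["zone"] = [geo.classify_zone(p) for p in crowns["rainfall"]]
        io.write_crowns_geojson(crowns, out / "crowns.geojson")
        io.write_ascii_grid(
            rainfall.grid, rainfall.x_origin, rainfall.y_origin,
            rainfall.cell_size, out / "rainfall.asc", nodata=rainfall.nodata,
        )

    with _stage("aggregation"):
        grid, gx, gy = geo.carbon_density_grid(
            crowns, rainfall.bounds, cell_size=config.cell_size
        )
        io.write_ascii_grid(grid, gx, gy, config.cell_size, out / "carbon_density.asc")
        land = geo.zone_land_areas(rainfall)
        summaries = geo.zonal_summary(crowns, zone_land_area_ha=land)
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(
            out / "zone_summary.csv", index=False
        )

    with _stage("evaluation"):
        plots = synthetic.gen_eval_fixture(
            config.eval_n_true, config.eval_commission_rate,
            config.eval_omission_rate, seed=int(seeds[3]),
        )
        matchings = [crown_eval.match_crowns(p.labelled, p.predicted) for p in plots]
        rates = crown_eval.error_rates(matchings)
        lab_total = sum(sum(m.labelled_areas.values()) for m in matchings)
        pred_total = sum(sum(m.predicted_areas.values()) for m in matchings)
        delta_area = uncertainty.crown_area_relative_error(lab_total, pred_total)
        rmse = crown_eval.area_rmse(matchings[0])
        (out / "evaluation.json").write_text(json.dumps(asdict(rates), indent=2, sort_keys=True))

    with _stage("uncertainty"):
        report_unc = uncertainty.allometric_uncertainty(
            samples["wood"], samples["foliage"], samples["root"],
            n_reps=config.n_reps, train_fraction=config.train_fraction,
            seed=int(seeds[1]),
        ).with_area_error(delta_area)
        (out / "uncertainty.json").write_text(report_unc.to_json(indent=2))

    with _stage("select-images"):
        catalog.to_csv(out / "catalog.csv", index=False)
        selection = mosaic.select_catalog(catalog) if len(catalog) else pd.DataFrame(
            columns=["tile_id", "image_id", "priority_class", "n_candidates"]
        )
        selection.to_csv(out / "selection.csv", index=False)

    report = {
        "n_trees": int(len(crowns)),
        "total_carbon_kg": float(crowns["carbon_kg"].sum()) if len(crowns) else 0.0,
        "total_mass_kg": float(crowns["mass_total_kg"].sum()) if len(crowns) else 0.0,
        "mean_crown_area_m2": float(crowns["crown_area_m2"].mean()) if len(crowns) else None,
        "zones": {
            s.zone: {
                "n_trees": s.n_trees,
                "mean_carbon_kg": None if np.isnan(s.mean_carbon_kg) else s.mean_carbon_kg,
                "carbon_density_mg_ha": None
                if np.isnan(s.carbon_density_mg_ha) else s.carbon_density_mg_ha,
                "carbon_share_pct": s.carbon_share_pct,
            }
            for s in summaries
        },
        "evaluation": {
            "commission_rate": rates.commission_rate,
            "omission_rate": rates.omission_rate,
            "net_rate": rates.net_rate,
            "area_rmse_m2": rmse,
        },
        "uncertainty": {
            "delta_allometric": report_unc.delta_allometric_rel_mean,
            "delta_area": report_unc.delta_area,
            "delta_total": report_unc.delta_total,
        },
        "mosaic": {
            "n_tiles": int(len(selection)),
            "n_tiles_selected": int(selection["image_id"].notna().sum())
            if len(selection) else 0,
        },
        "config": {k: v for k, v in asdict(config).items()},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
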