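"""End-to-end orchestration: simulate, derive DELVs, fit, map, count.

A single :class:`PipelineConfig` (YAML/JSON-loadable) drives every
stage; one global seed fans out to per-stage seeds by fixed offsets so
that reruns with the same configuration reproduce every numeric output
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ws_io
from .brt import BRTConfig, evaluate, gbm_step, model_to_json, relative_influence, simplify
from .delv import build_delv_stack, sample_delv
from .grid import write_geotiff
from .landscape import (
    DEFAULT_BP_CLASS_PROBS,
    LandscapeConfig,
    RiskSpec,
    default_risk_spec,
    generate_carcass_records,
    generate_density_map,
    generate_landscape,
    generate_turbines,
    simulate_collisions,
)
from .risk import (
    classify_sc,
    count_turbines_by_class,
    point_density_raster,
    predict_cp_raster,
    relative_density,
    strike_susceptibility,
)
from .training import TrainingSet, assemble, downsample_balance, label_turbines

log = logging.getLogger("windstrike")

# seed offsets per stochastic stage (global seed + offset, kept < 2**31)
_SEED_OFFSETS = {
    "landscape": 1,
    "turbines": 2,
    "collisions": 3,
    "carcasses": 4,
    "density": 5,
    "balance": 6,
    "split": 7,
    "brt": 8,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-data pipeline run."""

    out_dir: str = "windstrike_run"
    seed: int = 0
    extent: tuple[float, float] = (20000.0, 20000.0)
    cell_size: float = 100.0
    n_turbines: int = 800
    status_probs: dict = field(
        default_factory=lambda: {"functional": 0.60, "approved": 0.25, "proposed": 0.15}
    )
    risk_spec: RiskSpec = field(default_factory=default_risk_spec)
    quadrant_size: float = 5000.0
    bp_class_probs: tuple = DEFAULT_BP_CLASS_PROBS
    balance_ratio: float = 1.0
    holdout_fraction: float = 0.3
    max_drop: int = 2
    density_bandwidth: float = 1000.0
    brt: BRTConfig = field(default_factory=BRTConfig)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "brt" in data:
            brt = dict(data["brt"])
            if "lr_candidates" in brt:
                brt["lr_candidates"] = tuple(brt["lr_candidates"])
            data["brt"] = BRTConfig(**brt)
        if "risk_spec" in data:
            rs = data["risk_spec"]
            data["risk_spec"] = RiskSpec(
                intercept=rs.get("intercept", 0.0),
                effects={
                    k: [tuple(p) for p in v] for k, v in rs.get("effects", {}).items()
                },
            )
        if "extent" in data:
            data["extent"] = tuple(data["extent"])
        if "bp_class_probs" in data:
            data["bp_class_probs"] = tuple(data["bp_class_probs"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


#: stop points accepted by run_pipeline, in execution order
_STOP_POINTS = ("delv", "simulate", "train", "predict", "susceptibility", "report")


def run_pipeline(config: PipelineConfig, upto: str | None = None) -> dict:
    """Execute the pipeline and write all artifacts plus a JSON manifest.

    ``upto`` stops early at a named point: "delv" (land-use layers and
    distance rasters), "simulate" (plus turbines, outcomes, carcasses
    and the density map), "train" (plus the fitted/simplified model),
    "predict", "susceptibility", or "report"/None (everything).
    """
    if upto is not None and upto not in _STOP_POINTS:
        raise ValueError(f"unknown stop point {upto!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    artifacts: dict[str, Path] = {}
    metrics: dict = {}

    lc = LandscapeConfig(
        extent=config.extent, cell_size=config.cell_size, seed=seed + _SEED_OFFSETS["landscape"]
    )
    grid = lc.grid

    @_stage("simulate")
    def simulate():
        layers = generate_landscape(lc)
        for name, layer in layers.items():
            p = out / f"layer_{name}.geojson"
            ws_io.write_layer_geojson(layer, p)
            artifacts[f"layer_{name}"] = p
        turbines = generate_turbines(
            config.n_turbines, grid, config.status_probs, seed + _SEED_OFFSETS["turbines"]
        )
        density = generate_density_map(
            grid, config.quadrant_size, config.bp_class_probs, seed + _SEED_OFFSETS["density"]
        )
        ws_io.write_density_geojson(density, out / "density.geojson")
        artifacts["density"] = out / "density.geojson"
        return layers, turbines, density

    layers, turbines, density = simulate()

    @_stage("delv")
    def delv():
        stack = build_delv_stack(layers, grid)
        for name, raster in stack.rasters.items():
            p = out / f"delv_{name}.tif"
            write_geotiff(p, raster)
            artifacts[f"delv_{name}"] = p
        return stack

    stack = delv()
    if upto == "delv":
        return _finish(out, seed, config, artifacts, metrics)

    @_stage("collisions")
    def collisions():
        tb = simulate_collisions(
            turbines, stack, config.risk_spec, seed + _SEED_OFFSETS["collisions"]
        )
        ws_io.write_turbines_csv(tb, out / "turbines.csv")
        artifacts["turbines"] = out / "turbines.csv"
        carcasses = generate_carcass_records(tb, seed + _SEED_OFFSETS["carcasses"])
        carcasses.to_csv(out / "carcasses.csv", index=False)
        artifacts["carcasses"] = out / "carcasses.csv"
        return tb, carcasses

    turbines, carcasses = collisions()
    if upto == "simulate":
        return _finish(out, seed, config, artifacts, metrics)

    @_stage("training_set")
    def build_training():
        labels = label_turbines(carcasses)
        features = sample_delv(stack, turbines)
        labeled = assemble(labels, features)
        balanced = downsample_balance(
            labeled, config.balance_ratio, seed + _SEED_OFFSETS["balance"]
        )
        balanced.to_csv(out / "training.csv", index=False)
        artifacts["training"] = out / "training.csv"
        return TrainingSet(balanced)

    training = build_training()

    @_stage("fit")
    def fit():
        rng = np.random.default_rng(seed + _SEED_OFFSETS["split"])
        n = len(training)
        order = rng.permutation(n)
        n_test = int(round(config.holdout_fraction * n))
        test_idx = np.zeros(n, dtype=bool)
        test_idx[order[:n_test]] = True
        train_set = training.subset(~test_idx)
        test_set = training.subset(test_idx)
        cfg = config.brt.replace(seed=seed + _SEED_OFFSETS["brt"])
        full_model = gbm_step(train_set, cfg)
        simplified, drop_report = simplify(full_model, train_set, config.max_drop)
        report = evaluate(simplified, test_set)
        model_to_json(simplified, out / "model.json")
        artifacts["model"] = out / "model.json"
        relative_influence(simplified).to_csv(out / "influence.csv", header=True)
        artifacts["influence"] = out / "influence.csv"
        (out / "evaluation.json").write_text(json.dumps(report.to_dict(), indent=2))
        artifacts["evaluation"] = out / "evaluation.json"
        if len(drop_report):
            drop_report.to_csv(out / "simplification.csv", index=False)
            artifacts["simplification"] = out / "simplification.csv"
        metrics.update(
            {
                "n_training": len(train_set),
                "n_holdout": len(test_set),
                "full_model_nt": full_model.nt,
                "full_model_lr": full_model.lr,
                "simplified_nt": simplified.nt,
                "simplified_lr": simplified.lr,
                "retained_variables": list(simplified.var_names),
                "n_retained": len(simplified.var_names),
                "holdout_auc": report.auc,
                "cv_dev_explained": report.cv_dev_explained,
            }
        )
        return simplified

    model = fit()
    if upto == "train":
        return _finish(out, seed, config, artifacts, metrics)

    @_stage("predict")
    def predict_raster():
        cp = predict_cp_raster(model, stack)
        write_geotiff(out / "collision_potential.tif", cp)
        artifacts["collision_potential"] = out / "collision_potential.tif"
        return cp

    cp = predict_raster()
    if upto == "predict":
        return _finish(out, seed, config, artifacts, metrics)

    @_stage("susceptibility")
    def susceptibility():
        bpd = relative_density(density, grid)
        sc = strike_susceptibility(cp, bpd)
        cls = classify_sc(sc)
        write_geotiff(out / "strike_susceptibility.tif", sc)
        artifacts["strike_susceptibility"] = out / "strike_susceptibility.tif"
        write_geotiff(out / "sc_class.tif", cls)
        artifacts["sc_class"] = out / "sc_class.tif"
        return sc, cls

    sc, cls = susceptibility()
    if upto == "susceptibility":
        return _finish(out, seed, config, artifacts, metrics)

    @_stage("report")
    def report_stage():
        planned = turbines[turbines["status"].isin(["approved", "proposed"])]
        zones = count_turbines_by_class(planned, cls, statuses=["approved", "proposed"])
        zones.to_csv(out / "zone_counts.csv")
        artifacts["zone_counts"] = out / "zone_counts.csv"
        functional = turbines[turbines["status"] == "functional"]
        dens_t = point_density_raster(functional, config.density_bandwidth, grid)
        write_geotiff(out / "turbine_density.tif", dens_t)
        artifacts["turbine_density"] = out / "turbine_density.tif"
        collided = turbines[turbines["outcome"] == 1]
        dens_c = point_density_raster(collided, config.density_bandwidth, grid)
        write_geotiff(out / "collision_density.tif", dens_c)
        artifacts["collision_density"] = out / "collision_density.tif"
        metrics.update(
            {
                "zone_above60_count": zones.above60_count,
                "zone_above60_percent": zones.above60_percent,
                "zone_totals": zones.status_totals,
            }
        )
        return zones

    report_stage()
    return _finish(out, seed, config, artifacts, metrics)


def _finish(out: Path, seed: int, config: PipelineConfig, artifacts, metrics) -> dict:
    manifest = {
        "seed": seed,
        "config": _config_dict(config),
        "metrics": metrics,
        "artifacts": {k: str(p) for k, p in artifacts.items()},
        "hashes": {k: _sha256(p) for k, p in artifacts.items()},
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def _versions() -> dict:
    import importlib.metadata as im

    out = {}
    for pkg in ("windstrike", "numpy", "scipy", "pandas", "shapely"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out
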