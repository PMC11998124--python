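"""One-command orchestration: synth → terrain → features → sample → train
→ assess → predict → postproc.

A :class:`RunConfig` either embeds a synthetic :class:`~wetpot.synth.SceneConfig`
or points at pre-built input rasters. Validation is fail-fast: every
stage's inputs are checked before any stage executes. A run writes all
intermediate products plus a JSON manifest (config, seeds, per-stage wall
time, metrics); re-running with the same config reproduces every
deterministic output byte-identically.

The single global seed expands into per-stage seeds by fixed offsets, so
stages can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import terrain
from .evaluate import accuracy_metrics, score_points
from .features import (FEATURE_NAMES, SoilComponentTable, assemble_stack,
                       compute_pws, sar_percentiles)
from .grids import Grid, GridError, fill_nodata, read_grid, write_grid
from .postprocess import (areal_summary, cluster_stats, cropland_overlay,
                          region_group)
from .sampling import (RFConfig, fit_rf, normalized_importance, predict_map,
                       split_points, stratified_sample)
from .synth import SceneConfig, generate_scene

log = logging.getLogger("wetpot")

# fixed per-stage seed offsets derived from the global seed
_SEED_OFFSETS = {"synth": 0, "sample": 101, "split": 202, "rf": 303}

STAGES = ("synth", "terrain", "features", "sample", "train", "assess",
          "predict", "postproc")

_REQUIRED_INPUTS = ("dem", "soil_table", "soil_units", "labels", "cropland")


@dataclass
class TerrainParams:
    threshold_cells: int = 45_000
    buffer_m: float = 6675.0
    epsilon: float = 1e-4
    outlets_as_channels: bool = True
    fillnodata_max_distance: int = 15


@dataclass
class SamplingParams:
    density_km2_per_point: float = 475.0
    split_fraction: float = 0.7


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    synth: SceneConfig | None = None
    inputs: dict[str, Any] | None = None
    terrain: TerrainParams = field(default_factory=TerrainParams)
    sampling: SamplingParams = field(default_factory=SamplingParams)
    rf: RFConfig = field(default_factory=RFConfig)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _SEED_OFFSETS[stage]) % 2**31

    def validate(self) -> None:
        if (self.synth is None) == (self.inputs is None):
            raise GridError("config must set exactly one of 'synth' and 'inputs'")
        if self.inputs is not None:
            for key in _REQUIRED_INPUTS:
                if key not in self.inputs:
                    raise GridError(f"config field 'inputs.{key}' is required "
                                    "when synth is disabled")
                if not Path(self.inputs[key]).exists():
                    raise GridError(f"inputs.{key}: no such file "
                                    f"{self.inputs[key]!r}")
            sar = self.inputs.get("sar", [])
            if len(sar) < 2:
                raise GridError("config field 'inputs.sar' needs >= 2 "
                                "(vv, vh) raster path pairs")
            for vv, vh in sar:
                for p in (vv, vh):
                    if not Path(p).exists():
                        raise GridError(f"inputs.sar: no such file {p!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {
            "out_dir": raw.get("out_dir", "wetpot_run"),
            "seed": int(raw.get("seed", 0)),
        }
        if "synth" in raw and raw["synth"] is not None:
            synth_kwargs = dict(raw["synth"])
            if "effect_weights" in synth_kwargs:
                synth_kwargs["effect_weights"] = tuple(synth_kwargs["effect_weights"])
            synth_kwargs.setdefault("seed", kwargs["seed"])
            kwargs["synth"] = SceneConfig(**synth_kwargs)
        if "inputs" in raw and raw["inputs"] is not None:
            kwargs["inputs"] = dict(raw["inputs"])
        if "terrain" in raw:
            kwargs["terrain"] = TerrainParams(**raw["terrain"])
        if "sampling" in raw:
            kwargs["sampling"] = SamplingParams(**raw["sampling"])
        if "rf" in raw:
            rf_kwargs = dict(raw["rf"])
            rf_kwargs.setdefault("seed", kwargs["seed"])
            kwargs["rf"] = RFConfig(**rf_kwargs)
        return cls(**kwargs)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_all(cfg: RunConfig, return_state: bool = False) -> dict[str, Any]:
    """Execute every pipeline stage in order and write a run manifest.

    Returns the manifest dict (also written to ``out_dir/manifest.json``),
    or the full in-memory stage state when ``return_state`` is set. Any
    stage failure aborts with the stage name and cause.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": _jsonable({"out_dir": cfg.out_dir, "seed": cfg.seed,
                             "synth": cfg.synth, "inputs": cfg.inputs,
                             "terrain": cfg.terrain, "sampling": cfg.sampling,
                             "rf": cfg.rf}),
        "stage_seeds": {s: cfg.stage_seed(s) for s in _SEED_OFFSETS},
        "python": platform.python_version(),
        "stages": [],
    }
    state: dict[str, Any] = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: starting", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        log.info("stage %s: done in %.2fs", name, dt)
        manifest["stages"].append({"name": name, "wall_time_s": round(dt, 4)})

    # -- synth / load inputs -------------------------------------------------
    def stage_synth():
        if cfg.synth is not None:
            scene_cfg = dataclasses.replace(cfg.synth, seed=cfg.stage_seed("synth"))
            bundle = generate_scene(scene_cfg)
            state["dem"] = bundle.dem
            state["labels"] = bundle.labels
            state["cropland"] = bundle.cropland_30m  # None if dims % 3 != 0
            state["soil_units"] = bundle.soil_map_unit_raster
            state["soil_table"] = bundle.soil_table
            state["sar"] = [(vv, vh) for _, vv, vh in bundle.sar_stack]
            state["threshold_cells"] = scene_cfg.threshold_cells()
            write_grid(bundle.dem, out / "dem.tif")
            write_grid(bundle.labels, out / "labels.tif")
            write_grid(bundle.cropland_30m, out / "cropland.tif")
            write_grid(bundle.soil_map_unit_raster, out / "soil_units.tif")
            bundle.soil_table.to_csv(out / "soil_table.csv")
        else:
            state["dem"] = read_grid(cfg.inputs["dem"])
            state["labels"] = read_grid(cfg.inputs["labels"])
            state["cropland"] = read_grid(cfg.inputs["cropland"])
            state["soil_units"] = read_grid(cfg.inputs["soil_units"])
            state["soil_table"] = SoilComponentTable.from_csv(cfg.inputs["soil_table"])
            state["sar"] = [(read_grid(vv), read_grid(vh))
                            for vv, vh in cfg.inputs["sar"]]
            state["threshold_cells"] = cfg.terrain.threshold_cells

    # -- terrain -------------------------------------------------------------
    def stage_terrain():
        dem = state["dem"]
        if dem.nodata_mask().any():
            dem = fill_nodata(dem, cfg.terrain.fillnodata_max_distance)
        filled = terrain.remove_pits(dem, cfg.terrain.epsilon)
        flow = terrain.dinf_flow_direction(filled)
        acc = terrain.dinf_accumulation(flow)
        channels = terrain.extract_channels(acc, state["threshold_cells"])
        kw = {"outlets_as_channels": cfg.terrain.outlets_as_channels}
        hofd = terrain.distance_down(flow, filled, channels, "horizontal", **kw)
        vofd = terrain.distance_down(flow, filled, channels, "vertical", **kw)
        pofd = terrain.distance_down(flow, filled, channels, "pythagoras", **kw)
        cti = terrain.compute_cti(acc, flow.slope_grid())
        cti_scaled = terrain.smooth_and_scale_cti(cti)
        slope, aspect = terrain.slope_aspect(state["dem"])
        layers = {"Elevation": filled, "Slope": slope, "Aspect": aspect,
                  "CTI": cti_scaled, "HOFD": hofd, "VOFD": vofd, "POFD": pofd}
        state["terrain_layers"] = layers
        for name, g in layers.items():
            write_grid(g, out / f"{name.lower()}.tif")

    # -- features ------------------------------------------------------------
    def stage_features():
        pws = compute_pws(state["soil_units"], state["soil_table"])
        sar = sar_percentiles(state["sar"])
        layers = dict(state["terrain_layers"])
        layers["PWS"] = pws
        layers.update(sar)
        state["stack"] = assemble_stack(layers)
        write_grid(pws, out / "pws.tif")
        for name, g in sar.items():
            write_grid(g, out / f"{name.lower()}.tif")

    # -- sampling ------------------------------------------------------------
    def stage_sample():
        points = stratified_sample(state["labels"],
                                   cfg.sampling.density_km2_per_point,
                                   seed=cfg.stage_seed("sample"),
                                   stack=state["stack"])
        points = split_points(points, cfg.sampling.split_fraction,
                              seed=cfg.stage_seed("split"))
        state["points"] = points
        points.to_csv(out / "points.csv", index=False)

    # -- training ------------------------------------------------------------
    def stage_train():
        rf_cfg = dataclasses.replace(cfg.rf, seed=cfg.stage_seed("rf"))
        train = state["points"][state["points"]["split"] == "train"]
        model = fit_rf(train, rf_cfg)
        state["model"] = model
        imp = normalized_importance(model)
        imp.to_csv(out / "importance.csv", header=True)
        state["importance"] = imp

    # -- assessment ----------------------------------------------------------
    def stage_assess():
        val = state["points"][state["points"]["split"] == "validation"]
        cm = score_points(state["model"], val)
        metrics = accuracy_metrics(cm)
        state["metrics"] = metrics
        record = dict(metrics)
        record["confusion"] = {"n11": cm.n11, "n10": cm.n10,
                               "n01": cm.n01, "n00": cm.n00}
        (out / "metrics.json").write_text(json.dumps(_jsonable(record), indent=2))

    # -- prediction ----------------------------------------------------------
    def stage_predict():
        pwa = predict_map(state["model"], state["stack"])
        state["pwa"] = pwa
        write_grid(pwa, out / "pwa.tif")

    # -- post-processing -----------------------------------------------------
    def stage_postproc():
        pwa = state["pwa"]
        clusters, table = region_group(pwa)
        stats = cluster_stats(table, pwa.cell_size)
        region = pwa.like(np.ones(pwa.shape, dtype=np.int32))
        summary = areal_summary(pwa, region)
        if state["cropland"] is not None:
            pwac = cropland_overlay(pwa, state["cropland"])
            pwac_summary = areal_summary(pwac, region)
            summary["pwac_km2"] = pwac_summary["class_km2"]
            summary["pwac_pct"] = pwac_summary["class_pct"]
            write_grid(pwac, out / "pwac.tif")
        write_grid(clusters, out / "clusters.tif")
        table.to_csv(out / "clusters.csv", index=False)
        (out / "stats.json").write_text(json.dumps(_jsonable(stats.as_dict()),
                                                   indent=2))
        summary.to_csv(out / "summary.csv", index=False)
        state["cluster_stats"] = stats
        state["summary"] = summary

    for name, fn in zip(STAGES, (stage_synth, stage_terrain, stage_features,
                                 stage_sample, stage_train, stage_assess,
                                 stage_predict, stage_postproc)):
        run_stage(name, fn)

    manifest["metrics"] = _jsonable(state["metrics"])
    manifest["cluster_stats"] = _jsonable(state["cluster_stats"].as_dict())
    manifest["areal_summary"] = _jsonable(state["summary"].to_dict("records"))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    state["manifest"] = manifest
    return state if return_state else manifest
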