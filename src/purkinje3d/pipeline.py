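"""End-to-end orchestration and the pipeline configuration.

``PipelineConfig`` mirrors every stage's parameter type in a nested
structure that round-trips through YAML; unknown keys are rejected so
that typos fail loudly.  ``run_all`` chains
phantom → detect → layer-population selection → refine → layer surface
→ evaluation and records a run manifest (config hash, seed, package
versions, wall time, artifact paths).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import typing
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, layer as layer_mod, phantom as phantom_mod
from .refinement import RefinementParams, cells_to_table, refine_cells
from .segmentation import (SegmentationParams, detect_cells, objects_to_table)
from .vesselness import CELL_MODE, DENDRITE_MODE, FrangiParams
from .volumes import Volume, normalise, read_volume, write_volume

log = logging.getLogger("purkinje3d")

__all__ = ["NormaliseParams", "EvaluationParams", "PipelineConfig",
           "run_all", "load_config", "dump_config"]


@dataclass(frozen=True)
class NormaliseParams:
    lo_pct: float = 0.1
    hi_pct: float = 99.9


@dataclass(frozen=True)
class EvaluationParams:
    match_radius_um: float = 10.0


@dataclass
class PipelineConfig:
    seed: int = 42
    normalise: NormaliseParams = field(default_factory=NormaliseParams)
    phantom: phantom_mod.PhantomConfig = field(default_factory=phantom_mod.PhantomConfig)
    cell_mode: FrangiParams = field(default_factory=lambda: CELL_MODE)
    dendrite_mode: FrangiParams = field(default_factory=lambda: DENDRITE_MODE)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    refinement: RefinementParams = field(default_factory=RefinementParams)
    layer: layer_mod.LayerParams = field(default_factory=layer_mod.LayerParams)
    evaluation: EvaluationParams = field(default_factory=EvaluationParams)


# --- config (de)serialisation ------------------------------------------------

def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_dict(x) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _from_dict(cls, d: dict):
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(d).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        ftype = typing.get_type_hints(cls)[name]
        if dataclasses.is_dataclass(ftype):
            kwargs[name] = _from_dict(ftype, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def dump_config(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(_to_dict(cfg), sort_keys=False)


def load_config(source: str | Path | dict | None = None,
                overrides: dict[str, object] | None = None) -> PipelineConfig:
    """Build a PipelineConfig from YAML (path or dict) plus dot-path overrides."""
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        data = yaml.safe_load(Path(source).read_text()) or {}
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return _from_dict(PipelineConfig, data)


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]


# --- stages ------------------------------------------------------------------

def run_phantom(cfg: PipelineConfig, outdir: Path) -> dict:
    pcfg = dataclasses.replace(cfg.phantom, rng_seed=cfg.seed)
    volume, truth = phantom_mod.generate(pcfg)
    outdir.mkdir(parents=True, exist_ok=True)
    vol_path = write_volume(volume, outdir / "phantom.tif")
    truth_path = phantom_mod.truth_to_csv(truth, outdir / "truth.csv")
    log.info("phantom: %d cells, %d vessels, %d corpora",
             truth.n_cells, (truth.df["class"] == "vessel").sum(),
             (truth.df["class"] == "corpus").sum())
    return {"volume": volume, "truth": truth,
            "artifacts": {"phantom_volume": str(vol_path),
                          "truth_table": str(truth_path)}}


def run_detect(cfg: PipelineConfig, volume: Volume, outdir: Path) -> dict:
    v = normalise(volume, cfg.normalise.lo_pct, cfg.normalise.hi_pct)
    objs, _response = detect_cells(v, frangi=cfg.cell_mode, seg=cfg.segmentation)
    outdir.mkdir(parents=True, exist_ok=True)
    table = objects_to_table(objs)
    obj_path = outdir / "objects.csv"
    table.to_csv(obj_path, index=False)
    counts = table["cls"].value_counts().to_dict()
    log.info("detect: %d objects (%s)", len(objs),
             ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    return {"volume_norm": v, "objects": objs,
            "artifacts": {"object_table": str(obj_path)}}


def run_all(cfg: PipelineConfig, outdir: str | Path,
            input_volume: Volume | None = None,
            truth: "phantom_mod.PhantomTruth | None" = None) -> dict:
    """Full chain; generates the phantom unless an input volume is given."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict[str, str] = {}
    stages_done: list[str] = []
    try:
        if input_volume is None:
            ph = run_phantom(cfg, outdir)
            volume, truth = ph["volume"], ph["truth"]
            artifacts.update(ph["artifacts"])
            stages_done.append("phantom")
        else:
            volume = input_volume

        det = run_detect(cfg, volume, outdir)
        artifacts.update(det["artifacts"])
        stages_done.append("detect")
        v = det["volume_norm"]
        objs = det["objects"]
        candidates = [o for o in objs if o.cls == "cell_candidate"]

        cand_centroids = np.array([o.centroid for o in candidates]).reshape(-1, 3)
        kept_centroids, keep = layer_mod.select_layer_population(
            cand_centroids, cfg.layer, v.shape)
        kept = [o for o, k in zip(candidates, keep) if k]
        log.info("layer population: kept %d of %d candidates",
                 len(kept), len(candidates))
        stages_done.append("select_layer_population")

        cells = refine_cells(v, kept, cfg.refinement)
        cell_table = cells_to_table(cells)
        cells_path = outdir / "cells.csv"
        cell_table.to_csv(cells_path, index=False)
        artifacts["cell_table"] = str(cells_path)
        stages_done.append("refine")
        mean_cell_volume = (float(cell_table["volume_um3"].mean())
                            if len(cell_table) else None)

        roi_volume_mm3 = float(np.prod(v.shape)) * (v.voxel_len_um / 1000.0) ** 3
        summary: dict = {"n_cells": len(cells),
                         "mean_cell_volume_um3": mean_cell_volume}
        try:
            surface = layer_mod.extract_layer_surface(
                kept_centroids, cfg.layer, v.shape, v.voxel_len_um)
            surface = layer_mod.local_density(
                surface, kept_centroids, cfg.layer,
                roi_volume_mm3=roi_volume_mm3,
                mean_cell_volume_um3=mean_cell_volume)
            ply_path = layer_mod.write_ply(surface, outdir / "layer.ply")
            artifacts["layer_mesh"] = str(ply_path)
            summary.update(surface.summary)
            stages_done.append("layer")
        except ValueError as exc:
            log.warning("layer surface skipped: %s", exc)
            summary["layer_error"] = str(exc)

        report = None
        if truth is not None:
            detected_um = kept_centroids * v.voxel_len_um
            truth_um = truth.centroids_vox("cell") * v.voxel_len_um
            report = evaluation.detection_error(
                detected_um, truth_um, cfg.evaluation.match_radius_um)
            summary["detection_error"] = report.as_dict()
            stages_done.append("evaluate")

        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=1, default=float))
        artifacts["summary"] = str(summary_path)
        status = "ok"
    finally:
        manifest = {
            "config_hash": config_hash(cfg),
            "seed": cfg.seed,
            "versions": _versions(),
            "wall_time_s": round(time.time() - t0, 2),
            "stages_completed": stages_done,
            "artifacts": artifacts,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"summary": summary, "report": report, "artifacts": artifacts,
            "manifest": manifest, "cells": cells, "surface_summary": summary}


def _versions() -> dict:
    import scipy
    import skimage

    from . import __version__
    return {"purkinje3d": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "scikit-image": skimage.__version__}
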