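"""End-to-end orchestration of synthetic-study runs.

A YAML configuration (schema-validated; unknown keys rejected) selects the
stages to run (``synth`` -> ``tfm`` -> ``stats``), supplies gel and analysis
parameters and a single global seed, and names an output directory.  Each
stage writes its outputs before the next starts, and a run manifest (config
hash, input checksums, per-stage timings, warnings) is written atomically at
the end so runs can be reproduced and verified.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from . import __version__
from .errors import ConfigError, DataError
from . import synthetic, tfm as tfm_mod, stats as stats_mod

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RunSection(_Strict):
    seed: int = 0
    out_dir: str = "jmx_out"


class GelSection(_Strict):
    youngs_modulus_pa: float = 16400.0
    poisson_ratio: float = 0.5

    @field_validator("youngs_modulus_pa")
    @classmethod
    def _positive_e(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("youngs_modulus_pa must be > 0")
        return v

    @field_validator("poisson_ratio")
    @classmethod
    def _nu_range(cls, v: float) -> float:
        if not 0.0 <= v <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        return v


class SynthSection(_Strict):
    image_size_px: int = 256
    pixel_size_um: float = 0.65
    footprint_radius_um: float = 38.0
    magnitude_pa: float = 800.0
    pattern: Literal["contractile_dipole", "ring", "random_balanced"] = \
        "random_balanced"
    n_beads: int = 900
    drift_px: tuple[float, float] = (1.5, -1.0)
    gels: list[str] = ["gel1", "gel2"]
    conditions: dict[str, float] = {"control": 1.0, "treated": 1.2247}
    islands_per_condition: int = 2
    noise_gaussian_sd: float = 0.02


class TFMSection(_Strict):
    grid_spacing_um: float = 2.6
    window_px: int = 32
    overlap: float = 0.5
    regularization: float = 0.0
    ratio_threshold: float = 0.10
    size_range_um2: tuple[float, float] | None = None


class StatsSection(_Strict):
    control_condition: str = "control"


class RunConfig(_Strict):
    run: RunSection = RunSection()
    stages: list[Literal["synth", "tfm", "stats"]] = ["synth", "tfm", "stats"]
    gel: GelSection = GelSection()
    synth: SynthSection = SynthSection()
    tfm: TFMSection = TFMSection()
    stats: StatsSection = StatsSection()


class RunManifest(BaseModel):
    tool_version: str
    config_hash: str
    input_checksums: dict[str, str]
    stage_timings_s: dict[str, float]
    warnings: list[str]


def validate_config(path: str | Path) -> RunConfig:
    """Load, schema-check and default a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _island_seed(base: int, counter: int) -> int:
    """Counter-based per-scene seed fan-out (stage-order independent)."""
    return (base * 100003 + counter * 7919 + 1) % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_synth(cfg: RunConfig, out: Path, checksums: dict) -> None:
    s = cfg.synth
    gel = tfm_mod.GelProperties(cfg.gel.youngs_modulus_pa,
                                cfg.gel.poisson_ratio)
    counter = 0
    rows = []
    for gel_id in s.gels:
        for cond, scale in s.conditions.items():
            for i in range(s.islands_per_condition):
                seed = _island_seed(cfg.run.seed, counter)
                counter += 1
                scene = synthetic.SceneParams(
                    image_size_px=(s.image_size_px, s.image_size_px),
                    pixel_size_um=s.pixel_size_um, rng_seed=seed,
                    noise_model=synthetic.NoiseModel(
                        gaussian_sd=s.noise_gaussian_sd))
                traction = synthetic.make_island_traction(
                    scene, s.footprint_radius_um, s.magnitude_pa * scale,
                    pattern=s.pattern)
                stressed, relaxed, truth = synthetic.render_bead_pair(
                    traction, gel, scene, n_beads=s.n_beads,
                    drift_px=s.drift_px)
                mask = synthetic.island_footprint_mask(
                    scene, s.footprint_radius_um)
                d = out / "synth" / gel_id / cond / f"island{i}"
                d.mkdir(parents=True, exist_ok=True)
                synthetic.write_image(d / "stressed.tif", stressed)
                synthetic.write_image(d / "relaxed.tif", relaxed)
                tifffile.imwrite(str(d / "island_mask.tif"),
                                 mask.astype(np.uint8) * 255)
                synthetic.save_truth(truth, d)
                rows.append(dict(gel_id=gel_id, condition_id=cond,
                                 island=i, seed=seed, dir=str(d)))
    pd.DataFrame(rows).to_csv(out / "synth" / "scenes.csv", index=False)


def _stage_tfm(cfg: RunConfig, out: Path, checksums: dict) -> list:
    scenes_csv = out / "synth" / "scenes.csv"
    if not scenes_csv.exists():
        raise DataError("tfm stage requires synth outputs (scenes.csv)")
    checksums[str(scenes_csv)] = _sha256(scenes_csv)
    scenes = pd.read_csv(scenes_csv)
    gel = tfm_mod.GelProperties(cfg.gel.youngs_modulus_pa,
                                cfg.gel.poisson_ratio)
    records = []
    for _, row in scenes.iterrows():
        d = Path(row["dir"])
        stressed = tifffile.imread(str(d / "stressed.tif")).astype(float)
        relaxed = tifffile.imread(str(d / "relaxed.tif")).astype(float)
        mask = tifffile.imread(str(d / "island_mask.tif")) > 0
        for f in ("stressed.tif", "relaxed.tif", "island_mask.tif"):
            checksums[str(d / f)] = _sha256(d / f)
        rec, _, _ = tfm_mod.analyze_island(
            stressed, relaxed, mask, gel,
            pixel_size_um=cfg.synth.pixel_size_um,
            spacing_um=cfg.tfm.grid_spacing_um,
            window_px=cfg.tfm.window_px, overlap=cfg.tfm.overlap,
            regularization=cfg.tfm.regularization,
            island_id=f"{row.gel_id}/{row.condition_id}/{row.island}",
            gel_id=row.gel_id, condition_id=row.condition_id)
        records.append(rec)
    tfm_mod.filter_islands(records, ratio_threshold=cfg.tfm.ratio_threshold,
                           size_range_um2=cfg.tfm.size_range_um2)
    df = pd.DataFrame([
        dict(island_id=r.island_id, gel_id=r.gel_id,
             condition_id=r.condition_id, area_um2=r.area_um2,
             strain_energy_pj=r.strain_energy_j * 1e12,
             energy_density_j_per_m2=r.energy_density_j_per_m2,
             equilibrium_ratio=r.equilibrium_ratio, retained=r.retained,
             discard_reasons="; ".join(r.discard_reasons))
        for r in records])
    (out / "tfm").mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "tfm" / "islands.csv", index=False)
    return records


def _stage_stats(cfg: RunConfig, out: Path, checksums: dict) -> None:
    islands_csv = out / "tfm" / "islands.csv"
    if not islands_csv.exists():
        raise DataError("stats stage requires tfm outputs (islands.csv)")
    checksums[str(islands_csv)] = _sha256(islands_csv)
    df = pd.read_csv(islands_csv)
    records = [
        tfm_mod.IslandRecord(
            island_id=r.island_id, island_mask=None, area_um2=r.area_um2,
            strain_energy_j=r.strain_energy_pj * 1e-12,
            energy_density_j_per_m2=r.energy_density_j_per_m2,
            equilibrium_ratio=r.equilibrium_ratio, gel_id=r.gel_id,
            condition_id=r.condition_id, retained=bool(r.retained))
        for r in df.itertuples()]
    summary = tfm_mod.summarize_by_gel(records,
                                       cfg.stats.control_condition)
    (out / "stats").mkdir(parents=True, exist_ok=True)
    summary.per_gel.to_csv(out / "stats" / "per_gel.csv", index=False)
    summary.per_island.to_csv(out / "stats" / "per_island.csv", index=False)
    report = {}
    for cond in sorted(summary.per_island.condition_id.unique()):
        if cond == cfg.stats.control_condition:
            continue
        folds = summary.per_island.query(
            "condition_id == @cond")["fold_of_control"].to_numpy()
        entry = dict(mean_fold=float(folds.mean()),
                     median_fold=float(np.median(folds)),
                     n=int(folds.size))
        if folds.size >= 2:
            rec = stats_mod.signed_rank_vs_standard(folds, 1.0)
            entry["signed_rank_p"] = rec.p_value
            entry["warnings"] = rec.warnings
        else:
            entry["signed_rank_p"] = None
            entry["warnings"] = ["n < 2: signed-rank test not performed"]
        report[cond] = entry
    (out / "stats" / "fold_of_control.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the requested stages in dependency order and write a manifest."""
    out = Path(config.run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = [s for s in ("synth", "tfm", "stats") if s in config.stages]
    timings: dict[str, float] = {}
    checksums: dict[str, str] = {}
    caught: list[str] = []
    stage_fns = {"synth": _stage_synth, "tfm": _stage_tfm,
                 "stats": _stage_stats}
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for stage in order:
            t0 = time.perf_counter()
            stage_fns[stage](config, out, checksums)
            timings[stage] = time.perf_counter() - t0
    caught = [str(w.message) for w in wlist]
    cfg_json = json.dumps(config.model_dump(), sort_keys=True, default=str)
    manifest = RunManifest(
        tool_version=__version__,
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        input_checksums=checksums, stage_timings_s=timings,
        warnings=caught)
    tmp = out / "manifest.json.tmp"
    tmp.write_text(manifest.model_dump_json(indent=1))
    tmp.replace(out / "manifest.json")  # atomic on POSIX
    return manifest
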