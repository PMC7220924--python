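"""Stage orchestration: generator -> TVDI -> RWLR -> ranking -> SEM -> karst.

Each stage reads its inputs from the run directory (or from the configured
external paths), writes its outputs there, and records checksums in the run
manifest, so reruns with the same config and seed are verifiably identical
and stages can be re-executed in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rwlr import __version__
from rwlr.config import ALL_STAGES, RunConfig
from rwlr.dryspell import compute_rwlr, czu_mean_tvdi, detect_dry_spells
from rwlr.errors import ConfigError, RwlrError
from rwlr.importance import all_subsets_rank, collinearity_screen
from rwlr.karst import buffer_zones, compare_zones, pixel_correlation
from rwlr.pathsem import PathSpec, fit_path_model
from rwlr.synthetic import (CzuTable, PrecipSeries, gen_czu_table,
                            gen_global_grid, gen_precip, gen_scene_stack)
from rwlr.tvdi import compute_tvdi, fit_triangle_edges

__all__ = ["RunManifest", "StageError", "run_pipeline", "stage_seed"]

log = logging.getLogger("rwlr.pipeline")

NPP_CANDIDATES = ["rwlr", "soil_n", "sd", "ap", "mat", "pdsi"]
RWLR_CANDIDATES = ["br_si", "br_ca", "br_mg", "br_fe", "br_al"]


class StageError(RwlrError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    version: str = __version__
    seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)
    wall_time: dict[str, float] = field(default_factory=dict)
    failure: dict | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def stage_seed(base_seed: int, stage: str) -> int:
    """Counter-based per-stage seed so stages rerun independently."""
    idx = ALL_STAGES.index(stage)
    return int(np.random.SeedSequence([base_seed, idx]).generate_state(1)[0])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: RunManifest, stage: str, paths: list[Path]) -> None:
    manifest.outputs[stage] = {p.name: _sha256(p) for p in sorted(paths)}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    A stage failure leaves completed outputs in place, records the failure
    in the manifest, writes the manifest, then raises :class:`StageError`.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    manifest = RunManifest(
        config_hash=hashlib.sha256(config.to_yaml().encode()).hexdigest()
    )
    runners = {
        "simulate": _stage_simulate, "tvdi": _stage_tvdi, "rwlr": _stage_rwlr,
        "rank": _stage_rank, "sem": _stage_sem, "karst": _stage_karst,
    }
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        seed = stage_seed(config.seed, stage)
        manifest.seeds[stage] = seed
        t0 = time.perf_counter()
        try:
            paths = runners[stage](config, out, seed, state)
        except Exception as exc:  # noqa: BLE001 - recorded then re-raised
            manifest.failure = {"stage": stage, "error": str(exc)}
            (out / "manifest.json").write_text(manifest.to_json())
            raise StageError(stage, exc) from exc
        manifest.wall_time[stage] = time.perf_counter() - t0
        _record(manifest, stage, paths)
        log.info("stage %s done (%.2fs)", stage, manifest.wall_time[stage])
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: RunConfig, out: Path, seed: int, state: dict) -> list[Path]:
    precip = gen_precip(cfg.n_days, cfg.p_wet_to_wet, cfg.p_dry_to_wet,
                        cfg.mean_depth, seed=seed)
    precip.to_csv(out / "precip.csv")
    stack = gen_scene_stack(
        precip, leakage=cfg.leakage, et_rate=cfg.et_rate,
        noise_sd=cfg.noise_sd, seed=seed + 1,
        shape=(cfg.scene_rows, cfg.scene_cols),
        composite_interval=cfg.composite_interval,
    )
    np.savez(out / "scenes.npz", times=stack.times, ndvi=stack.ndvi,
             lst=stack.lst, moisture=stack.moisture_truth,
             anchor_dry=stack.anchor_dry, anchor_wet=stack.anchor_wet)
    (out / "scenes_meta.json").write_text(json.dumps({
        "edges_truth": stack.edges_truth.to_dict(),
        "grid": {"nrows": stack.grid.nrows, "ncols": stack.grid.ncols,
                 "dx": stack.grid.dx, "dy": stack.grid.dy,
                 "origin_x": stack.grid.origin_x,
                 "origin_y": stack.grid.origin_y},
        "params": stack.params}, indent=2))
    table = gen_czu_table(cfg.n_czu, noise_sd=cfg.czu_noise_sd, seed=seed + 2)
    table.to_csv(out / "czu.csv")
    table.write_truth(out / "czu_truth.json")
    state.update(precip=precip, stack=stack, czu=table)
    return [out / "precip.csv", out / "scenes.npz", out / "scenes_meta.json",
            out / "czu.csv", out / "czu_truth.json"]


def _load_stack(cfg: RunConfig, out: Path, state: dict):
    if "stack" in state:
        return state["stack"]
    npz_path, meta_path = out / "scenes.npz", out / "scenes_meta.json"
    if not (npz_path.exists() and meta_path.exists()):
        raise ConfigError("tvdi/rwlr stages need the simulate stage outputs "
                          "(enable 'simulate' or reuse its run directory)")
    from rwlr.grids import GridSpec
    from rwlr.synthetic import SceneStack
    from rwlr.tvdi import TriangleEdges

    npz = np.load(npz_path)
    meta = json.loads(meta_path.read_text())
    et = meta["edges_truth"]
    stack = SceneStack(
        times=npz["times"], ndvi=npz["ndvi"], lst=npz["lst"],
        moisture_truth=npz["moisture"],
        grid=GridSpec(**meta["grid"]),
        edges_truth=TriangleEdges(
            a=et["a"], b=et["b"], c=et["c"], d=et["d"],
            ndvi_range=tuple(et["ndvi_range"]),
            fit_r2_dry=et["fit_r2_dry"], fit_r2_wet=et["fit_r2_wet"]),
        anchor_dry=npz["anchor_dry"], anchor_wet=npz["anchor_wet"],
        params=meta["params"],
    )
    state["stack"] = stack
    return stack


def _stage_tvdi(cfg: RunConfig, out: Path, seed: int, state: dict) -> list[Path]:
    stack = _load_stack(cfg, out, state)
    scenes, edge_rows = [], []
    for i, t in enumerate(stack.times):
        edges = fit_triangle_edges(
            stack.ndvi[i], stack.lst[i], n_bins=cfg.n_bins,
            edge_percentile=cfg.edge_percentile,
            min_pixels_per_bin=cfg.min_pixels_per_bin, ndvi_min=cfg.ndvi_min,
            ndvi_range=stack.edges_truth.ndvi_range,
        )
        scene = compute_tvdi(stack.ndvi[i], stack.lst[i], edges, time=float(t))
        scenes.append(scene)
        edge_rows.append({"time": float(t), **edges.to_dict(),
                          "clip_fraction": scene.clip_fraction,
                          "mean_tvdi": float(np.nanmean(scene.tvdi))})
    df = pd.DataFrame(edge_rows)
    df["ndvi_range"] = df["ndvi_range"].map(lambda r: f"{r[0]:.4f}:{r[1]:.4f}")
    df.to_csv(out / "edges.csv", index=False)
    state["tvdi_scenes"] = scenes
    return [out / "edges.csv"]


def _stage_rwlr(cfg: RunConfig, out: Path, seed: int, state: dict) -> list[Path]:
    if cfg.precip_csv:
        precip = PrecipSeries.from_csv(cfg.precip_csv)
    elif "precip" in state:
        precip = state["precip"]
    else:
        precip = PrecipSeries.from_csv(out / "precip.csv")
    stack = _load_stack(cfg, out, state)
    if "tvdi_scenes" not in state:
        _stage_tvdi(cfg, out, seed, state)
    scenes = state["tvdi_scenes"]
    spells = detect_dry_spells(precip, min_length=cfg.min_length,
                               wet_threshold=cfg.wet_threshold)
    center = (stack.grid.ncols / 2.0, stack.grid.origin_y
              - stack.grid.nrows / 2.0)
    series = czu_mean_tvdi(scenes, stack.grid, center, cfg.czu_radius,
                           pixel_mask=stack.regular_mask)
    result = compute_rwlr(series, spells, start_date=precip.dates[0],
                          aggregate=cfg.aggregate,
                          min_composites=cfg.min_composites,
                          czu_id=precip.station_id)
    pd.DataFrame([{
        "czu_id": result.czu_id, "rwlr": result.rwlr,
        "n_spells_used": result.n_spells_used,
        "n_composites": int(len(series)), "n_spells_detected": len(spells),
    }]).to_csv(out / "rwlr.csv", index=False)
    state["rwlr_result"] = result
    return [out / "rwlr.csv"]


def _czu_frame(cfg: RunConfig, state: dict) -> pd.DataFrame:
    if cfg.czu_csv:
        return CzuTable.read_csv(cfg.czu_csv)
    if "czu" in state:
        return state["czu"].frame
    return CzuTable.read_csv(Path(cfg.out_dir) / "czu.csv")


def _stage_rank(cfg: RunConfig, out: Path, seed: int, state: dict) -> list[Path]:
    frame = _czu_frame(cfg, state)
    paths = []

    npp_rank = all_subsets_rank(frame["npp"], frame[NPP_CANDIDATES])
    paths.append(_write_ranking(out, "npp", npp_rank))

    screen = collinearity_screen(frame[RWLR_CANDIDATES], frame["rwlr"],
                                 threshold=cfg.collinearity_threshold,
                                 keep_both=("br_si", "br_ca"))
    for i, subset in enumerate(screen.subsets):
        rank = all_subsets_rank(frame["rwlr"], frame[subset])
        paths.append(_write_ranking(out, f"rwlr_subset{i}", rank))
    (out / "collinearity.json").write_text(json.dumps({
        "excluded": screen.excluded, "subsets": screen.subsets}, indent=2))
    paths.append(out / "collinearity.json")
    return paths


def _write_ranking(out: Path, tag: str, rank) -> Path:
    df = rank.models.copy()
    df["variables"] = df["variables"].map(lambda v: "+".join(v) or "(null)")
    path = out / f"ranking_{tag}.csv"
    df.to_csv(path, index=False)
    rvi_path = out / f"rvi_{tag}.csv"
    pd.DataFrame(sorted(rank.rvi.items(), key=lambda kv: -kv[1]),
                 columns=["variable", "rvi"]).to_csv(rvi_path, index=False)
    return path


def _stage_sem(cfg: RunConfig, out: Path, seed: int, state: dict) -> list[Path]:
    frame = _czu_frame(cfg, state)
    paths = []
    for element in ("br_si", "br_ca"):
        spec = PathSpec.from_text(f"rwlr ~ {element}\nnpp ~ rwlr + mat")
        fit = fit_path_model(frame, spec)
        path = out / f"sem_{element}.json"
        path.write_text(json.dumps(fit.to_dict(), indent=2))
        paths.append(path)
    return paths


def _stage_karst(cfg: RunConfig, out: Path, seed: int, state: dict) -> list[Path]:
    grid = gen_global_grid(shape=(cfg.grid_rows, cfg.grid_cols),
                           r_inside=cfg.r_inside, r_outside=cfg.r_outside,
                           years=cfg.grid_years, seed=seed)
    field_ = pixel_correlation(grid.ndvi_series, grid.temp_series)
    inner, outer = buffer_zones(grid.karst_mask, cfg.buffer_width,
                                connectivity=cfg.connectivity)
    contrast = compare_zones(field_, inner, outer)
    path = out / "karst_contrast.json"
    path.write_text(json.dumps({
        "inner_mean": contrast.inner_mean, "outer_mean": contrast.outer_mean,
        "ci95_inner": contrast.ci95_inner, "ci95_outer": contrast.ci95_outer,
        "n_inner": contrast.n_inner, "n_outer": contrast.n_outer,
        "u_stat": contrast.u_stat, "p_value": contrast.p_value,
        "significant": contrast.significant, "method": contrast.method,
    }, indent=2))
    return [path]
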