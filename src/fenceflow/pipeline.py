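"""End-to-end pipeline driver on the synthetic study system.

Runs the whole analytical chain: simulate the landscape and pre-fencing
movement, fit the selection model, predict suitability, build pre-fencing
and fenced resistance surfaces, solve pairwise connectivity for both, map
connectivity change and corridors, evaluate all fence-removal scenarios,
and validate the surfaces against independently simulated (fence-impacted)
movement. Every stage writes its outputs to the run directory and a
manifest records the configuration, file hashes, and library versions.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circuit import build_graph, connectivity_change, cumulative_current, identify_corridors
from .config import PipelineConfig
from .habitat import build_presence_absence_table, fit_rsf, predict_suitability
from .raster import write_ascii_grid
from .resistance import burn_fences, detect_parcels, suitability_to_resistance
from .restoration import results_table, run_scenarios
from .synthetic import make_fenced_world, simulate_trajectories, write_trajectories
from .validation import validate_metrics
from .vectors import write_corridors, write_fences, write_focal_regions, write_geojson


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs up to the stage are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_raster(raster, name):
        written.append(write_ascii_grid(raster, outdir / f"{name}.asc"))

    stage = "synthetic_world"
    try:
        world = make_fenced_world(
            config.seed,
            shape=tuple(config.grid_shape),
            cell_size=config.cell_size,
            n_corridors=config.n_corridors,
        )
        rng = np.random.default_rng(config.seed)
        traj_pre = simulate_trajectories(
            world.stack,
            world.true_beta,
            n_animals=config.n_animals,
            n_steps=config.n_steps,
            step_mean_km=config.step_mean_km,
            step_sd_km=config.step_sd_km,
            fix_interval_h=config.fix_interval_h,
            fences=None,
            seed=int(rng.integers(2**31)),
        )
        written.append(write_fences(world.fences, outdir / "fences.geojson"))
        written.append(write_focal_regions(world.focal, outdir / "focal_regions.geojson"))
        written.append(write_corridors(world.corridors, outdir / "corridors.geojson"))
        written.append(write_geojson(outdir / "roi.geojson", [world.roi], [{"name": "roi"}]))
        written.append(write_trajectories(traj_pre, outdir / "trajectories_prefence.csv"))
        for name, layer in world.stack.layers.items():
            save_raster(layer, f"covariate_{name}")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "habitat_model"
    try:
        table = build_presence_absence_table(
            traj_pre, world.stack, pseudo_ratio=config.pseudo_ratio, seed=int(rng.integers(2**31))
        )
        coef = fit_rsf(table)
        suitability = predict_suitability(coef, world.stack)
        (outdir / "rsf_coefficients.json").write_text(json.dumps(coef.to_dict(), indent=1))
        written.append(outdir / "rsf_coefficients.json")
        save_raster(suitability, "suitability")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "resistance_surface"
    try:
        r_pre = suitability_to_resistance(
            suitability, r_min=config.r_min, r_max=config.r_max, mode=config.resistance_mode
        )
        parcels = detect_parcels(world.fences)
        r_fenced = burn_fences(r_pre, world.fences, config.barrier_value, parcels=parcels)
        save_raster(r_pre, "resistance_prefence")
        save_raster(r_fenced, "resistance_fenced")
        written.append(
            write_geojson(
                outdir / "parcels.geojson",
                [p.polygon for p in parcels],
                [
                    {"area_acres": p.area_acres, "nested": p.nested, "fence_ids": p.bounding_fence_ids}
                    for p in parcels
                ],
            )
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "circuit_solver"
    try:
        cm_pre = cumulative_current(build_graph(r_pre, world.focal))
        cm_fenced = cumulative_current(build_graph(r_fenced, world.focal))
        change = connectivity_change(cm_fenced, cm_pre)
        corridor_mask, threshold = identify_corridors(cm_pre, config.top_fraction)
        save_raster(cm_pre.cumulative, "current_prefence")
        save_raster(cm_fenced.cumulative, "current_fenced")
        save_raster(change, "connectivity_change")
        save_raster(corridor_mask, "corridor_mask")
        reffs = {
            f"{a}-{b}": {"prefence": cm_pre.effective_resistances[(a, b)], "fenced": cm_fenced.effective_resistances[(a, b)]}
            for (a, b) in cm_pre.effective_resistances
        }
        (outdir / "effective_resistances.json").write_text(
            json.dumps({"pairs": reffs, "corridor_threshold": threshold}, indent=1)
        )
        written.append(outdir / "effective_resistances.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "restoration"
    try:
        scenarios = run_scenarios(
            r_pre,
            world.fences,
            world.focal,
            world.corridors,
            roi=world.roi,
            widths_km=tuple(config.widths_km),
            unit_cost_per_acre=config.unit_cost_per_acre,
            barrier_value=config.barrier_value,
            parcels=parcels,
        )
        results_table(scenarios).to_csv(outdir / "scenarios.csv", index=False)
        written.append(outdir / "scenarios.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "validation_stats"
    try:
        traj_val = simulate_trajectories(
            world.stack,
            world.true_beta,
            n_animals=config.n_animals,
            n_steps=config.n_steps,
            step_mean_km=config.validation_step_mean_km,
            step_sd_km=config.validation_step_sd_km,
            fix_interval_h=config.validation_fix_interval_h,
            fences=world.fences_partial,
            seed=int(rng.integers(2**31)),
        )
        written.append(write_trajectories(traj_val, outdir / "trajectories_validation.csv"))
        vtable = build_presence_absence_table(
            traj_val, world.stack, pseudo_ratio=config.pseudo_ratio, seed=int(rng.integers(2**31))
        )
        metrics = {
            "suitability": (suitability, "logit"),
            "prefence_connectivity": (cm_pre.cumulative, "log"),
            "fenced_connectivity": (cm_fenced.cumulative, "log"),
            "connectivity_change": (change, "none"),
        }
        vres = validate_metrics(vtable, metrics, roi=world.roi)
        vres.to_csv(outdir / "validation.csv", index=False)
        written.append(outdir / "validation.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "fenceflow_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
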