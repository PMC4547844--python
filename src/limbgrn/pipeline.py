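"""End-to-end orchestration: domain -> data -> fit -> select -> perturb -> cell.

Each stage writes its outputs (plus a small JSON marker) into the run
directory and is skipped on re-run if its marker is already present, so a
failed pipeline resumes from the last completed stage.  The run manifest
records the config hash, seeds and per-stage output hashes; identical
configs and seeds reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import cell as cell_mod
from . import fitting, perturb, synth, vtkio
from .config import RunConfig
from .geometry import GeometryParams, build_growth_series
from .models import make_model
from .solver import SeriesContext

logger = logging.getLogger(__name__)

STAGES = ("domain", "data", "fit", "select", "perturb", "cell")


class StageError(RuntimeError):
    pass


def _hash_dir(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(p for p in path.rglob("*") if p.is_file()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()[:12]


def run_pipeline(config: RunConfig, stages=STAGES, out_dir=None) -> Path:
    """Execute the requested stages in order; returns the run directory."""
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"stages": {}})
    manifest["config_hash"] = config.hash()

    state: dict = {}
    requested = set(stages)
    if requested & {"fit", "select"}:
        requested |= {"domain", "data"}
    elif requested & {"perturb", "cell", "data"}:
        requested.add("domain")
    for stage in STAGES:
        if stage not in requested:
            continue
        marker = out / stage / ".done.json"
        try:
            t0 = time.perf_counter()
            ran = _run_stage(stage, config, out, state,
                             skip=marker.exists() and stage not in stages)
            if ran:
                manifest["stages"][stage] = {
                    "wall_time_s": round(time.perf_counter() - t0, 2),
                    "hash": _hash_dir(out / stage),
                }
                marker.write_text(json.dumps({"stage": stage}))
        except Exception as exc:  # halt with the failing stage named
            raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest_path.write_text(json.dumps(manifest, indent=1))
    return out


def _load_state(config: RunConfig, out: Path, state: dict, need: str):
    """Lazily build or reload the objects a stage depends on."""
    if need == "series" and "series" not in state:
        if (out / "domain" / "manifest.json").exists():
            state["series"] = vtkio.load_series(out / "domain")
        else:
            dom = config.domain
            state["series"] = build_growth_series(
                dom["n_hours"], GeometryParams(**dom.get("geometry", {})),
                dom["target_edge"])
        state["ctx"] = SeriesContext(state["series"])
    if need == "dataset" and "dataset" not in state:
        if (out / "data" / "manifest.json").exists():
            state["dataset"] = vtkio.load_dataset(out / "data")
        else:
            raise StageError("dataset stage has not run")
    return state[need]


def _run_stage(stage: str, config: RunConfig, out: Path, state: dict,
               skip: bool) -> bool:
    stage_dir = out / stage
    if skip:
        logger.info("stage %s: outputs present, skipping", stage)
        return False
    stage_dir.mkdir(parents=True, exist_ok=True)

    if stage == "domain":
        series = _load_state(config, out, state, "series")
        vtkio.write_series(stage_dir, series)
        return True

    if stage == "data":
        series = _load_state(config, out, state, "series")
        ds_cfg = config.dataset
        truth = make_model(ds_cfg.get("truth_model", "C"))
        params = ds_cfg.get("truth_params") or synth.truth_params(truth.name)
        traj = synth.generate_ground_truth(
            series, truth, params, **config.sim_opts())
        dataset = synth.sample_observations(
            traj, counts=ds_cfg["counts"], noise_sd=ds_cfg["noise_sd"],
            rescale=ds_cfg["rescale"], seed=ds_cfg.get("seed", 0))
        vtkio.write_dataset(stage_dir, dataset)
        state["dataset"] = dataset
        state["truth_traj"] = traj
        return True

    series = _load_state(config, out, state, "series")
    dataset = _load_state(config, out, state, "dataset")
    opt = config.optimization
    sim_opts = config.sim_opts()

    if stage == "fit":
        model = make_model(config.model["name"])
        results = fitting.fit_multistart(
            model, dataset, series, seed=opt.get("seed", 0),
            n_starts=opt["n_starts"], budget=opt["budget"],
            refine_top=opt.get("refine_top", 2),
            refine_budget=opt.get("refine_budget", 150),
            polish_budget=opt.get("polish_budget", 0),
            ctx=state["ctx"], sim_opts=sim_opts)
        best = results[0]
        (stage_dir / "fit.json").write_text(json.dumps({
            "model": model.name, "best_score": best.final_score,
            "best_params": best.final.values,
            "converged": best.converged,
            "n_converged": sum(r.converged for r in results),
            "scores": [r.final_score for r in results]}, indent=1))
        state["best_fit"] = best
        return True

    if stage == "select":
        table = fitting.select_models(
            opt.get("models", ["A", "B", "C", "D"]), dataset, series,
            seed=opt.get("seed", 0), n_starts=opt["n_starts"],
            budget=opt["budget"], refine_top=opt.get("refine_top", 2),
            refine_budget=opt.get("refine_budget", 150),
            sim_opts=sim_opts)
        table.to_csv(stage_dir / "ranking.csv")
        state["ranking"] = table
        return True

    if stage == "perturb":
        params = _fitted_or_truth(config, out, state)
        mesh0 = series.meshes[0]
        bead = perturb.BeadSpec(element=perturb.distal_element(mesh0),
                                hour=3.0)
        ctrl, pert = perturb.run_bead("C", params, series, bead,
                                      hours=(0, min(13, series.n_hours)),
                                      ctx=state["ctx"],
                                      **_strip_hours(sim_opts))
        report = {"bead": _boundary_report(ctrl, pert, series)}
        ctrl, pert = perturb.run_aer_removal("C", params, series,
                                             ctx=state["ctx"],
                                             **_strip_hours(sim_opts))
        report["aer_removal"] = _aer_report(ctrl, pert)
        (stage_dir / "perturbations.json").write_text(
            json.dumps(report, indent=1, default=float))
        return True

    if stage == "cell":
        params = _fitted_or_truth(config, out, state, prefer_model="F")
        levels = cell_mod.levels_test("F", params)
        durations = cell_mod.duration_test("F", params)
        levels.to_csv(stage_dir / "levels.csv", index=False)
        durations.to_csv(stage_dir / "durations.csv", index=False)
        return True

    raise StageError(f"unknown stage {stage!r}")


def _strip_hours(sim_opts: dict) -> dict:
    return {k: v for k, v in sim_opts.items() if k != "hours"}


def _fitted_or_truth(config: RunConfig, out: Path, state: dict,
                     prefer_model: str = "C") -> dict:
    fit_file = out / "fit" / "fit.json"
    if "best_fit" in state:
        params = dict(state["best_fit"].final.values)
    elif fit_file.exists():
        params = json.loads(fit_file.read_text())["best_params"]
    else:
        params = synth.truth_params(config.dataset.get("truth_model", "C"))
    if prefer_model == "F" and "k_MC" not in params:
        params = {**params, "k_MC": synth.TRUTH_PARAMS_F["k_MC"]}
    return params


def _boundary_report(ctrl, pert, series):
    from .models import SPECIES_INDEX
    h = ctrl.h0 + ctrl.times_min[-1] / 60.0
    mesh = series.meshes[ctrl.mesh_hours[-1]]
    out = {}
    for gene in ("M", "H11", "H13"):
        s = SPECIES_INDEX[gene]
        bc = perturb.boundary_metrics(ctrl.fields[-1][s], mesh)
        bp = perturb.boundary_metrics(pert.fields[-1][s], mesh)
        entry = {"present_control": bc.present, "present_perturbed": bp.present}
        if bc.present and bp.present:
            entry["distal_shift_um"] = perturb.boundary_shift(bc, bp, "distal")
            entry["proximal_shift_um"] = perturb.boundary_shift(bc, bp,
                                                               "proximal")
        out[gene] = entry
    out["hour"] = h
    return out


def _aer_report(ctrl, pert):
    from .models import H11 as H11_IDX, H13 as H13_IDX
    return {
        "h13_max_ratio": float(pert.fields[-1][H13_IDX].max()
                               / max(ctrl.fields[-1][H13_IDX].max(), 1e-12)),
        "h11_max_ratio": float(pert.fields[-1][H11_IDX].max()
                               / max(ctrl.fields[-1][H11_IDX].max(), 1e-12)),
    }
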