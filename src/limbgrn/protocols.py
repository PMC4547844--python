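"""Canonical study protocols at desk scale.

These functions bundle the standard experiment configurations — the coarse
27-hour growth series (~300 elements at the final stage), the Model-C truth
dataset, the 27-start selection and recovery protocols, the perturbation
battery and the single-cell analyses — so the test suite, the acceptance
script and the CLI pipeline all run the identical study.  Budgets are chosen
for a single desktop CPU; they are configuration, not science.
"""

from __future__ import annotations

import numpy as np

from . import cell as cell_mod
from . import perturb as pb
from .fitting import fit_multistart, select_models
from .geometry import GeometryParams, GrowthSeries, build_growth_series
from .models import H11, H13, M, SPECIES_INDEX, make_model
from .solver import FieldTrajectory, SeriesContext
from .synth import (ExpressionDataset, alternative_rescaling,
                    generate_ground_truth, sample_observations,
                    sigmoid_rescale, truth_params)

#: study conditions
STUDY_EDGE_UM = 65.0
STUDY_HOURS = 27
STUDY_NOISE_SD = 0.05
SELECTION_BUDGETS = dict(n_starts=27, budget=36, refine_top=1,
                         refine_budget=300)
ALTERED_SELECTION_BUDGETS = dict(n_starts=27, budget=36, refine_top=1,
                                 refine_budget=200)
RECOVERY_BUDGETS = dict(n_starts=27, budget=80, refine_top=2,
                        refine_budget=1200)
ALTERED_RESCALE = dict(k=0.35, mu=5.0)


def study_series(n_hours: int = STUDY_HOURS,
                 target_edge: float = STUDY_EDGE_UM) -> GrowthSeries:
    return build_growth_series(n_hours, GeometryParams(), target_edge)


def study_truth_trajectory(series: GrowthSeries,
                           ctx: SeriesContext | None = None) -> FieldTrajectory:
    return generate_ground_truth(series, "C", hours=(0, series.n_hours),
                                 ctx=ctx)


def study_dataset(traj: FieldTrajectory, seed: int,
                  noise_sd: float = STUDY_NOISE_SD) -> ExpressionDataset:
    return sample_observations(traj, noise_sd=noise_sd, seed=seed)


def run_selection(dataset: ExpressionDataset, series: GrowthSeries,
                  seed: int, budgets: dict | None = None, models=("A", "B", "C", "D")):
    return select_models(list(models), dataset, series, seed=seed,
                         **(budgets or SELECTION_BUDGETS))


def run_recovery(dataset: ExpressionDataset, series: GrowthSeries,
                 seed: int, budgets: dict | None = None):
    return fit_multistart(make_model("C"), dataset, series, seed=seed,
                          **(budgets or RECOVERY_BUDGETS))


def threshold_recovery_errors(fit, truth: dict | None = None) -> dict:
    truth = truth or truth_params("C")
    return {k: abs(fit.final.values[k] - truth[k]) / truth[k]
            for k in truth if k.startswith("k")}


def rescaled(field: np.ndarray, rescale: dict | None = None) -> np.ndarray:
    kw = rescale or {}
    return sigmoid_rescale(np.clip(field, 0.0, None), **kw)


def h11_curvature(model_name: str, params: dict, series: GrowthSeries,
                  hour: float = 24.0, ctx: SeriesContext | None = None):
    """(proximal, distal) curvature indices of the late Hoxa11 domain."""
    from .solver import simulate

    traj = simulate(series, make_model(model_name), params,
                    hours=(0, series.n_hours), ctx=ctx)
    i = traj.index_at_hour(hour)
    mesh = series.meshes[traj.mesh_hours[i]]
    bm = pb.boundary_metrics(rescaled(traj.fields[i][H11]), mesh)
    return bm


def bead_experiment(series: GrowthSeries, params: dict,
                    ctx: SeriesContext | None = None,
                    insertion_hour: float = 3.0, readout_hour: int = 13):
    """RA-bead run; returns per-gene central boundary shifts (um)."""
    bead = pb.BeadSpec(element=pb.distal_element(
        series.meshes[int(insertion_hour)]), hour=insertion_hour)
    ctrl, pert = pb.run_bead("C", params, series, bead,
                             hours=(0, readout_hour), ctx=ctx)
    mesh = series.meshes[ctrl.mesh_hours[-1]]
    out = {}
    for gene in ("M", "H11", "H13"):
        s = SPECIES_INDEX[gene]
        bc = pb.boundary_metrics(rescaled(ctrl.fields[-1][s]), mesh)
        bp = pb.boundary_metrics(rescaled(pert.fields[-1][s]), mesh)
        if bc.present and bp.present:
            out[gene] = {
                "distal_shift": pb.boundary_shift(bc, bp, "distal"),
                "proximal_shift": pb.boundary_shift(bc, bp, "proximal"),
            }
        else:
            out[gene] = None
    out["pd_extent"] = series.params.pd_extent(readout_hour)
    return out


def aer_removal_experiment(series: GrowthSeries, params: dict,
                           ctx: SeriesContext | None = None):
    """FGF shutoff at mE10:16 (+6 h readout): marker retention ratios."""
    ctrl, pert = pb.run_aer_removal("C", params, series, t_off=7.0, ctx=ctx)
    tip = pb.distal_element(series.meshes[ctrl.mesh_hours[-1]])
    from .models import R as R_IDX
    return {
        "h13_ratio": float(pert.fields[-1][H13].max()
                           / max(ctrl.fields[-1][H13].max(), 1e-12)),
        "h11_ratio": float(pert.fields[-1][H11].max()
                           / max(ctrl.fields[-1][H11].max(), 1e-12)),
        "tip_ra_control": float(ctrl.fields[-1][R_IDX][tip]),
        "tip_ra_perturbed": float(pert.fields[-1][R_IDX][tip]),
    }


def meis_overexpression_experiment(series: GrowthSeries, model_name: str,
                                   params: dict,
                                   ctx: SeriesContext | None = None,
                                   readout_hour: int = 22):
    """Uniform ectopic Meis in Model E or F: boundary shifts + H13 level."""
    ctrl, pert = pb.run_meis_overexpression(model_name, params, series,
                                            hours=(0, readout_hour), ctx=ctx)
    mesh = series.meshes[ctrl.mesh_hours[-1]]
    bc11 = pb.boundary_metrics(rescaled(ctrl.fields[-1][H11]), mesh)
    bp11 = pb.boundary_metrics(rescaled(pert.fields[-1][H11]), mesh)
    out = {
        "h13_level_ratio": float(pert.fields[-1][H13].max()
                                 / max(ctrl.fields[-1][H13].max(), 1e-12)),
        "pd_extent": series.params.pd_extent(readout_hour),
    }
    if bc11.present and bp11.present:
        out["h11_distal_shift"] = pb.boundary_shift(bc11, bp11, "distal")
        out["h11_proximal_shift"] = pb.boundary_shift(bc11, bp11, "proximal")
    return out


def single_cell_summary(params_f: dict) -> dict:
    levels = cell_mod.levels_test("F", params_f)

    def dom(r, f):
        row = levels[(levels.R == r) & (levels.F == f)]
        return row["dominant"].iloc[0]

    durations = cell_mod.duration_test("F", params_f)
    fine = cell_mod.duration_test(
        "F", params_f, durations=(0, 15, 30, 45, 60, 90, 150, 300, 480))
    return {
        "levels": {"proximal": dom(2.0, 0.0), "medial": dom(0.4, 0.8),
                   "distal": dom(0.0, 2.0)},
        "staircase": list(durations["dominant"]),
        "staircase_monotone": cell_mod.staircase_is_monotone(fine["dominant"]),
    }
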