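"""In-silico perturbation experiments and boundary/curvature metrics.

Three classical limb manipulations are emulated on the simulated tissue:

* **RA bead** — a single mesh element carried along with the tissue secretes
  extra RA at a rate P0 * exp(-rho * (t - t_b)) from insertion time t_b
  (the exponential models exhaustion of the soaked bead).
* **AER removal** — FGF production is set to zero everywhere from a given
  stage, measuring the effect 6 h later.  Reproducing the observed
  differential marker loss requires reducing the Hoxa11 decay rate by 60%
  (factor 0.4), applied in the perturbed arm from the removal time.
* **Meis overexpression** — a constant term equal to P_M is added to Meis
  production in every element, contrasted between Model E (direct
  Meis -| Hoxa13) and Model F (indirect, via Cyp26b1).

Domain boundaries are quantified along three anteroposterior transects
(anterior, central, posterior): the proximal/distal boundary of a gene's
supra-threshold domain on each transect, a curvature index per boundary
(deviation of the central boundary point from the chord spanned by the
anterior and posterior points), and the central band thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np

from .geometry import GrowthSeries, TransferMap, TriMesh
from .models import FIXED_PARAMS, M as M_IDX, NetworkModel, R as R_IDX, SPECIES_INDEX, make_model
from .solver import (FieldState, FieldTrajectory, SeriesContext,
                     concat_trajectories, simulate)


@dataclass
class BeadSpec:
    """An implanted RA-soaked bead."""

    element: int                 # host element id at insertion
    hour: float                  # insertion time t_b (series hour)
    P0: float = 20.0             # initial release rate, 1/min
    rho: float = log(2) / 120.0  # release decay rate (2-h half-life)

    def __post_init__(self):
        if self.P0 < 0 or self.rho <= 0:
            raise ValueError("bead needs P0 >= 0 and rho > 0")

    def release_rate(self, minutes_since_insertion: float) -> float:
        if minutes_since_insertion < 0:
            return 0.0
        return self.P0 * np.exp(-self.rho * minutes_since_insertion)


class RABead:
    """Solver hook: moving point source of RA.

    The host element is tracked through each remesh as the new element that
    receives the largest mass fraction of the old host.
    """

    def __init__(self, spec: BeadSpec):
        self.spec = spec
        self.element = spec.element

    def reset(self):
        self.element = self.spec.element

    def modify_production(self, t_abs_min, hour, mesh, prod):
        rate = self.spec.release_rate(t_abs_min - self.spec.hour * 60.0)
        if rate > 0.0:
            if self.element >= mesh.n_elements:
                raise RuntimeError(
                    f"bead host element {self.element} lost from mesh at "
                    f"hour {hour}")
            prod[R_IDX, self.element] += rate

    def on_remesh(self, tmap: TransferMap, old: TriMesh, new: TriMesh):
        if old.hour < int(self.spec.hour):
            return  # host id refers to the insertion-hour mesh
        col = tmap.matrix.getcol(self.element)
        if col.nnz == 0:
            raise RuntimeError("bead host element has no image in new mesh")
        self.element = int(col.indices[np.argmax(col.data)])


class AERRemoval:
    """Solver hook: FGF production terminated from ``t_off`` (series hour)."""

    def __init__(self, t_off_hour: float):
        self.t_off = t_off_hour

    def modify_production(self, t_abs_min, hour, mesh, prod):
        if t_abs_min >= self.t_off * 60.0:
            prod[SPECIES_INDEX["F"]] = 0.0


class MeisOverexpression:
    """Solver hook: uniform ectopic Meis production (+P_M everywhere)."""

    def __init__(self, amount: float | None = None):
        self.amount = FIXED_PARAMS["P_M"] if amount is None else amount

    def modify_production(self, t_abs_min, hour, mesh, prod):
        prod[M_IDX] += self.amount


def distal_element(mesh: TriMesh, ap: float = 0.0) -> int:
    """Element nearest the distal tip at AP offset ``ap`` (um)."""
    c = mesh.centroids
    score = c[:, 0] - 2.0 * np.abs(c[:, 1] - ap)
    return int(np.argmax(score))


def run_bead(model: NetworkModel | str, params: dict, series: GrowthSeries,
             bead: BeadSpec, hours=(0, 13), ctx: SeriesContext | None = None,
             **sim_opts):
    """(control, perturbed) trajectories for the RA-bead experiment."""
    if isinstance(model, str):
        model = make_model(model)
    if not (hours[0] <= bead.hour <= hours[1]):
        raise ValueError("bead insertion hour outside the simulated window")
    ctx = ctx or SeriesContext(series)
    control = simulate(series, model, params, hours=hours, ctx=ctx, **sim_opts)
    perturbed = simulate(series, model, params, hours=hours, ctx=ctx,
                         perturbations=(RABead(bead),), **sim_opts)
    return control, perturbed


def run_aer_removal(model: NetworkModel | str, params: dict,
                    series: GrowthSeries, t_off: float = 7.0,
                    h11_decay_factor: float = 0.4, follow_up_hours: float = 6.0,
                    hours=None, ctx: SeriesContext | None = None,
                    reduce_decay_in_control: bool = False, **sim_opts):
    """(control, perturbed) for FGF-source removal at ``t_off``.

    The perturbed arm is run in two segments: normal dynamics up to
    ``t_off``, then FGF production zeroed *and* the Hoxa11 decay rate
    reduced (default factor 0.4, i.e. by 60%) — the one modification needed
    for the differential marker response (Hoxa13 collapse with Hoxa11
    retention).  By default the control keeps the normal decay so the two
    arms are identical before ``t_off``; ``reduce_decay_in_control`` applies
    the reduced decay to the whole control run instead.  Both trajectories
    extend to t_off + follow_up_hours.
    """
    if isinstance(model, str):
        model = make_model(model)
    if hours is None:
        hours = (0, int(round(t_off + follow_up_hours)))
    if not (hours[0] <= t_off <= hours[1]):
        raise ValueError("t_off outside the simulated window")
    ctx = ctx or SeriesContext(series)
    reduced = dict(params)
    reduced["lam_H11"] = (params.get("lam_H11", FIXED_PARAMS["lam_H11"])
                          * h11_decay_factor)
    ctrl_params = reduced if reduce_decay_in_control else dict(params)
    control = simulate(series, model, ctrl_params, hours=hours, ctx=ctx,
                       **sim_opts)
    h_cut = int(round(t_off))
    pre = simulate(series, model, params, hours=(hours[0], h_cut), ctx=ctx,
                   **sim_opts)
    post = simulate(series, model, reduced, hours=(h_cut, hours[1]), ctx=ctx,
                    perturbations=(AERRemoval(t_off),),
                    initial_state=FieldState(h_cut, 0.0, pre.fields[-1]),
                    **sim_opts)
    return control, concat_trajectories(pre, post)


def run_meis_overexpression(model: NetworkModel | str, params: dict,
                            series: GrowthSeries, hours=(0, 22),
                            ctx: SeriesContext | None = None, **sim_opts):
    """(control, perturbed) for uniform ectopic Meis (Models E or F)."""
    if isinstance(model, str):
        model = make_model(model)
    if model.name not in ("E", "F"):
        raise ValueError("Meis overexpression contrasts Models E and F")
    ctx = ctx or SeriesContext(series)
    control = simulate(series, model, params, hours=hours, ctx=ctx, **sim_opts)
    perturbed = simulate(series, model, params, hours=hours, ctx=ctx,
                         perturbations=(MeisOverexpression(),), **sim_opts)
    return control, perturbed


@dataclass
class BoundaryMetrics:
    """Transect-based geometry of one expression domain."""

    present: bool
    #: per transect name: (proximal x, distal x) in um, or None if the domain
    #: is absent on that transect
    positions: dict = field(default_factory=dict)
    curvature_proximal: float | None = None
    curvature_distal: float | None = None
    central_thickness: float | None = None


def boundary_metrics(values: np.ndarray, mesh: TriMesh,
                     threshold: float = 0.5,
                     transect_fracs=(0.55, 0.0, -0.55),
                     band: float | None = None) -> BoundaryMetrics:
    """Boundary positions and curvature indices of a supra-threshold domain.

    ``transect_fracs`` are AP positions as fractions of the domain half-width
    (positive = anterior).  The curvature index of a boundary is the absolute
    deviation of its central position from the anterior-posterior chord
    midpoint; a straight (RA-like) isocline scores ~0, a curved (AER-hugging)
    isocline scores large.
    """
    if band is None:
        band = 1.3 * float(np.median(np.sqrt(mesh.element_area)))
    half_width = float(np.abs(mesh.vertices[:, 1]).max())
    names = ("anterior", "central", "posterior")
    positions: dict[str, tuple[float, float] | None] = {}
    for name, frac in zip(names, transect_fracs):
        y = frac * half_width
        sel = np.abs(mesh.centroids[:, 1] - y) <= band
        x = mesh.centroids[sel, 0]
        order = np.argsort(x)
        x, v = x[order], values[sel][order]
        above = np.flatnonzero(v > threshold)
        if above.size == 0:
            positions[name] = None
            continue
        i0, i1 = above[0], above[-1]
        # sub-element precision: interpolate the threshold crossing between
        # the boundary element and its sub-threshold neighbour
        if i0 == 0:
            prox = x[0]
        else:
            prox = np.interp(threshold, [v[i0 - 1], v[i0]],
                             [x[i0 - 1], x[i0]])
        if i1 == len(x) - 1:
            dist = x[-1]
        else:
            dist = np.interp(threshold, [v[i1 + 1], v[i1]],
                             [x[i1 + 1], x[i1]])
        positions[name] = (float(prox), float(dist))
    if any(p is None for p in positions.values()):
        return BoundaryMetrics(present=False, positions=positions)
    prox = {n: positions[n][0] for n in names}
    dist = {n: positions[n][1] for n in names}
    curv_p = abs(prox["central"] - 0.5 * (prox["anterior"] + prox["posterior"]))
    curv_d = abs(dist["central"] - 0.5 * (dist["anterior"] + dist["posterior"]))
    return BoundaryMetrics(
        present=True, positions=positions,
        curvature_proximal=float(curv_p), curvature_distal=float(curv_d),
        central_thickness=float(dist["central"] - prox["central"]))


def boundary_shift(control: BoundaryMetrics, perturbed: BoundaryMetrics,
                   which: str = "distal") -> float:
    """Central-transect boundary displacement (um), perturbed - control."""
    if not (control.present and perturbed.present):
        raise ValueError("domain absent in one of the compared states")
    i = 1 if which == "distal" else 0
    return perturbed.positions["central"][i] - control.positions["central"][i]
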