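"""Multi-start parameter optimization, model selection and robustness checks.

Each candidate topology is fitted to the staged expression dataset by local
minimization of the shape-based objective (:func:`limbgrn.scoring.total_score`)
over its free parameters.  Rates and thresholds, which span orders of
magnitude, are searched in log10 space; the Hill coefficients and the FGF4
production rate are searched linearly.  Following the multi-start protocol,
27 initial parameter sets are built from a 3 x 3 x 3 grid over three
upstream parameters that affect all genes (lam_F, lam_R, c1), each taking
three values spanning two orders of magnitude, with the remaining free
parameters drawn at random within their bounds.

Model ranking uses the best score over starts, with the number of converged
runs as a secondary signal (a good model both scores better and converges
more often).  The super-model X0 is analysed by ablating its four
RA/FGF -> Hox links one at a time, with and without refitting.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize as sciopt

from .geometry import GrowthSeries
from .models import NetworkModel, SPECIES_INDEX, ablate_link, make_model
from .scoring import ScoreReport, total_score
from .solver import SeriesContext, simulate
from .synth import (ExpressionDataset, GENES, halve_observations,
                    sigmoid_rescale)

#: (low, high, transform) per free parameter; "log" parameters are searched
#: in log10 space
DEFAULT_BOUNDS: dict[str, tuple[float, float, str]] = {
    "P_FGF4": (0.0, 1.0, "lin"),
    "lam_F": (1e-3, 1.0, "log"),
    "lam_R": (1e-3, 1.0, "log"),
    "mu": (1.0, 12.0, "lin"),
    "mu_tilde": (1.0, 12.0, "lin"),
    "c1": (1e-2, 1e2, "log"),
}
_K_BOUNDS = (1e-3, 2.0, "log")


def param_bounds(name: str) -> tuple[float, float, str]:
    if name in DEFAULT_BOUNDS:
        return DEFAULT_BOUNDS[name]
    if name.startswith("k"):
        return _K_BOUNDS
    raise KeyError(f"no bounds known for parameter {name!r}")


#: 3-value grids (spanning two orders of magnitude) for the three upstream
#: parameters used to spread the 27 starts across parameter space
DEFAULT_START_GRID = {
    "lam_F": (0.001, 0.01, 0.1),
    "lam_R": (0.001, 0.01, 0.1),
    "c1": (0.03, 0.3, 3.0),
}


@dataclass
class ParameterSet:
    """Named free-parameter values for one model, with transforms."""

    model_name: str
    values: dict[str, float]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def validate(self, model: NetworkModel) -> None:
        missing = set(model.free_parameters) - set(self.values)
        if missing:
            raise KeyError(f"missing free parameters for model "
                           f"{model.name}: {sorted(missing)}")
        for name, v in self.values.items():
            lo, hi, _ = param_bounds(name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")

    def to_vector(self) -> np.ndarray:
        """Map to unit-box search coordinates (log10 for rate/threshold
        parameters, linear otherwise, each rescaled to [0, 1] by its bounds)
        so that optimizer steps are comparable across parameters."""
        out = []
        for name, v in self.values.items():
            lo, hi, tr = param_bounds(name)
            if tr == "log":
                x = (np.log10(v) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
            else:
                x = (v - lo) / (hi - lo)
            out.append(x)
        return np.asarray(out)

    @classmethod
    def from_vector(cls, model_name: str, names, vec) -> "ParameterSet":
        values = {}
        for name, x in zip(names, vec):
            lo, hi, tr = param_bounds(name)
            x = float(np.clip(x, 0.0, 1.0))
            if tr == "log":
                llo, lhi = np.log10(lo), np.log10(hi)
                v = 10.0 ** (llo + x * (lhi - llo))
            else:
                v = lo + x * (hi - lo)
            values[name] = float(np.clip(v, lo, hi))
        return cls(model_name, values)

    def transformed_bounds(self) -> list[tuple[float, float]]:
        return [(0.0, 1.0)] * len(self.values)


def initial_parameter_sets(model: NetworkModel, seed: int = 0,
                           grid: dict | None = None) -> list[ParameterSet]:
    """The 27 multi-start initial parameter sets.

    A full factorial over the three grid values of lam_F, lam_R and c1; the
    remaining free parameters are drawn per start — log-uniform within
    bounds for rates/thresholds, uniform for the linear ones.
    """
    grid = dict(DEFAULT_START_GRID, **(grid or {}))
    rng = np.random.default_rng(seed)
    sets = []
    for lf in grid["lam_F"]:
        for lr in grid["lam_R"]:
            for c1 in grid["c1"]:
                values = {}
                for name in model.free_parameters:
                    lo, hi, tr = param_bounds(name)
                    if name == "lam_F":
                        values[name] = lf
                    elif name == "lam_R":
                        values[name] = lr
                    elif name == "c1":
                        values[name] = c1
                    elif tr == "log":
                        values[name] = 10.0 ** rng.uniform(np.log10(lo),
                                                           np.log10(hi))
                    else:
                        values[name] = rng.uniform(lo, hi)
                sets.append(ParameterSet(model.name, values))
    return sets


@dataclass
class FitResult:
    model_name: str
    init: ParameterSet
    final: ParameterSet
    score_trajectory: list[float]      # best-so-far score per evaluation
    final_score: float
    report: ScoreReport | None
    converged: bool
    n_evals: int
    seed: int | None = None
    wall_time_s: float = 0.0


class Objective:
    """total_score as a function of the transformed parameter vector."""

    def __init__(self, model: NetworkModel, dataset: ExpressionDataset,
                 series: GrowthSeries, ctx: SeriesContext | None = None,
                 sim_opts: dict | None = None, penalty: float = 1e6,
                 max_failures: int = 25):
        self.model = model
        self.dataset = dataset
        self.series = series
        self.ctx = ctx or SeriesContext(series)
        self.sim_opts = {**dict(hours=(0, series.n_hours), dt=2.0,
                                output_every=30.0), **(sim_opts or {})}
        self.penalty = penalty
        self.max_failures = max_failures
        self.names: tuple[str, ...] = tuple(model.free_parameters)
        self.n_evals = 0
        self.n_failures = 0
        self.best: list[float] = []
        self._n_residuals: int | None = None

    def params_from_vector(self, vec) -> dict:
        return ParameterSet.from_vector(self.model.name, self.names,
                                        vec).values

    def score(self, params: dict) -> float:
        traj = simulate(self.series, self.model, params, ctx=self.ctx,
                        **self.sim_opts)
        return total_score(traj, self.dataset).total

    def residuals(self, vec) -> np.ndarray:
        """Weighted per-element residual vector (its squared norm equals the
        total score), for Gauss-Newton style least-squares descent."""
        self.n_evals += 1
        params = self.params_from_vector(vec)
        try:
            traj = simulate(self.series, self.model, params, ctx=self.ctx,
                            **self.sim_opts)
            parts = []
            k, mu = self.dataset.rescale["k"], self.dataset.rescale["mu"]
            for o in self.dataset.observations:
                i = traj.index_at_hour(o.hour)
                sim = sigmoid_rescale(
                    np.clip(traj.fields[i][SPECIES_INDEX[o.gene]], 0.0, None),
                    k=k, mu=mu)
                parts.append(np.sqrt(o.weight / sim.shape[0])
                             * (sim - o.values))
            r = np.concatenate(parts)
            self.n_failures = 0
        except (RuntimeError, FloatingPointError, ValueError):
            self.n_failures += 1
            if self.n_failures > self.max_failures:
                raise RuntimeError(
                    f"repeated simulation failures while optimizing model "
                    f"{self.model.name}; aborting run")
            r = np.full(self._n_residuals or 1, np.sqrt(self.penalty))
        if self._n_residuals is None:
            self._n_residuals = r.size
        s = float(r @ r)
        self.best.append(min(s, self.best[-1]) if self.best else s)
        return r

    def __call__(self, vec) -> float:
        self.n_evals += 1
        try:
            s = self.score(self.params_from_vector(vec))
            self.n_failures = 0
        except (RuntimeError, FloatingPointError, ValueError):
            self.n_failures += 1
            if self.n_failures > self.max_failures:
                raise RuntimeError(
                    f"{self.n_failures} consecutive simulation failures while "
                    f"optimizing model {self.model.name}; aborting run")
            s = self.penalty
        self.best.append(min(s, self.best[-1]) if self.best else s)
        return s


def _converged(best: list[float], patience: int = 40, tol: float = 1e-3) -> bool:
    """Converged = the descent plateaued (relative improvement below ``tol``
    over the trailing window) after making real progress from its start.

    Runs that stall immediately on a flat region of parameter space (no
    descent at all) count as failed, mirroring the converged/not-converged
    dichotomy of the multi-start protocol.
    """
    if len(best) < 3 or not np.isfinite(best[-1]):
        return False
    window = min(patience, max(2, len(best) - 1))
    prev = best[-window - 1]
    plateaued = (prev - best[-1]) <= tol * max(prev, 1e-12)
    progressed = best[-1] <= 0.8 * best[0] + 1e-12
    return plateaued and progressed


def optimize(model: NetworkModel, dataset: ExpressionDataset,
             series: GrowthSeries, init: ParameterSet, budget: int = 300,
             method: str = "least-squares",
             ctx: SeriesContext | None = None,
             sim_opts: dict | None = None, seed: int | None = None,
             diff_step: float = 1e-3) -> FitResult:
    """One local-descent run from ``init``; ``budget`` caps evaluations."""
    if budget <= 0:
        raise ValueError("budget must be positive")
    init.validate(model)
    obj = Objective(model, dataset, series, ctx=ctx, sim_opts=sim_opts)
    x0 = ParameterSet(model.name, {n: init.values[n] for n in obj.names}).to_vector()
    bounds = ParameterSet(model.name,
                          {n: init.values[n] for n in obj.names}
                          ).transformed_bounds()
    t0 = time.perf_counter()
    if method == "nelder-mead":
        res = sciopt.minimize(obj, x0, method="Nelder-Mead", bounds=bounds,
                              options={"maxfev": budget, "xatol": 1e-4,
                                       "fatol": 1e-10, "adaptive": True})
    elif method == "l-bfgs-b":
        res = sciopt.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                              jac=None, options={"maxfun": budget,
                                                 "eps": 1e-4, "ftol": 1e-14,
                                                 "gtol": 1e-12})
    elif method == "least-squares":
        # Gauss-Newton (trust-region reflective) on the weighted residual
        # vector: far more effective in the narrow sum-of-squares valleys of
        # this objective than simplex descent.  x_scale='jac' makes steps
        # scale-invariant along sloppy directions; the fine finite-difference
        # step matters close to the optimum.  max_nfev excludes FD Jacobian
        # columns, so convert the evaluation budget to iteration count.
        n = len(x0)
        res = sciopt.least_squares(
            obj.residuals, np.clip(x0, 0.0, 1.0),
            bounds=(np.zeros(n), np.ones(n)), method="trf",
            diff_step=diff_step, x_scale="jac",
            xtol=1e-14, ftol=1e-14, gtol=1e-15,
            max_nfev=max(2, budget // (n + 1)))
        res.fun = float(np.dot(res.fun, res.fun))
    else:
        raise ValueError(f"unknown method {method!r}")
    final = ParameterSet.from_vector(model.name, obj.names, res.x)
    # res.x is the best simplex vertex for NM but only the last iterate for
    # L-BFGS-B; score it explicitly so final/final_score are consistent
    report = None
    final_score = float(obj.best[-1])
    try:
        traj = simulate(series, model, final.values, ctx=obj.ctx,
                        **obj.sim_opts)
        report = total_score(traj, dataset)
        final_score = float(report.total)
    except RuntimeError:
        final_score = float(res.fun)
    return FitResult(
        model_name=model.name, init=init, final=final,
        score_trajectory=obj.best, final_score=final_score, report=report,
        converged=_converged(obj.best), n_evals=obj.n_evals, seed=seed,
        wall_time_s=time.perf_counter() - t0)


def _continue_from(model, dataset, series, r: FitResult, budget, ctx,
                   sim_opts, seed, diff_step) -> FitResult:
    nxt = optimize(model, dataset, series, r.final, budget=budget, ctx=ctx,
                   sim_opts=sim_opts, seed=seed, diff_step=diff_step)
    if nxt.final_score > r.final_score:
        return r
    nxt.init = r.init
    nxt.score_trajectory = r.score_trajectory + nxt.score_trajectory
    nxt.n_evals += r.n_evals
    nxt.converged = nxt.converged or r.converged
    nxt.wall_time_s += r.wall_time_s
    return nxt


def fit_multistart(model: NetworkModel, dataset: ExpressionDataset,
                   series: GrowthSeries, seed: int = 0, n_starts: int = 27,
                   budget: int = 300, refine_top: int = 2,
                   refine_budget: int = 1200,
                   polish_budget: int = 0,
                   ctx: SeriesContext | None = None,
                   sim_opts: dict | None = None,
                   grid: dict | None = None) -> list[FitResult]:
    """The multi-start protocol: coarse runs, then refinement of the best.

    Coarse runs use the standard finite-difference step; refinement (and the
    optional extra ``polish_budget`` round on the single best run) uses the
    fine step that resolves the bottom of the valley.  Returns all results
    sorted by final score; refined results replace their coarse-stage
    ancestors.
    """
    ctx = ctx or SeriesContext(series)
    inits = initial_parameter_sets(model, seed=seed, grid=grid)[:n_starts]
    results = [optimize(model, dataset, series, init, budget=budget,
                        ctx=ctx, sim_opts=sim_opts, seed=seed)
               for init in inits]
    results.sort(key=lambda r: r.final_score)
    for i in range(min(refine_top, len(results))):
        results[i] = _continue_from(model, dataset, series, results[i],
                                    refine_budget, ctx, sim_opts, seed,
                                    diff_step=1e-4)
    results.sort(key=lambda r: r.final_score)
    if polish_budget > 0:
        results[0] = _continue_from(model, dataset, series, results[0],
                                    polish_budget, ctx, sim_opts, seed,
                                    diff_step=1e-4)
        results.sort(key=lambda r: r.final_score)
    return results


def select_models(model_names, dataset: ExpressionDataset,
                  series: GrowthSeries, seed: int = 0,
                  **fit_kwargs) -> pd.DataFrame:
    """Rank candidate topologies by the multi-start protocol.

    Columns: best_score, median_converged_score, n_converged, n_starts and
    rank (1 = best).  Ranking is by best score, ties broken by convergence
    count (more convergent runs ranks better).
    """
    if len(model_names) < 1:
        raise ValueError("need at least one model")
    rows = {}
    fits = {}
    for name in model_names:
        model = make_model(name) if isinstance(name, str) else name
        results = fit_multistart(model, dataset, series, seed=seed,
                                 **fit_kwargs)
        conv = [r.final_score for r in results if r.converged]
        rows[model.name] = {
            "best_score": results[0].final_score,
            "median_converged_score": float(np.median(conv)) if conv else np.nan,
            "n_converged": len(conv),
            "n_starts": len(results),
        }
        fits[model.name] = results
    df = pd.DataFrame(rows).T
    df = df.sort_values(["best_score", "n_converged"],
                        ascending=[True, False])
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["fits"] = fits
    df.attrs["seed"] = seed
    return df


def ablation_study(dataset: ExpressionDataset, series: GrowthSeries,
                   seed: int = 0, x0_fit: FitResult | None = None,
                   refit_budget: int = 60, **fit_kwargs) -> pd.DataFrame:
    """Fit the super-model X0, then remove its RA/FGF->Hox links one by one.

    For each single-link ablation the score is reported without refitting
    (same parameters, link deleted) and after a short refit; the score delta
    relative to the fitted super-model measures how much the link matters.
    """
    x0 = make_model("X0")
    ctx = SeriesContext(series)
    if x0_fit is None:
        x0_fit = fit_multistart(x0, dataset, series, seed=seed, ctx=ctx,
                                **fit_kwargs)[0]
    base = x0_fit.final_score
    obj = Objective(x0, dataset, series, ctx=ctx,
                    sim_opts=fit_kwargs.get("sim_opts"))
    rows = []
    for key in (("R", "H11"), ("R", "H13"), ("F", "H11"), ("F", "H13")):
        sub = ablate_link(x0, key)
        params = {k: v for k, v in x0_fit.final.values.items()
                  if k in sub.free_parameters}
        pset = ParameterSet(sub.name, params)
        sub_obj = Objective(sub, dataset, series, ctx=ctx,
                            sim_opts=fit_kwargs.get("sim_opts"))
        unrefit = sub_obj.score(params)
        refit = optimize(sub, dataset, series, pset, budget=refit_budget,
                         ctx=ctx, sim_opts=fit_kwargs.get("sim_opts"))
        rows.append({"removed_link": f"{key[0]}->{key[1]}",
                     "unrefit_score": unrefit,
                     "refit_score": refit.final_score,
                     "delta_unrefit": unrefit - base,
                     "delta_refit": refit.final_score - base})
    df = pd.DataFrame(rows).set_index("removed_link")
    df.attrs["x0_score"] = base
    df.attrs["x0_fit"] = x0_fit
    return df


def _final_pattern(series, model, params, sim_opts, rescale, ctx):
    opts = dict(hours=(0, series.n_hours), dt=2.0, output_every=30.0,
                **(sim_opts or {}))
    traj = simulate(series, model, params, ctx=ctx, **opts)
    h_final = opts["hours"][1]
    fields = []
    for g in GENES:
        raw = np.clip(traj.field_at(g, h_final), 0.0, None)
        fields.append(sigmoid_rescale(raw, **rescale))
    return np.concatenate(fields)


def robustness_half_data(model: NetworkModel, dataset: ExpressionDataset,
                         series: GrowthSeries, seed: int = 0,
                         full_fit: FitResult | None = None,
                         refit_budget: int = 200,
                         sim_opts: dict | None = None,
                         **fit_kwargs) -> dict:
    """Refit after dropping every second Hoxa11/Hoxa13 time-point.

    The halved-data refit starts from the full-data optimum (a stability
    check: if the data over-constrain the model, halving should not move the
    fitted pattern).  Reports parameter ratios and the RMS difference of the
    final rescaled patterns.
    """
    ctx = SeriesContext(series)
    if full_fit is None:
        full_fit = fit_multistart(model, dataset, series, seed=seed, ctx=ctx,
                                  sim_opts=sim_opts, **fit_kwargs)[0]
    half = halve_observations(dataset)
    refit = optimize(model, half, series, full_fit.final,
                     budget=refit_budget, ctx=ctx, sim_opts=sim_opts)
    p_full = _final_pattern(series, model, full_fit.final.values, sim_opts,
                            dataset.rescale, ctx)
    p_half = _final_pattern(series, model, refit.final.values, sim_opts,
                            dataset.rescale, ctx)
    rms = float(np.sqrt(np.mean((p_full - p_half) ** 2)))
    ratios = {k: refit.final.values[k] / v
              for k, v in full_fit.final.values.items()}
    return {"full_fit": full_fit, "half_fit": refit,
            "half_counts": half.counts(), "pattern_rms": rms,
            "parameter_ratios": ratios}


def sensitivity_analysis(model: NetworkModel, fitted: ParameterSet,
                         dataset: ExpressionDataset, series: GrowthSeries,
                         factors=None, sim_opts: dict | None = None,
                         flat_threshold: float = 0.05) -> pd.DataFrame:
    """Score response to scaling each fitted parameter by 1/4 ... 4.

    ``normalized_curvature`` is the mean relative score increase at the scan
    end-points; parameters below ``flat_threshold`` are flagged as flat
    (poorly determined) directions.
    """
    if factors is None:
        factors = np.geomspace(0.25, 4.0, 9)
    obj = Objective(model, dataset, series, sim_opts=sim_opts)
    s0 = obj.score(fitted.values)
    rows = []
    for name, v in fitted.values.items():
        lo, hi, _ = param_bounds(name)
        scores = []
        for f in factors:
            p = dict(fitted.values)
            p[name] = float(np.clip(v * f, lo, hi))
            scores.append(obj.score(p))
        scores = np.asarray(scores)
        end_rise = 0.5 * (scores[0] + scores[-1]) - s0
        curv = end_rise / max(s0, 1e-9)
        rows.append({"parameter": name, "fitted_value": v,
                     "factors": list(map(float, factors)),
                     "scores": [float(s) for s in scores],
                     "min_scan_score": float(scores.min()),
                     "normalized_curvature": float(curv),
                     "flat": bool(curv < flat_threshold)})
    df = pd.DataFrame(rows).set_index("parameter")
    df.attrs["fitted_score"] = s0
    return df
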