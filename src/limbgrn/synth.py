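"""Synthetic expression datasets standing in for mapped WMISH data.

Whole-mount in situ hybridization is non-quantitative: the mapped intensity
of each stained limb is converted to relative concentrations in [0, 1] and
then passed through a steep sigmoid rescaling so the information content is
the *shape* of the expression domain rather than absolute levels.  The real
mapped dataset is not distributed, so this module generates the equivalent
observations from a known ground-truth network simulated on the synthetic
growth series: staged per-element snapshots of Meis, Hoxa11 and Hoxa13 with
observation noise, the sigmoid rescaling, and per-observation weights.

Defaults follow the study conditions: 4 / 26 / 32 time-points for
Meis / Hoxa11 / Hoxa13 (more for the more dynamic patterns), weight 20 for
the last Hoxa11 time-point, rescaling parameters k = 0.5 and mu = 8, and
truncated-Gaussian observation noise with sd 0.05 on raw concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GrowthSeries
from .models import NetworkModel, SPECIES_INDEX, make_model
from .solver import FieldTrajectory, simulate

GENES = ("M", "H11", "H13")

#: default number of staged observations per gene
DEFAULT_COUNTS = {"M": 4, "H11": 26, "H13": 32}

#: observation windows (hours within the patterning window) per gene; denser
#: sampling is assigned to the genes with more dynamic patterns
DEFAULT_WINDOWS = {"M": (0.0, 9.0), "H11": (2.0, 27.0), "H13": (4.0, 27.0)}

DEFAULT_RESCALE = {"k": 0.5, "mu": 8.0}
DEFAULT_NOISE_SD = 0.05
H11_LAST_WEIGHT = 20.0

#: curated ground-truth parameters for the crossover topology (Model C).
#: Chosen so the simulated wild type reproduces the canonical marker
#: sequence on the synthetic domain: Meis retreats from the distal bud over
#: the first hours, Hoxa11 switches on distally and resolves into a medial
#: band, Hoxa13 switches on distally-posteriorly (around hour 5 of this
#: compressed synthetic window) and expands while excluding Hoxa11 — and so
#: that the fitted circuit reproduces the classical perturbation responses
#: (RA bead, AER removal, Meis overexpression).
TRUTH_PARAMS_C = {
    "P_FGF4": 0.01,
    "lam_F": 0.0016,
    "lam_R": 0.006,
    "mu": 6.0,
    "mu_tilde": 8.0,
    "c1": 0.5,
    "k1": 1.1,
    "k2": 0.7,
    "k7": 0.3,
    "k_FH11": 0.45,
    "k_RH13": 0.1,
}

#: Model F adds the Meis -| Cyp26b1 link; with the threshold at the top of
#: the wild-type Meis range the link is inert in the control (distal Meis is
#: low where Cyp26b1 is expressed) but engages under uniform overexpression.
TRUTH_PARAMS_F = {**TRUTH_PARAMS_C, "k_MC": 1.0}
#: Model E adds direct Meis -| Hoxa13; slightly higher threshold so ectopic
#: Meis lowers Hoxa13 levels without extinguishing the domain.
TRUTH_PARAMS_E = {**TRUTH_PARAMS_C, "k_MH13": 1.1}


#: stylized display parameter sets for the alternative minimal topologies,
#: chosen (same upstream circuit as the truth set) so each model expresses a
#: visible late Hoxa11 band and therefore shows its characteristic boundary
#: geometry: Model A bounds H11 by two RA isoclines, Model B by two FGF
#: isoclines, Model D (anti-crossover) proximally by RA and distally by FGF.
_UPSTREAM_TRUTH = {k: v for k, v in TRUTH_PARAMS_C.items()
                   if k not in ("k_FH11", "k_RH13")}
DISPLAY_PARAMS = {
    "A": {**_UPSTREAM_TRUTH, "k_RH11": 0.5, "k_RH13": 0.15},
    "B": {**_UPSTREAM_TRUTH, "k_FH11": 0.4, "k_FH13": 1.0},
    "D": {**_UPSTREAM_TRUTH, "k_RH11": 0.5, "k_FH13": 1.0},
}


def display_params(model_name: str) -> dict:
    """Curated parameters that make a topology's H11 geometry visible."""
    if model_name in DISPLAY_PARAMS:
        return dict(DISPLAY_PARAMS[model_name])
    return truth_params(model_name)


def truth_params(model_name: str) -> dict:
    if model_name == "F":
        return dict(TRUTH_PARAMS_F)
    if model_name == "E":
        return dict(TRUTH_PARAMS_E)
    if model_name == "C":
        return dict(TRUTH_PARAMS_C)
    raise KeyError(f"no curated truth parameters for model {model_name!r}")


def sigmoid_rescale(x, k: float = DEFAULT_RESCALE["k"],
                    mu: float = DEFAULT_RESCALE["mu"]):
    """Scaling Hill function x^mu / (k^mu + x^mu) applied elementwise.

    Monotone, so the rank order of elements is preserved; with a steep mu it
    soft-thresholds low values and saturates high ones, which is what makes
    the objective sensitive to domain shape rather than absolute level.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sigmoid_rescale expects non-negative values")
    xm = x ** mu
    return xm / (k ** mu + xm)


@dataclass
class Observation:
    """One staged snapshot of one gene on one hourly mesh."""

    gene: str
    hour: float
    mesh_hour: int
    values: np.ndarray            # rescaled, in [0, 1]
    weight: float = 1.0
    raw: np.ndarray | None = None  # noisy pre-rescale field, kept for
    # regeneration under an altered rescaling


@dataclass
class ExpressionDataset:
    observations: list[Observation]
    rescale: dict
    provenance: dict = field(default_factory=dict)

    def for_gene(self, gene: str) -> list[Observation]:
        return [o for o in self.observations if o.gene == gene]

    def counts(self) -> dict[str, int]:
        return {g: len(self.for_gene(g)) for g in GENES}

    def total_weight(self) -> float:
        return sum(o.weight for o in self.observations)


def generate_ground_truth(series: GrowthSeries,
                          truth_model: NetworkModel | str = "C",
                          params: dict | None = None,
                          hours: tuple[int, int] = (0, 27),
                          output_every: float = 30.0,
                          dt: float = 2.0, **kwargs) -> FieldTrajectory:
    """Simulate the ground-truth wild-type trajectory."""
    if isinstance(truth_model, str):
        truth_model = make_model(truth_model)
    if params is None:
        params = truth_params(truth_model.name)
    return simulate(series, truth_model, params, hours=hours,
                    output_every=output_every, dt=dt, **kwargs)


def observation_hours(traj: FieldTrajectory, counts: dict | None = None,
                      windows: dict | None = None) -> dict[str, np.ndarray]:
    """Evenly spaced observation hours per gene, snapped to the output grid."""
    counts = dict(DEFAULT_COUNTS, **(counts or {}))
    windows = dict(DEFAULT_WINDOWS, **(windows or {}))
    grid = np.asarray(traj.hours)
    out = {}
    for gene in GENES:
        n = counts[gene]
        lo, hi = windows[gene]
        lo, hi = max(lo, grid.min()), min(hi, grid.max())
        if lo >= hi:  # active window outside the simulated span
            lo, hi = grid.min(), grid.max()
        targets = np.linspace(lo, hi, n)
        idx = np.unique([int(np.argmin(np.abs(grid - t))) for t in targets])
        if len(idx) < n:
            raise ValueError(
                f"cannot place {n} distinct {gene} observations on the "
                f"output grid within window ({lo}, {hi}); record more "
                f"frequent outputs or widen the window")
        out[gene] = grid[idx]
    return out


def sample_observations(traj: FieldTrajectory, counts: dict | None = None,
                        noise_sd: float = DEFAULT_NOISE_SD,
                        rescale: dict | None = None, seed: int = 0,
                        windows: dict | None = None,
                        keep_raw: bool = True) -> ExpressionDataset:
    """Draw a staged, noisy, rescaled dataset from a simulated trajectory.

    Noise is truncated Gaussian on the raw concentration (clipped at 0), the
    sigmoid rescaling is then applied and the result clamped to [0, 1].  All
    weights are 1 except the last Hoxa11 time-point, which is weighted 20
    because its complex late shape is particularly important to recreate.
    """
    rescale = dict(DEFAULT_RESCALE, **(rescale or {}))
    hours = observation_hours(traj, counts, windows)
    rng = np.random.default_rng(seed)
    obs: list[Observation] = []
    for gene in GENES:
        s = SPECIES_INDEX[gene]
        for j, hour in enumerate(hours[gene]):
            i = traj.index_at_hour(hour)
            raw = traj.fields[i][s].copy()
            if noise_sd > 0:
                raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
            raw = np.clip(raw, 0.0, None)
            values = np.clip(sigmoid_rescale(raw, **rescale), 0.0, 1.0)
            weight = H11_LAST_WEIGHT if (gene == "H11"
                                         and j == len(hours[gene]) - 1) else 1.0
            obs.append(Observation(gene=gene, hour=float(hour),
                                   mesh_hour=traj.mesh_hours[i], values=values,
                                   weight=weight,
                                   raw=raw if keep_raw else None))
    return ExpressionDataset(
        observations=obs, rescale=rescale,
        provenance={"noise_sd": noise_sd, "seed": seed,
                    "counts": {g: len(hours[g]) for g in GENES},
                    "truth": dict(traj.provenance)})


def alternative_rescaling(dataset: ExpressionDataset, k: float,
                          mu: float) -> ExpressionDataset:
    """Regenerate the dataset under altered sigmoid parameters.

    Emulates under-developing the colour reaction of the in situ: the same
    raw (noisy) fields are re-thresholded, changing the apparent patterns
    without changing the underlying data.
    """
    new_obs = []
    for o in dataset.observations:
        if o.raw is None:
            raise ValueError("raw fields were not retained; regenerate the "
                             "dataset with keep_raw=True")
        values = np.clip(sigmoid_rescale(o.raw, k=k, mu=mu), 0.0, 1.0)
        new_obs.append(replace(o, values=values))
    return ExpressionDataset(observations=new_obs,
                             rescale={"k": k, "mu": mu},
                             provenance={**dataset.provenance,
                                         "rescaled_from": dataset.rescale})


def halve_observations(dataset: ExpressionDataset,
                       genes: tuple[str, ...] = ("H11", "H13")) -> ExpressionDataset:
    """Keep every second time-point of the listed genes (Meis untouched).

    The odd-indexed points are kept so the heavily weighted last Hoxa11
    observation survives the halving (26 -> 13, 32 -> 16).
    """
    new_obs = []
    for gene in GENES:
        gene_obs = dataset.for_gene(gene)
        if gene in genes:
            gene_obs = gene_obs[1::2]
        new_obs.extend(gene_obs)
    return ExpressionDataset(observations=new_obs, rescale=dict(dataset.rescale),
                             provenance={**dataset.provenance, "halved": list(genes)})
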