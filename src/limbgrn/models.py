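"""Regulatory circuits for proximodistal limb patterning.

Six species are tracked: the diffusible morphogens FGF (F, produced along the
AER) and retinoic acid (R, produced at the embryo flank), the RA-degrading
enzyme Cyp26b1 (C), and the three segment markers Meis (M, stylopod),
Hoxa11 (H11, zeugopod) and Hoxa13 (H13, autopod).  The upstream circuit is
common to every topology: FGF induces Cyp26b1 (threshold k1), Cyp26b1
degrades RA linearly with strength c1, RA activates Meis (threshold k2), and
Hoxa13 represses Hoxa11 (threshold k7) with its own, typically much steeper,
Hill coefficient (mu_tilde) because this repression is experimentally seen to
be very fast.

The candidate topologies differ only in how the opposing RA/FGF gradients
feed into the Hox genes:

======  =========================================================
A       R -| H11,  R -| H13        (RA-dominant)
B       F -> H11,  F -> H13        (FGF-dominant)
C       F -> H11,  R -| H13        (the "crossover" wiring)
D       R -| H11,  F -> H13        (anti-crossover)
E       C plus M -| H13            (direct Meis repression of Hoxa13)
F       C plus M -| C              (indirect, via Cyp26b1)
X0      all four RA/FGF -> Hox links (super-model)
X1..X4  X0 minus one RA/FGF -> Hox link each
======  =========================================================

All regulatory interactions are Hill functions; multiple regulators of one
gene combine multiplicatively.  The linear RA degradation term -c1*C*R is
applied by the solver, not by :func:`production_rates`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

SPECIES = ("F", "R", "C", "M", "H11", "H13")
SPECIES_INDEX = {s: i for i, s in enumerate(SPECIES)}
F, R, C, M, H11, H13 = range(6)

#: fixed parameter values; rates in 1/min, diffusion in um^2/min.
#: Production and decay of the non-diffusible species are fixed at 0.05/min so
#: their maximum steady-state concentration is 1.0 (relative units).
FIXED_PARAMS = {
    "P_C": 0.05, "P_M": 0.05, "P_H11": 0.05, "P_H13": 0.05,
    "lam_C": 0.05, "lam_M": 0.05, "lam_H11": 0.05, "lam_H13": 0.05,
    "D_F": 100.0, "D_R": 600.0,
    # Source strengths of the two morphogen inputs.  These are fixed (not
    # optimized); their values set the overall concentration scale of the
    # gradients so that regulatory thresholds fall inside the k bounds.
    "P_FGF8": 0.015, "P_R": 0.3,
}

#: free parameters shared by every topology (model-specific link thresholds
#: are added per model)
COMMON_FREE = ("P_FGF4", "lam_F", "lam_R", "mu", "mu_tilde", "c1",
               "k1", "k2", "k7")


class HillDomainError(ValueError):
    pass


def hill_act(x, k, mu):
    """Activating Hill function x^mu / (k^mu + x^mu), in [0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise HillDomainError("negative concentration passed to hill_act")
    if k <= 0 or mu <= 0:
        raise HillDomainError("Hill threshold and coefficient must be positive")
    xm = x ** mu
    return xm / (k ** mu + xm)


def hill_inh(x, k, mu):
    """Inhibiting Hill function k^mu / (k^mu + x^mu) = 1 - hill_act."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise HillDomainError("negative concentration passed to hill_inh")
    if k <= 0 or mu <= 0:
        raise HillDomainError("Hill threshold and coefficient must be positive")
    km = k ** mu
    return km / (km + x ** mu)


@dataclass(frozen=True)
class RegulatoryLink:
    """One signed Hill link; ``param`` names its threshold, ``hill`` selects
    the shared coefficient ``mu`` or the distinct ``mu_tilde``."""

    source: str
    target: str
    sign: str          # "act" | "inh"
    param: str         # threshold parameter name, e.g. "k_FH11"
    hill: str = "mu"   # "mu" | "mu_tilde"

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)

    def describe(self) -> str:
        arrow = "->" if self.sign == "act" else "-|"
        return f"{self.source}{arrow}{self.target}"


_UPSTREAM = (
    RegulatoryLink("F", "C", "act", "k1"),
    RegulatoryLink("R", "M", "act", "k2"),
    RegulatoryLink("H13", "H11", "inh", "k7", hill="mu_tilde"),
)

_HOX_LINKS = {
    ("R", "H11"): RegulatoryLink("R", "H11", "inh", "k_RH11"),
    ("R", "H13"): RegulatoryLink("R", "H13", "inh", "k_RH13"),
    ("F", "H11"): RegulatoryLink("F", "H11", "act", "k_FH11"),
    ("F", "H13"): RegulatoryLink("F", "H13", "act", "k_FH13"),
}

_MODEL_HOX = {
    "A": (("R", "H11"), ("R", "H13")),
    "B": (("F", "H11"), ("F", "H13")),
    "C": (("F", "H11"), ("R", "H13")),
    "D": (("R", "H11"), ("F", "H13")),
    "X0": (("R", "H11"), ("R", "H13"), ("F", "H11"), ("F", "H13")),
}
# X1..X4: the super-model minus one RA/FGF->Hox link each
_X_ORDER = (("R", "H11"), ("R", "H13"), ("F", "H11"), ("F", "H13"))
for _i, _drop in enumerate(_X_ORDER, start=1):
    _MODEL_HOX[f"X{_i}"] = tuple(k for k in _X_ORDER if k != _drop)

_EXTRA = {
    "E": RegulatoryLink("M", "H13", "inh", "k_MH13"),
    "F": RegulatoryLink("M", "C", "inh", "k_MC"),
}

MODEL_NAMES = ("A", "B", "C", "D", "E", "F", "X0", "X1", "X2", "X3", "X4")


@dataclass(frozen=True)
class SpeciesSpec:
    """Kinetic constants of one species; D = 0 for non-diffusible species."""

    name: str
    diffusion: float      # um^2/min
    decay_param: str      # parameter name of the decay rate
    production_param: str | None  # None => produced by regulation only


@dataclass(frozen=True)
class NetworkModel:
    name: str
    links: tuple[RegulatoryLink, ...]

    @property
    def free_parameters(self) -> tuple[str, ...]:
        extra = tuple(l.param for l in self.links
                      if l.param not in ("k1", "k2", "k7"))
        return COMMON_FREE + extra

    def links_into(self, target: str) -> tuple[RegulatoryLink, ...]:
        return tuple(l for l in self.links if l.target == target)

    def hox_links(self) -> tuple[RegulatoryLink, ...]:
        return tuple(l for l in self.links
                     if l.target in ("H11", "H13") and l.source in ("R", "F"))

    def has_link(self, source: str, target: str) -> bool:
        return any(l.key == (source, target) for l in self.links)

    def species_specs(self) -> tuple[SpeciesSpec, ...]:
        return (
            SpeciesSpec("F", FIXED_PARAMS["D_F"], "lam_F", "P_FGF8"),
            SpeciesSpec("R", FIXED_PARAMS["D_R"], "lam_R", "P_R"),
            SpeciesSpec("C", 0.0, "lam_C", None),
            SpeciesSpec("M", 0.0, "lam_M", None),
            SpeciesSpec("H11", 0.0, "lam_H11", None),
            SpeciesSpec("H13", 0.0, "lam_H13", None),
        )


def make_model(name: str) -> NetworkModel:
    """Build one of the named topologies A-F, X0-X4."""
    if name not in MODEL_NAMES:
        raise KeyError(f"unknown model {name!r}; valid: {MODEL_NAMES}")
    if name in ("E", "F"):
        hox = _MODEL_HOX["C"]
        extra = (_EXTRA[name],)
    else:
        hox = _MODEL_HOX[name]
        extra = ()
    links = _UPSTREAM + tuple(_HOX_LINKS[k] for k in hox) + extra
    return NetworkModel(name=name, links=links)


def ablate_link(model: NetworkModel, key: tuple[str, str]) -> NetworkModel:
    """Remove one RA/FGF -> Hox link (and its threshold) from ``model``."""
    key = tuple(key)
    if key not in _HOX_LINKS:
        raise KeyError(f"{key} is not an ablatable RA/FGF->Hox link")
    if not model.has_link(*key):
        raise KeyError(f"model {model.name} has no link {key}")
    links = tuple(l for l in model.links if l.key != key)
    return replace(model, name=f"{model.name}-{key[0]}{key[1]}", links=links)


def _link_factor(link: RegulatoryLink, state: np.ndarray, params: dict):
    x = state[SPECIES_INDEX[link.source]]
    k = params[link.param]
    mu = params[link.hill]
    return hill_act(x, k, mu) if link.sign == "act" else hill_inh(x, k, mu)


def make_production_fn(model: NetworkModel, params: dict,
                       flank_mask: np.ndarray, aer_mask: np.ndarray,
                       fgf4_mask: np.ndarray):
    """Compile the production fields for fixed parameters and masks.

    Used by the solver's inner loop: the source fields and every k^mu are
    precomputed, and x^mu is shared between links reading the same species
    with the same Hill coefficient.  Semantics match
    :func:`production_rates` exactly (validated by tests).
    """
    prod_f = FIXED_PARAMS["P_FGF8"] * aer_mask + params["P_FGF4"] * fgf4_mask
    prod_r = FIXED_PARAMS["P_R"] * flank_mask
    targets = []
    for target, p_name in (("C", "P_C"), ("M", "P_M"),
                           ("H11", "P_H11"), ("H13", "P_H13")):
        terms = []
        for link in model.links_into(target):
            if link.param not in params:
                raise KeyError(f"missing parameter {link.param!r} for active "
                               f"link {link.describe()} of model {model.name}")
            mu = params[link.hill]
            terms.append((SPECIES_INDEX[link.source], mu,
                          params[link.param] ** mu, link.sign == "act"))
        targets.append((SPECIES_INDEX[target], FIXED_PARAMS[p_name], terms))

    def production(state: np.ndarray, out: np.ndarray) -> np.ndarray:
        out[F] = prod_f
        out[R] = prod_r
        cache = {}
        for t_idx, p_max, terms in targets:
            acc = p_max
            for s_idx, mu, km, is_act in terms:
                key = (s_idx, mu)
                xm = cache.get(key)
                if xm is None:
                    xm = state[s_idx] ** mu
                    cache[key] = xm
                acc = acc * (xm / (km + xm)) if is_act \
                    else acc * (km / (km + xm))
            out[t_idx] = acc
        return out

    return production


def production_rates(state: np.ndarray, model: NetworkModel, params: dict,
                     flank_mask: np.ndarray, aer_mask: np.ndarray,
                     fgf4_mask: np.ndarray) -> np.ndarray:
    """Per-species, per-element production fields (1/min).

    ``state`` is (6, n_elements).  FGF production combines the uniform AER
    source (P_FGF8) and the posteriorly biased FGF4 source (P_FGF4); RA is
    produced in flank elements at the fixed rate P_R.  Regulated species are
    produced at their fixed maximal rate times the product of their incoming
    Hill factors.  The linear RA degradation -c1*C*R belongs to the solver.
    """
    if state.shape[0] != len(SPECIES):
        raise ValueError("state must have one row per species")
    prod = np.zeros_like(state)
    prod[F] = FIXED_PARAMS["P_FGF8"] * aer_mask + params["P_FGF4"] * fgf4_mask
    prod[R] = FIXED_PARAMS["P_R"] * flank_mask
    for target, p_name in (("C", "P_C"), ("M", "P_M"),
                           ("H11", "P_H11"), ("H13", "P_H13")):
        links = model.links_into(target)
        fac = FIXED_PARAMS[p_name]
        term = np.full(state.shape[1], fac)
        for link in links:
            if link.param not in params:
                raise KeyError(f"missing parameter {link.param!r} for active "
                               f"link {link.describe()} of model {model.name}")
            term = term * _link_factor(link, state, params)
        prod[SPECIES_INDEX[target]] = term
    return prod
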