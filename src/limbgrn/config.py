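"""Run configuration: one structured file collecting every knob.

The defaults reproduce the study conditions: fixed 0.05/min production and
decay for the downstream species, D_R = 600 and D_F = 100 um^2/min, the 3-h
gradient presimulation, hourly remeshing over the patterning window, the
4/26/32 observation counts with weight 20 on the last Hoxa11 time-point,
and the 27-start optimization protocol.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    domain: dict = field(default_factory=lambda: {
        "n_hours": 27, "target_edge": 65.0, "geometry": {}})
    solver: dict = field(default_factory=lambda: {
        "dt": 2.0, "scheme": "imex", "output_every": 30.0,
        "presim_duration": 180.0, "presim_mode": "upstream"})
    model: dict = field(default_factory=lambda: {"name": "C"})
    dataset: dict = field(default_factory=lambda: {
        "truth_model": "C", "counts": {"M": 4, "H11": 26, "H13": 32},
        "noise_sd": 0.05, "rescale": {"k": 0.5, "mu": 8.0}, "seed": 0})
    optimization: dict = field(default_factory=lambda: {
        "n_starts": 27, "budget": 36, "refine_top": 1, "refine_budget": 300,
        "polish_budget": 0, "seed": 0,
        "models": ["A", "B", "C", "D"]})
    out_dir: str = "runs/default"

    _REQUIRED = ("domain", "solver", "model", "dataset", "optimization")

    def validate(self) -> None:
        for key in ("n_hours", "target_edge"):
            if key not in self.domain:
                raise ValueError(f"domain config missing {key!r}")
        if self.solver.get("scheme") not in ("imex", "euler"):
            raise ValueError("solver.scheme must be 'imex' or 'euler'")
        if 60.0 % self.solver.get("output_every", 30.0) != 0:
            raise ValueError("solver.output_every must divide 60")
        for key in ("counts", "noise_sd", "rescale"):
            if key not in self.dataset:
                raise ValueError(f"dataset config missing {key!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def sim_opts(self, n_hours: int | None = None) -> dict:
        s = self.solver
        return {
            "hours": (0, n_hours if n_hours is not None
                      else self.domain["n_hours"]),
            "dt": s.get("dt", 2.0), "scheme": s.get("scheme", "imex"),
            "output_every": s.get("output_every", 30.0),
            "presim_duration": s.get("presim_duration", 180.0),
            "presim_mode": s.get("presim_mode", "upstream"),
        }
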