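"""Run configuration: YAML round-trip and model construction."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .aom_sr import DEFAULT_SCENARIO, build_aomsr_model
from .model_core import ConsortiumModel

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``scenario`` holds boundary conditions (pH, temperature, environmental
    concentrations); ``overrides`` optional ``phi`` / ``nu_plus`` blocks
    keyed ``CELL.REACTION``; integrator and optimizer blocks carry numeric
    options.  Every CLI run writes its resolved configuration next to its
    outputs.
    """

    scenario: dict = field(default_factory=lambda: dict(DEFAULT_SCENARIO))
    overrides: dict = field(default_factory=dict)
    integrator: dict = field(default_factory=lambda: {
        "horizon": 1.0e4, "tol": 1.0e-8})
    optimizer: dict = field(default_factory=lambda: {
        "maxiter": 400, "restarts": 3, "f_g_grid": [0.4, 0.45, 0.5, 0.55, 0.6]})
    outdir: str | None = None
    seed: int = 0

    def build_model(self) -> ConsortiumModel:
        return build_aomsr_model(self.scenario, self.overrides or None)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f: data[f] for f in
                 ("scenario", "overrides", "integrator", "optimizer",
                  "outdir", "seed") if f in data}
        cfg = cls(**known)
        scen = dict(DEFAULT_SCENARIO)
        scen.update(cfg.scenario or {})
        cfg.scenario = scen
        return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
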