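"""Run configuration: a strict YAML schema resolved to model objects.

Schema (all keys optional except where noted)::

    model: reference            # or path to an atmkin model text file
    parameters:                 # overrides of named Parameters fields
      k_repair: 0.1
    protocol:
      agent: IR                 # IR | BLM | oxidant | none
      dose_rate: 1.0
      exposure_time: 1.0
    t_span: [0.0, 100.0]
    grid_points: 501
    solver:
      method: BDF
      rtol: 1.0e-6
      atol: 1.0e-9
    repair_mode: independent    # or atm
    output_dir: results
    seed: 0                     # reserved; the model is deterministic

Unknown keys at any level are rejected with the offending name.  All outputs
are dimensionless, matching the model convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .controls import AgentProtocol
from .modelio import read_model
from .network import ReactionNetwork, ValidationError
from .params import Parameters, default_parameters
from .reference import build_atm_network
from .simulator import ShuttlingSpec, SolverOptions, reference_shuttling

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValidationError):
    """A configuration file violates the schema."""


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigError(f"{where}: unknown key(s): {', '.join(unknown)}")


@dataclass
class RunConfig:
    model: str = "reference"
    parameters: dict[str, float] = field(default_factory=dict)
    protocol: AgentProtocol = field(default_factory=AgentProtocol)
    t_span: tuple[float, float] = (0.0, 100.0)
    grid_points: int = 501
    solver: SolverOptions = field(default_factory=SolverOptions)
    repair_mode: str = "independent"
    output_dir: str = "results"
    seed: int = 0

    def resolved_parameters(self) -> Parameters:
        return default_parameters().with_overrides(self.parameters)

    def build(self) -> tuple[ReactionNetwork, ShuttlingSpec, Parameters]:
        """Materialise the network and shuttling spec this config describes."""
        params = self.resolved_parameters()
        if self.model == "reference":
            network = build_atm_network(params)
        else:
            network = read_model(self.model)
        shuttling = reference_shuttling(network, params)
        return network, shuttling, params

    def echo(self) -> str:
        """Fully-resolved YAML (re-running it reproduces the outputs)."""
        return yaml.safe_dump(
            {
                "model": self.model,
                "parameters": self.resolved_parameters().as_dict(),
                "protocol": {
                    "agent": self.protocol.agent,
                    "dose_rate": self.protocol.dose_rate,
                    "exposure_time": self.protocol.exposure_time,
                },
                "t_span": list(self.t_span),
                "grid_points": self.grid_points,
                "solver": {
                    "method": self.solver.method,
                    "rtol": self.solver.rtol,
                    "atol": self.solver.atol,
                },
                "repair_mode": self.repair_mode,
                "output_dir": self.output_dir,
                "seed": self.seed,
            },
            sort_keys=False,
        )


def _parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(
        data,
        {
            "model",
            "parameters",
            "protocol",
            "t_span",
            "grid_points",
            "solver",
            "repair_mode",
            "output_dir",
            "seed",
        },
        "config",
    )
    cfg = RunConfig()
    cfg.model = str(data.get("model", cfg.model))
    pars = data.get("parameters") or {}
    if not isinstance(pars, dict):
        raise ConfigError("parameters: must be a mapping")
    # validate override names eagerly so the error points at the file
    default_parameters().with_overrides(pars)
    cfg.parameters = {k: float(v) for k, v in pars.items()}
    proto = data.get("protocol") or {}
    _check_keys(proto, {"agent", "dose_rate", "exposure_time"}, "protocol")
    cfg.protocol = AgentProtocol(
        agent=str(proto.get("agent", "none")),
        dose_rate=float(proto.get("dose_rate", 0.0)),
        exposure_time=float(proto.get("exposure_time", 0.0)),
    )
    span = data.get("t_span", list(cfg.t_span))
    if not (isinstance(span, (list, tuple)) and len(span) == 2):
        raise ConfigError("t_span: must be a pair [start, end]")
    cfg.t_span = (float(span[0]), float(span[1]))
    if cfg.t_span[0] >= cfg.t_span[1]:
        raise ConfigError("t_span: start must be < end")
    cfg.grid_points = int(data.get("grid_points", cfg.grid_points))
    if cfg.grid_points < 2:
        raise ConfigError("grid_points: must be >= 2")
    solver = data.get("solver") or {}
    _check_keys(solver, {"method", "rtol", "atol", "max_step"}, "solver")
    cfg.solver = SolverOptions(
        method=str(solver.get("method", "BDF")),
        rtol=float(solver.get("rtol", 1e-6)),
        atol=float(solver.get("atol", 1e-9)),
        max_step=float(solver.get("max_step", float("inf"))),
    )
    cfg.repair_mode = str(data.get("repair_mode", "independent"))
    if cfg.repair_mode not in ("independent", "atm"):
        raise ConfigError(f"repair_mode: unknown mode {cfg.repair_mode!r}")
    cfg.output_dir = str(data.get("output_dir", "results"))
    cfg.seed = int(data.get("seed", 0))
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"configuration file not found: {p}")
    data = yaml.safe_load(p.read_text())
    if data is None:
        data = {}
    return _parse_config(data)
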