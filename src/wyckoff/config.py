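"""Run configuration: one YAML/JSON file with params, solver and MC blocks.

Schema (all blocks optional except ``params``; CLI flags override file
values):

.. code-block:: yaml

    params:            # flat mapping, all 18 keys required
      theta1: 0.2      # ... theta8
      lambda1: 0.0     # ... lambda8
      u1: 0.5
      u2: 0.5
    solver:
      grid_nodes: 1001
      mode: free       # or pinned
      tol: 1.0e-10
      max_iter: 10000
      init: zero       # or identity
      boundary0: 0.0   # pinned-mode W(0)
      boundary1: 1.0   # pinned-mode W(1)
    mc:
      x0: 0.5
      depth: 20
      n_paths: 100000
      n_chains: 1000
      n_trials: 100
    seed: 0
    output_dir: runs
    emit_plots: false
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelParams, ParameterError
from .solver import SolverOptions

__all__ = ["MCSettings", "RunConfig", "load_config"]

_SOLVER_KEYS = {"grid_nodes", "mode", "tol", "max_iter", "init", "boundary0", "boundary1"}
_MC_KEYS = {"x0", "depth", "n_paths", "n_chains", "n_trials"}
_TOP_KEYS = {"params", "solver", "mc", "seed", "output_dir", "emit_plots"}


@dataclass(frozen=True)
class MCSettings:
    """Monte Carlo block: initial state, estimator depth and sample sizes."""

    x0: float = 0.5
    depth: int = 20
    n_paths: int = 10_000
    n_chains: int = 1_000
    n_trials: int = 100

    def __post_init__(self):
        if not 0.0 <= self.x0 <= 1.0:
            raise ParameterError(f"mc.x0 must lie in [0, 1], got {self.x0!r}")
        for name in ("depth", "n_trials"):
            if getattr(self, name) < 0:
                raise ParameterError(f"mc.{name} must be nonnegative")
        if self.n_paths < 1:
            raise ParameterError("mc.n_paths must be at least 1")
        if self.n_chains < 2:
            raise ParameterError("mc.n_chains must be at least 2")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one CLI run."""

    params: ModelParams
    solver: SolverOptions = field(default_factory=SolverOptions)
    mc: MCSettings = field(default_factory=MCSettings)
    seed: int = 0
    output_dir: Path = Path("runs")
    emit_plots: bool = False


def _solver_options(block: dict) -> SolverOptions:
    unknown = sorted(set(block) - _SOLVER_KEYS)
    if unknown:
        raise ParameterError(f"unknown solver key(s): {', '.join(unknown)}")
    kwargs: dict = {}
    if "grid_nodes" in block:
        kwargs["n_nodes"] = int(block["grid_nodes"])
    if "mode" in block:
        kwargs["mode"] = str(block["mode"])
    if "tol" in block:
        kwargs["tol"] = float(block["tol"])
    if "max_iter" in block:
        kwargs["max_iter"] = int(block["max_iter"])
    if "init" in block:
        kwargs["init"] = str(block["init"])
    b0 = float(block.get("boundary0", 0.0))
    b1 = float(block.get("boundary1", 1.0))
    kwargs["boundary_values"] = (b0, b1)
    return SolverOptions(**kwargs)


def parse_config(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a parsed mapping."""
    if not isinstance(raw, dict):
        raise ParameterError("config root must be a mapping")
    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        raise ParameterError(f"unknown config key(s): {', '.join(unknown)}")
    if "params" not in raw:
        raise ParameterError("config is missing the 'params' block")
    params = ModelParams.from_dict(raw["params"])
    solver = _solver_options(raw.get("solver", {}) or {})
    mc_block = raw.get("mc", {}) or {}
    unknown = sorted(set(mc_block) - _MC_KEYS)
    if unknown:
        raise ParameterError(f"unknown mc key(s): {', '.join(unknown)}")
    mc = MCSettings(**{k: v for k, v in mc_block.items()})
    return RunConfig(
        params=params,
        solver=solver,
        mc=mc,
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw.get("output_dir", "runs")),
        emit_plots=bool(raw.get("emit_plots", False)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return parse_config(raw)
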