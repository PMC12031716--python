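"""Trial-by-trial simulation of the event chain and Monte Carlo estimation.

The state x_n (attention probability on trial n) evolves as a Markov chain:
one of the eight events is drawn with the current event probabilities, and
the matching learning operator is applied.  This module provides the
single-trial and whole-chain simulators, learning-curve statistics across
independent chains, a path-sampling Monte Carlo estimator of the Picard
iterates of the asymptotic equation, and a deterministic-vs-Monte-Carlo
comparison table.

The Monte Carlo scheme: the depth-N Picard iterate started from a terminal
function W0 satisfies W_N(x0) = E[W0(X_N)] where X_N is the chain after N
trials from x0 (up to grid interpolation of W0).  Averaging W0 over
simulated endpoints is therefore an unbiased estimator of the deterministic
iterate, making solver-vs-simulation error analysis well-posed.

Event sampling uses a single uniform draw per trial against the cumulative
event probabilities in fixed E1..E8 order, so runs are bit-reproducible
given the generator state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import (
    EVENTS,
    ModelParams,
    ParameterError,
    apply_operator,
    contraction_constants,
    event_probabilities,
)
from .solver import GridFunction, apply_Z

__all__ = [
    "TrialStep",
    "Trajectory",
    "MCEstimate",
    "simulate_trial",
    "simulate_chain",
    "simulate_states",
    "learning_curve",
    "mc_estimate_W",
    "compare_solvers",
]


@dataclass(frozen=True)
class TrialStep:
    """One trial: state before, event index drawn, state after."""

    trial: int
    x_before: float
    event: int
    x_after: float


@dataclass(frozen=True)
class Trajectory:
    """A simulated chain: initial state plus the per-trial steps."""

    x0: float
    steps: tuple[TrialStep, ...]

    @property
    def states(self) -> np.ndarray:
        """States x_0..x_N including the initial one."""
        return np.array([self.x0] + [s.x_after for s in self.steps])

    @property
    def events(self) -> np.ndarray:
        return np.array([s.event for s in self.steps], dtype=int)

    def to_frame(self, chain: int = 0) -> pd.DataFrame:
        """Tabular export with event semantics (choice, outcome, reward)."""
        rows = []
        for s in self.steps:
            ev = EVENTS[s.event - 1]
            rows.append(
                {
                    "chain": chain,
                    "trial": s.trial,
                    "x": s.x_before,
                    "event": s.event,
                    "choice": ev.choice,
                    "outcome": ev.outcome,
                    "reward": int(ev.rewarded),
                }
            )
        return pd.DataFrame(
            rows, columns=["chain", "trial", "x", "event", "choice", "outcome", "reward"]
        )


@dataclass(frozen=True)
class MCEstimate:
    """A Monte Carlo point estimate with its standard error."""

    point: float
    stderr: float
    n_paths: int
    depth: int
    seed: int | None = None


def _check_x(x: float) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ParameterError(f"x must lie in [0, 1], got {x!r}")
    return x


def simulate_trial(
    x: float, params: ModelParams, rng: np.random.Generator
) -> tuple[int, float]:
    """Sample one trial: returns (event index 1..8, updated state).

    The event is drawn by inverse CDF over the eight event probabilities in
    fixed E1..E8 order using one uniform variate.
    """
    x = _check_x(x)
    p = event_probabilities(x, params)
    k = int(np.searchsorted(np.cumsum(p), rng.uniform())) + 1
    k = min(k, 8)  # guard against cumsum rounding at u ~ 1
    return k, apply_operator(k, x, params)


def simulate_chain(
    x0: float, n_trials: int, params: ModelParams, rng: np.random.Generator
) -> Trajectory:
    """Run one chain of ``n_trials`` trials from initial state ``x0``."""
    x = _check_x(x0)
    if n_trials < 0:
        raise ParameterError("n_trials must be nonnegative")
    steps = []
    for n in range(int(n_trials)):
        k, x_next = simulate_trial(x, params, rng)
        steps.append(TrialStep(trial=n, x_before=x, event=k, x_after=x_next))
        x = x_next
    return Trajectory(x0=float(x0), steps=tuple(steps))


def simulate_states(
    x0, n_trials: int, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised chain simulation: states of many chains, shape (n_chains, n_trials+1).

    ``x0`` may be a scalar (broadcast) or a vector of per-chain initial
    states.  Uses one uniform draw per chain per trial against the
    cumulative event probabilities in E1..E8 order — the same scheme as
    :func:`simulate_trial`, applied to all chains at once.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    if np.any((x < 0) | (x > 1)):
        raise ParameterError("x0 must lie in [0, 1]")
    th, lm = params.theta, params.lam
    out = np.empty((x.size, int(n_trials) + 1))
    out[:, 0] = x
    for n in range(int(n_trials)):
        p = event_probabilities(x, params)  # (n_chains, 8)
        u = rng.uniform(size=x.size)
        k = np.minimum((np.cumsum(p, axis=1) < u[:, None]).sum(axis=1), 7)
        x = th[k] * x + (1 - th[k]) * lm[k]
        out[:, n + 1] = x
    return out


def learning_curve(
    x0: float,
    n_trials: int,
    n_chains: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mean and standard error of x_n across independent chains.

    Returns a DataFrame with columns ``trial`` (0..n_trials), ``mean`` and
    ``stderr``.  With a common (theta, lambda) across events the chain is
    deterministic and the mean follows lambda + theta^n (x0 - lambda).
    """
    if n_chains < 2:
        raise ParameterError("n_chains must be at least 2")
    states = simulate_states(np.full(int(n_chains), _check_x(x0)), n_trials, params, rng)
    mean = states.mean(axis=0)
    stderr = states.std(axis=0, ddof=1) / np.sqrt(n_chains)
    return pd.DataFrame(
        {"trial": np.arange(n_trials + 1), "mean": mean, "stderr": stderr}
    )


def _terminal_callable(terminal) -> Callable:
    if isinstance(terminal, GridFunction):
        return terminal
    if callable(terminal):
        return terminal
    if terminal == "identity":
        return lambda x: np.asarray(x, dtype=float)
    if terminal == "zero":
        return lambda x: np.zeros_like(np.asarray(x, dtype=float))
    raise ParameterError(
        f"terminal must be 'zero', 'identity', a callable or a GridFunction, got {terminal!r}"
    )


def mc_estimate_W(
    x0: float,
    depth: int,
    n_paths: int,
    terminal,
    params: ModelParams,
    rng: np.random.Generator,
    seed: int | None = None,
) -> MCEstimate:
    """Path-sampling estimate of the depth-``depth`` Picard iterate at ``x0``.

    Runs ``n_paths`` independent chains of length ``depth`` from ``x0`` and
    averages ``terminal`` at the endpoints; the sample mean is unbiased for
    (Z^depth terminal)(x0) up to terminal-function interpolation.
    """
    if depth < 0:
        raise ParameterError("depth must be nonnegative")
    if n_paths < 1:
        raise ParameterError("n_paths must be at least 1")
    f = _terminal_callable(terminal)
    x0 = _check_x(x0)
    if depth == 0:
        return MCEstimate(
            point=float(f(x0)), stderr=0.0, n_paths=n_paths, depth=0, seed=seed
        )
    endpoints = simulate_states(np.full(int(n_paths), x0), depth, params, rng)[:, -1]
    contrib = np.asarray(f(endpoints), dtype=float)
    point = float(contrib.mean())
    stderr = float(contrib.std(ddof=1) / np.sqrt(n_paths)) if n_paths > 1 else 0.0
    return MCEstimate(point=point, stderr=stderr, n_paths=n_paths, depth=depth, seed=seed)


def compare_solvers(
    params: ModelParams,
    x0_grid: Sequence[float],
    depth: int,
    n_paths: int,
    rng: np.random.Generator,
    terminal="identity",
    n_nodes: int = 1001,
    warn_non_contraction: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Deterministic depth-N iterate vs Monte Carlo estimate over ``x0_grid``.

    The deterministic column applies Z ``depth`` times to the terminal
    function on an ``n_nodes`` uniform grid and reads off interpolated
    values; the Monte Carlo column calls :func:`mc_estimate_W` at each x0.
    Returns the per-x0 table (columns x0, deterministic, mc, abs_error,
    stderr) and a summary dict with the max absolute error and mean stderr.
    """
    import warnings as _warnings

    K1 = contraction_constants(params).K1
    if warn_non_contraction and K1 >= 1.0:
        _warnings.warn(
            f"K1*={K1:.4g} >= 1: iterates may not converge; comparison still "
            "valid at fixed depth",
            RuntimeWarning,
            stacklevel=2,
        )
    f = _terminal_callable(terminal)
    W = GridFunction.uniform(n_nodes, f)
    for _ in range(int(depth)):
        W = apply_Z(W, params)

    rows = []
    for x0 in x0_grid:
        est = mc_estimate_W(float(x0), depth, n_paths, f, params, rng)
        det = float(W(float(x0)))
        rows.append(
            {
                "x0": float(x0),
                "deterministic": det,
                "mc": est.point,
                "abs_error": abs(est.point - det),
                "stderr": est.stderr,
            }
        )
    table = pd.DataFrame(rows, columns=["x0", "deterministic", "mc", "abs_error", "stderr"])
    summary = {
        "max_abs_error": float(table["abs_error"].max()),
        "mean_stderr": float(table["stderr"].mean()),
        "depth": int(depth),
        "n_paths": int(n_paths),
        "K1": K1,
    }
    return table, summary
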