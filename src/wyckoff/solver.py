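"""Grid representation of the asymptotic choice function W and its solver.

The model's long-run choice behaviour is characterised by a function
W : [0,1] -> R satisfying the functional equation W = ZW, where

    (ZW)(x) = sum_k p_k(x) * W(P_k x)

averages W over the eight one-trial updates P_k weighted by the event
probabilities p_k(x).  Z is affine in W, maps constants to themselves, and
is a contraction in the Lipschitz seminorm whenever the constant K1* is
below 1, in which case Picard iteration W_n = Z W_{n-1} converges
geometrically to the unique fixed point.

W is represented by its values on a grid over [0,1]; off-node arguments
P_k x are evaluated by linear interpolation.  Because the equation is
homogeneous, the unique fixed point in the contraction regime is the zero
function; a ``pinned`` solver mode clamps W(0), W(1) to chosen boundary
values after every sweep to expose nontrivial absorption-style solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np

from .model import ModelParams, ParameterError, contraction_constants, event_probabilities

__all__ = [
    "GridFunction",
    "SolverOptions",
    "ConvergenceReport",
    "apply_Z",
    "picard_solve",
    "lipschitz_seminorm",
    "boundary_probe",
]


@dataclass(frozen=True)
class GridFunction:
    """A function on [0,1] stored as values at strictly increasing nodes.

    Nodes must span [0,1] inclusive with at least 3 nodes; between nodes
    the function is piecewise linear.
    """

    nodes: np.ndarray
    values: np.ndarray

    def __init__(self, nodes, values):
        nodes = np.asarray(nodes, dtype=float)
        values = np.asarray(values, dtype=float)
        if nodes.ndim != 1 or nodes.size < 3:
            raise ParameterError("grid needs at least 3 one-dimensional nodes")
        if nodes.shape != values.shape:
            raise ParameterError(
                f"nodes and values lengths differ: {nodes.size} vs {values.size}"
            )
        if nodes[0] != 0.0 or nodes[-1] != 1.0:
            raise ParameterError("grid must span [0, 1] including both endpoints")
        if np.any(np.diff(nodes) <= 0):
            raise ParameterError("grid nodes must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ParameterError("grid values must be finite")
        object.__setattr__(self, "nodes", nodes.copy())
        object.__setattr__(self, "values", values.copy())
        self.nodes.flags.writeable = False
        self.values.flags.writeable = False

    @classmethod
    def uniform(cls, n_nodes: int = 1001, fn: Callable | None = None) -> "GridFunction":
        """Uniform grid with ``n_nodes`` nodes; values from ``fn`` (default 0)."""
        x = np.linspace(0.0, 1.0, int(n_nodes))
        v = np.zeros_like(x) if fn is None else np.asarray(fn(x), dtype=float)
        return cls(x, v)

    @classmethod
    def zero(cls, n_nodes: int = 1001) -> "GridFunction":
        return cls.uniform(n_nodes)

    @classmethod
    def identity(cls, n_nodes: int = 1001) -> "GridFunction":
        return cls.uniform(n_nodes, lambda x: x)

    def __call__(self, x):
        """Evaluate by linear interpolation; accepts scalars or arrays."""
        return np.interp(x, self.nodes, self.values)

    def with_values(self, values) -> "GridFunction":
        return GridFunction(self.nodes, values)


@dataclass(frozen=True)
class SolverOptions:
    """Settings for the Picard iteration.

    mode ``"free"`` iterates W_n = Z W_{n-1} verbatim; ``"pinned"`` resets
    the two endpoint values to ``boundary_values`` after every sweep.
    ``init`` selects the starting function: ``"zero"``, ``"identity"`` or a
    custom :class:`GridFunction` (whose grid then overrides ``n_nodes``).
    """

    mode: str = "free"
    boundary_values: tuple[float, float] = (0.0, 1.0)
    tol: float = 1e-10
    max_iter: int = 10_000
    init: str | GridFunction = "zero"
    n_nodes: int = 1001

    def __post_init__(self):
        if self.mode not in ("free", "pinned"):
            raise ParameterError(f"mode must be 'free' or 'pinned', got {self.mode!r}")
        if not self.tol > 0:
            raise ParameterError("tol must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be at least 1")
        if isinstance(self.init, str) and self.init not in ("zero", "identity"):
            raise ParameterError(
                f"init must be 'zero', 'identity' or a GridFunction, got {self.init!r}"
            )
        if self.mode == "pinned" and len(self.boundary_values) != 2:
            raise ParameterError("pinned mode needs both boundary values")

    def initial_function(self) -> GridFunction:
        if isinstance(self.init, GridFunction):
            return self.init
        if self.init == "zero":
            return GridFunction.zero(self.n_nodes)
        return GridFunction.identity(self.n_nodes)


@dataclass
class ConvergenceReport:
    """Per-iteration record of a Picard run.

    ``sup_deltas[i]`` is the max node change of sweep i+1; ``empirical_rate``
    the geometric mean of successive delta ratios (NaN when fewer than two
    informative deltas); ``K1`` the contraction constant of the parameters.
    """

    iterations: int
    sup_deltas: np.ndarray
    K1: float
    tol: float
    converged: bool

    @property
    def empirical_rate(self) -> float:
        d = np.asarray(self.sup_deltas, dtype=float)
        # drop deltas already at floating-noise level so the rate reflects
        # the contraction, not round-off
        floor = max(10 * self.tol, 1e-14)
        d = d[d > floor]
        if d.size < 2:
            return float("nan")
        ratios = d[1:] / d[:-1]
        return float(np.exp(np.mean(np.log(ratios))))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iter": np.arange(1, self.iterations + 1), "sup_delta": self.sup_deltas}
        )


def apply_Z(W: GridFunction, params: ModelParams) -> GridFunction:
    """One application of the averaging operator Z on the grid of ``W``.

    (ZW)(x) = sum_{k=1..8} p_k(x) W(P_k x), with W(P_k x) linearly
    interpolated.  Z maps constants to themselves and preserves nodewise
    bounds (convex-combination property).
    """
    x = W.nodes
    p = event_probabilities(x, params)  # (n, 8)
    th, lm = params.theta, params.lam
    out = np.zeros_like(x)
    for k in range(8):
        out += p[:, k] * np.interp(th[k] * x + (1 - th[k]) * lm[k], x, W.values)
    return W.with_values(out)


def picard_solve(
    params: ModelParams, options: SolverOptions | None = None
) -> tuple[GridFunction, ConvergenceReport]:
    """Iterate W_n = Z W_{n-1} until the sup-node change drops below tol.

    In free mode with K1* < 1 the limit is the unique fixed point of the
    discretised Z (the zero function when starting inside the model's
    homogeneous function class).  In pinned mode the endpoint values are
    clamped to ``options.boundary_values`` after every sweep, producing the
    absorption-style solution with the prescribed W(0), W(1).
    """
    options = options or SolverOptions()
    K1 = contraction_constants(params).K1
    W = options.initial_function()
    if options.mode == "pinned":
        v = W.values.copy()
        v[0], v[-1] = options.boundary_values
        W = W.with_values(v)

    deltas: list[float] = []
    converged = False
    for _ in range(options.max_iter):
        W_next = apply_Z(W, params)
        if options.mode == "pinned":
            v = W_next.values.copy()
            v[0], v[-1] = options.boundary_values
            W_next = W_next.with_values(v)
        delta = float(np.max(np.abs(W_next.values - W.values)))
        deltas.append(delta)
        W = W_next
        if delta <= options.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"Picard iteration did not reach tol={options.tol} within "
            f"{options.max_iter} sweeps (K1*={K1:.4g}; contraction requires K1*<1)",
            RuntimeWarning,
            stacklevel=2,
        )
    report = ConvergenceReport(
        iterations=len(deltas),
        sup_deltas=np.asarray(deltas),
        K1=K1,
        tol=options.tol,
        converged=converged,
    )
    return W, report


def lipschitz_seminorm(W: GridFunction) -> float:
    """Discrete Lipschitz seminorm: max |W(a)-W(b)|/|a-b| over node pairs.

    For a piecewise-linear function this is attained on an adjacent pair,
    so only the n-1 segment slopes are examined.
    """
    if W.nodes.size < 2:
        raise ParameterError("need at least 2 nodes")
    slopes = np.diff(W.values) / np.diff(W.nodes)
    return float(np.max(np.abs(slopes)))


def boundary_probe(
    W: GridFunction, epsilon: float = 1e-3
) -> tuple[float, float, float, float]:
    """One-sided slopes and values of W at the two boundaries.

    Returns ``(slope_at_0, slope_at_1, W(0), W(1))`` with the slopes
    estimated by forward/backward differences of width ``epsilon`` using
    interpolated values — a quick probe of how W approaches the absorbing
    states 0 and 1.
    """
    if not 0.0 < epsilon < 0.5:
        raise ParameterError(f"epsilon must lie in (0, 0.5), got {epsilon!r}")
    w0 = float(W.values[0])
    w1 = float(W.values[-1])
    slope0 = (float(W(epsilon)) - w0) / epsilon
    slope1 = (w1 - float(W(1.0 - epsilon))) / epsilon
    return slope0, slope1, w0, w1
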