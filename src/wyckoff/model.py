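"""Parameter space, event tree and learning operators of the T-maze model.

The model describes a rat in a T-maze with two discriminative lights (L and
L-tilde), one lit at random on each trial with probability 1/2.  The evolving
state is the attention probability ``x``: the chance the animal notices which
light is on.  Each trial ends in one of eight joint events E1..E8 (attended /
ignored light x choice of arm A or B x reward O1 / no reward O2), and each
event k triggers a linear operator

    P_k x = theta_k * x + (1 - theta_k) * lambda_k

moving the state toward the operator's fixed point ``lambda_k`` at rate set by
the learning-rate parameter ``theta_k``.  Reward probabilities are ``u1`` on
L-trials and ``u2`` on L-tilde trials.

This module holds the parameter container and its validation, the eight-event
probability vector, the operators, the four contraction constants K1*..K4*
that govern solvability of the model's asymptotic functional equation, the
special parameter regimes (common lambda; reflex elimination lambda=0;
food-side absorption lambda=1), and a seedable parameter sampler for tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "Event",
    "EVENTS",
    "SpecialCase",
    "SpecialCaseTag",
    "ContractionDiagnostics",
    "ParameterError",
    "event_probabilities",
    "apply_operator",
    "contraction_constants",
    "make_special_case",
    "sample_params",
]

N_EVENTS = 8


class ParameterError(ValueError):
    """A model parameter or state variable is outside its admissible range."""


@dataclass(frozen=True)
class Event:
    """One of the eight joint trial outcomes.

    Attributes
    ----------
    index : int
        1-based event index (E1..E8).
    attention : str
        ``"T"`` if the animal attended to the lit light, ``"T~"`` if it
        ignored the lights.
    light : str
        Which light was lit from the attending animal's viewpoint: ``"L"``,
        ``"L~"``, or ``"off"`` for inattentive events.
    choice : str
        Goal arm chosen, ``"A"`` (left) or ``"B"`` (right).
    outcome : str
        ``"O1"`` reward (food side) or ``"O2"`` no reward.
    """

    index: int
    attention: str
    light: str
    choice: str
    outcome: str

    @property
    def rewarded(self) -> bool:
        return self.outcome == "O1"


#: The eight events in fixed order, exactly as the model's event table binds
#: them: E1..E4 attended (light seen), E5..E8 inattentive.
EVENTS: tuple[Event, ...] = (
    Event(1, "T", "L", "A", "O1"),
    Event(2, "T", "L", "A", "O2"),
    Event(3, "T", "L~", "B", "O1"),
    Event(4, "T", "L~", "B", "O2"),
    Event(5, "T~", "off", "A", "O1"),
    Event(6, "T~", "off", "A", "O2"),
    Event(7, "T~", "off", "B", "O1"),
    Event(8, "T~", "off", "B", "O2"),
)


def _check_unit(name: str, value: float, *, strict: bool = False) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    if strict:
        if not 0.0 < value < 1.0:
            raise ParameterError(
                f"{name} must lie strictly inside (0, 1), got {value!r}"
            )
    elif not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of one model instance.

    Parameters
    ----------
    theta : array-like of 8 floats
        Learning rates theta_1..theta_8, strictly inside (0, 1).  theta_k
        close to 1 means event k barely moves the state; close to 0 means
        the state jumps almost all the way to lambda_k.
    lam : array-like of 8 floats
        Operator fixed points lambda_1..lambda_8 in [0, 1].
    u1, u2 : float
        Reward probabilities on L-trials and L-tilde-trials, in [0, 1].
    """

    theta: np.ndarray
    lam: np.ndarray
    u1: float
    u2: float

    def __init__(self, theta, lam, u1: float, u2: float):
        theta = np.asarray(theta, dtype=float)
        lam = np.asarray(lam, dtype=float)
        if theta.shape != (N_EVENTS,):
            raise ParameterError(
                f"theta must have exactly {N_EVENTS} entries, got shape {theta.shape}"
            )
        if lam.shape != (N_EVENTS,):
            raise ParameterError(
                f"lam must have exactly {N_EVENTS} entries, got shape {lam.shape}"
            )
        for k in range(N_EVENTS):
            _check_unit(f"theta{k + 1}", theta[k], strict=True)
            _check_unit(f"lambda{k + 1}", lam[k])
        object.__setattr__(self, "theta", theta.copy())
        object.__setattr__(self, "lam", lam.copy())
        object.__setattr__(self, "u1", _check_unit("u1", u1))
        object.__setattr__(self, "u2", _check_unit("u2", u2))
        self.theta.flags.writeable = False
        self.lam.flags.writeable = False

    # ------------------------------------------------------------------
    # serialization: flat mapping with keys theta1..theta8, lambda1..lambda8,
    # u1, u2 (the on-disk config format shared with the CLI)
    # ------------------------------------------------------------------
    _KEYS = tuple(
        [f"theta{k}" for k in range(1, 9)] + [f"lambda{k}" for k in range(1, 9)] + ["u1", "u2"]
    )

    def to_dict(self) -> dict[str, float]:
        """Flat mapping with keys theta1..theta8, lambda1..lambda8, u1, u2."""
        out: dict[str, float] = {}
        for k in range(N_EVENTS):
            out[f"theta{k + 1}"] = float(self.theta[k])
        for k in range(N_EVENTS):
            out[f"lambda{k + 1}"] = float(self.lam[k])
        out["u1"] = self.u1
        out["u2"] = self.u2
        return out

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParams":
        unknown = sorted(set(mapping) - set(cls._KEYS))
        if unknown:
            raise ParameterError(f"unknown parameter key(s): {', '.join(unknown)}")
        missing = sorted(set(cls._KEYS) - set(mapping))
        if missing:
            raise ParameterError(f"missing parameter key(s): {', '.join(missing)}")
        theta = [float(mapping[f"theta{k}"]) for k in range(1, 9)]
        lam = [float(mapping[f"lambda{k}"]) for k in range(1, 9)]
        return cls(theta, lam, float(mapping["u1"]), float(mapping["u2"]))

    @classmethod
    def common(cls, theta: float, lam: float, u1: float = 0.5, u2: float = 0.5) -> "ModelParams":
        """Convenience constructor with a single shared theta and lambda."""
        return cls(np.full(N_EVENTS, float(theta)), np.full(N_EVENTS, float(lam)), u1, u2)

    @property
    def common_lambda(self) -> bool:
        """True when all eight lambda_k coincide (the commutative regime)."""
        return bool(np.all(self.lam == self.lam[0]))


class SpecialCaseTag(str, enum.Enum):
    GENERAL = "general"
    COMMON_LAMBDA = "common_lambda"
    ALL_ZERO = "all_zero"
    ALL_ONE = "all_one"


@dataclass(frozen=True)
class SpecialCase:
    """A named parameter regime obtained by constraining the lambda vector.

    ``common_lambda`` sets every lambda_k to a shared value (the commutative
    condition); ``all_zero`` is the reflex-elimination regime where every
    operator contracts the state toward 0; ``all_one`` drives the state
    toward 1 (the animal ends up always choosing the food side); ``general``
    leaves the parameters untouched.
    """

    tag: SpecialCaseTag
    lam_value: float | None = None

    def __post_init__(self):
        tag = SpecialCaseTag(self.tag)
        object.__setattr__(self, "tag", tag)
        if tag is SpecialCaseTag.COMMON_LAMBDA:
            if self.lam_value is None:
                raise ParameterError("common_lambda case requires lam_value")
            _check_unit("lam_value", self.lam_value)


@dataclass(frozen=True)
class ContractionDiagnostics:
    """The four contraction constants controlling solvability.

    K1 bounds the Lipschitz factor of the asymptotic-equation operator Z in
    the Lipschitz seminorm; K1 < 1 guarantees a unique fixed point and
    geometric Picard convergence.  K2 is the common-lambda specialisation
    (only defined when all lambda_k coincide; ``None`` otherwise), K3 the
    lambda=0 specialisation, K4 the constant appearing in the lambda=1
    regime.  K4 = 2 + K3 identically, so K4 > 2 for every valid parameter
    set and the K4 < 1 solvability condition stated for that regime can
    never hold — the diagnostics report it as printed rather than guessing
    a repair.

    ``k2_as_printed`` records whether K2 used the source text's literal
    third term (theta3 + theta3) or the pattern-completing (theta3 + theta7).
    """

    K1: float
    K2: float | None
    K3: float
    K4: float
    k2_as_printed: bool = True

    @property
    def contraction(self) -> bool:
        """Whether the K1 < 1 unique-solvability condition holds."""
        return self.K1 < 1.0

    def to_dict(self) -> dict:
        return {
            "K1": self.K1,
            "K2": self.K2,
            "K3": self.K3,
            "K4": self.K4,
            "variant": "as_printed" if self.k2_as_printed else "typo_corrected",
            "contraction": self.contraction,
        }


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def event_probabilities(x, params: ModelParams) -> np.ndarray:
    """Probabilities of the eight events at attention level ``x``.

    In E1..E8 order:

        (u1*x/2, (1-u1)*x/2, u2*x/2, (1-u2)*x/2,
         (1-x)*u1/2, (1-x)*(1-u1)/2, (1-x)*u2/2, (1-x)*(1-u2)/2)

    The leading 1/2 is the random choice of which light is lit.  The eight
    entries always sum to 1.  ``x`` may be a scalar or an array; an array
    input yields an array of shape ``x.shape + (8,)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)) or not np.all(np.isfinite(x)):
        raise ParameterError(f"x must lie in [0, 1], got {x!r}")
    u1, u2 = params.u1, params.u2
    p = np.empty(x.shape + (N_EVENTS,), dtype=float)
    p[..., 0] = 0.5 * u1 * x
    p[..., 1] = 0.5 * (1 - u1) * x
    p[..., 2] = 0.5 * u2 * x
    p[..., 3] = 0.5 * (1 - u2) * x
    p[..., 4] = 0.5 * (1 - x) * u1
    p[..., 5] = 0.5 * (1 - x) * (1 - u1)
    p[..., 6] = 0.5 * (1 - x) * u2
    p[..., 7] = 0.5 * (1 - x) * (1 - u2)
    return p


def apply_operator(k: int, x, params: ModelParams):
    """Apply learning operator ``P_k x = theta_k x + (1 - theta_k) lambda_k``.

    ``k`` is the 1-based event index.  ``x`` may be scalar or array; the
    result stays in [0, 1] because it is a convex combination of x and
    lambda_k.
    """
    if not 1 <= int(k) <= N_EVENTS:
        raise IndexError(f"event index must be in 1..{N_EVENTS}, got {k}")
    i = int(k) - 1
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ParameterError(f"x must lie in [0, 1], got {x!r}")
    out = params.theta[i] * x + (1.0 - params.theta[i]) * params.lam[i]
    return float(out) if out.ndim == 0 else out


def contraction_constants(
    params: ModelParams, variant: str = "as_printed"
) -> ContractionDiagnostics:
    """Compute the contraction constants K1*..K4*.

    K1 sums, over the four (light, outcome) branches weighted by u1, 1-u1,
    u2, 1-u2, the terms theta_a + theta_b + (1-theta_a)lambda_a/2 +
    (1-theta_b)lambda_b/2 pairing each attended event a in 1..4 with its
    inattentive counterpart b = a+4.  K3 drops the lambda terms; K4 adds 1
    per branch to K3.  K2 uses the shared lambda of the common-lambda regime
    and is reported as ``None`` when the lambdas differ.

    Parameters
    ----------
    variant : {"as_printed", "typo_corrected"}
        ``as_printed`` evaluates K2's third branch with the source text's
        literal (theta3 + theta3); ``typo_corrected`` uses (theta3 + theta7),
        completing the pattern of the other three branches.
    """
    if variant not in ("as_printed", "typo_corrected"):
        raise ValueError(f"unknown variant {variant!r}")
    th, lm = params.theta, params.lam
    u = np.array([params.u1, 1 - params.u1, params.u2, 1 - params.u2])

    # branch b pairs attended event b+1 with inattentive event b+5
    a, bvec = th[:4], th[4:]
    la, lb = lm[:4], lm[4:]
    K1 = float(np.sum(u * (a + bvec + 0.5 * (1 - a) * la + 0.5 * (1 - bvec) * lb)))
    K3 = float(np.sum(u * (a + bvec)))
    K4 = float(np.sum(u * (1 + a + bvec)))

    if params.common_lambda:
        lam = float(lm[0])
        pair3 = th[2] + th[2] if variant == "as_printed" else th[2] + th[6]
        pairs = np.array([th[0] + th[4], th[1] + th[5], pair3, th[3] + th[7]])
        K2 = float(np.sum(u * (lam + (1 - lam / 2.0) * pairs)))
    else:
        K2 = None

    return ContractionDiagnostics(
        K1=K1, K2=K2, K3=K3, K4=K4, k2_as_printed=(variant == "as_printed")
    )


def make_special_case(base: ModelParams, case: SpecialCase) -> ModelParams:
    """Return a copy of ``base`` with the lambda vector set per ``case``."""
    tag = case.tag
    if tag is SpecialCaseTag.GENERAL:
        return base
    if tag is SpecialCaseTag.ALL_ZERO:
        lam = np.zeros(N_EVENTS)
    elif tag is SpecialCaseTag.ALL_ONE:
        lam = np.ones(N_EVENTS)
    else:  # common_lambda; lam_value validated at construction
        lam = np.full(N_EVENTS, float(case.lam_value))
    return ModelParams(base.theta, lam, base.u1, base.u2)


def sample_params(
    rng: np.random.Generator,
    require_contraction: bool = False,
    *,
    theta_range: tuple[float, float] = (0.0, 1.0),
    lam_range: tuple[float, float] = (0.0, 1.0),
    max_tries: int = 200_000,
) -> ModelParams:
    """Sample a valid parameter set uniformly over its box.

    theta is drawn uniformly (exact endpoint hits, a measure-zero event, are
    rejected).  With ``require_contraction`` the draw is rejection-sampled
    until K1* < 1 (as-printed variant); K1* < 1 forces small theta and
    lambda, so under the full unit box only about one draw in 10^4 is
    accepted — candidates are drawn in vectorised batches to keep this
    cheap.  Narrow ``theta_range``/``lam_range`` to speed it up further.
    """
    lo_t = max(theta_range[0], 0.0)
    hi_t = min(theta_range[1], 1.0)
    lo_l = max(lam_range[0], 0.0)
    hi_l = min(lam_range[1], 1.0)
    batch = 1 if not require_contraction else 4096
    tried = 0
    while tried < max_tries:
        n = min(batch, max_tries - tried)
        tried += n
        theta = rng.uniform(lo_t, hi_t, (n, N_EVENTS))
        lam = rng.uniform(lo_l, hi_l, (n, N_EVENTS))
        u = rng.uniform(0, 1, (n, 2))
        ok = np.all((theta > 0.0) & (theta < 1.0), axis=1)
        if require_contraction:
            w = np.stack([u[:, 0], 1 - u[:, 0], u[:, 1], 1 - u[:, 1]], axis=1)
            a, b = theta[:, :4], theta[:, 4:]
            la, lb = lam[:, :4], lam[:, 4:]
            K1 = np.sum(
                w * (a + b + 0.5 * (1 - a) * la + 0.5 * (1 - b) * lb), axis=1
            )
            ok &= K1 < 1.0
        hits = np.flatnonzero(ok)
        if hits.size:
            i = hits[0]
            return ModelParams(theta[i], lam[i], u[i, 0], u[i, 1])
    raise RuntimeError(
        f"no parameter set with K1* < 1 found in {max_tries} draws; "
        "pass a smaller theta_range (and lam_range) — the contraction "
        "condition requires small learning-step sums"
    )
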