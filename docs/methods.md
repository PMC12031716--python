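# Methods

## Model and state

The package implements a linear-operator ("Bush–Mosteller / Wyckoff")
model of two-choice discrimination learning. The scalar state is the
attention probability `x ∈ [0,1]` — the chance the animal notices which
of the two discriminative lights is lit on the current trial. Each trial
produces one of eight joint events (attended/ignored × arm A/B × reward /
no reward); the lit light is chosen fairly, so every event probability
carries a factor ½, and the eight probabilities sum to one identically in
`(x, u₁, u₂)`. Event `k` then applies

    P_k x = ϑ_k x + (1 − ϑ_k) λ_k ,

a convex combination of the current state and the operator's fixed point,
so the state can never leave `[0,1]`. The model makes the usual
linear-operator assumptions: updates depend only on the current state and
event (Markov property), effects are linear, and parameters are constant
across trials.

### Parameters

| parameter | meaning | range | notes |
|---|---|---|---|
| ϑ₁..ϑ₈ | learning rates (per event) | (0,1) strict | ϑ_k → 1: event k barely moves the state |
| λ₁..λ₈ | operator fixed points | [0,1] | shared λ = commutative regime |
| u₁, u₂ | reward probabilities on L / L̃ trials | [0,1] | |
| x₀ | initial attention probability | [0,1] | simulator input |

The ϑ bounds are strict and enforced at construction with an error naming
the offending component; λ, u and x use closed intervals. There is one
modelling tension in the source tradition: the verbal description says an
inattentive animal is rewarded with probability ½, while the event table
assigns u-dependent probabilities to the inattentive events. The package
follows the event table.

## Contraction constants

Solvability of the asymptotic equation is governed by four explicit
constants. Writing the branch weights `w = (u₁, 1−u₁, u₂, 1−u₂)` and
pairing attended event `i ∈ {1..4}` with its inattentive counterpart
`i+4`:

    K₁* = Σᵢ wᵢ (ϑᵢ + ϑᵢ₊₄ + ½(1−ϑᵢ)λᵢ + ½(1−ϑᵢ₊₄)λᵢ₊₄)
    K₃* = Σᵢ wᵢ (ϑᵢ + ϑᵢ₊₄)                                (λ ≡ 0 case)
    K₄* = Σᵢ wᵢ (1 + ϑᵢ + ϑᵢ₊₄) = 2 + K₃*                  (λ ≡ 1 case)
    K₂* = Σᵢ wᵢ (λ + (1 − λ/2) · pairᵢ)                    (common-λ case)

`K₁* < 1` is the contraction condition. Useful identities, all covered by
tests: with a shared ϑ and λ, `K₁* = 2(2ϑ + (1−ϑ)λ)` and `K₃* = 4ϑ`;
`K₃*` equals `K₁*` evaluated at λ ≡ 0; and `K₄* = 2 + K₃* > 2` for every
valid parameter set, so a `K₄* < 1` solvability hypothesis is empty — the
package computes and reports `K₄*` as defined rather than guessing an
intended repair.

Two further reading decisions. The printed `K₂*` formula repeats ϑ₃ in
its third branch where the pattern of the other three constants implies
ϑ₇; both variants are implemented behind a flag (`as_printed` default,
`typo_corrected` optional) and their difference is
`u₂(1 − λ/2)(ϑ₇ − ϑ₃)`. `K₂*`'s unsubscripted λ only makes sense under a
common λ, so the diagnostics report `K₂* = None` for heterogeneous λ
vectors rather than silently picking one. The multi-row absolute-value
bars in the printed constants are read as "sum the rows, then take the
absolute value"; every summand is nonnegative for valid parameters, so
the bars are inert.

## Fixed-point solver

`W` is stored on a uniform grid over `[0,1]` (default 1001 nodes) and
treated as piecewise linear; the operator

    (ZW)(x) = Σ_k p_k(x) W(P_k x)

is evaluated nodewise with `np.interp` for the off-node arguments
`P_k x`. Linear interpolation is chosen deliberately: it preserves the
convex-combination structure, so nodewise bounds and monotonicity in `W`
survive discretisation, which the property tests rely on. The Picard
iteration stops when the sup-norm change over nodes drops to `tol`
(default 1e−10) or at `max_iter` (default 10 000, returned unconverged
with a warning naming `K₁*`).

Two modes:

* **free** — the iteration verbatim. Note that `Z` fixes every *constant*
  function and is a contraction only in the Lipschitz *seminorm*, and the
  discrete `Z` does not preserve the class constraint `W(0) = 0` (at
  `x = 0` the inattentive branch contributes `W` at the points
  `(1−ϑ_k)λ_k ≠ 0`). In practice the free iteration therefore flattens
  toward a constant — zero when started from the zero function (criterion:
  one sweep), generally the chain's expected terminal value of the initial
  function otherwise. The empirical rate of successive sup-deltas is
  bounded by `K₁*` (plus a small grid-interpolation slack that shrinks
  under refinement); it is often much smaller, e.g. exactly ϑ for a shared
  ϑ with λ ≡ 0.
* **pinned** — endpoint values are clamped to user-chosen `(W(0), W(1))`
  (default `(0,1)`) after every sweep. Because the free equation is
  homogeneous its only solution in the contraction regime is trivial;
  pinning produces a nontrivial absorption-style profile without
  inventing an inhomogeneous term. The source material plots a nontrivial,
  non-monotone `W` without stating its initial function, grid or
  parameters; the package exposes both modes and does not attempt to
  reproduce that particular curve.

The Lipschitz seminorm of a grid function is computed from adjacent
segment slopes (`O(n)`), which equals the all-pairs maximum for piecewise
linear functions; a brute-force all-pairs oracle checks this. The
boundary probe reports one-sided finite-difference slopes at 0 and 1.

## Monte Carlo scheme

The simulator draws one uniform variate per trial and selects the event
by inverse CDF over the cumulative event probabilities in fixed E₁..E₈
order, then applies the matching operator — bit-reproducible given the
generator. The estimator `mc_estimate_W` exploits the identity

    W_N(x₀) = E[ W₀(X_N) | X₀ = x₀ ],

i.e. the depth-N Picard iterate equals the expectation of the terminal
function over the event chain, making path sampling an unbiased estimator
of the deterministic iterate (up to terminal interpolation). This is what
makes the deterministic-vs-Monte-Carlo error analysis well-posed: the two
columns estimate the same quantity, and discrepancies are judged against
the CLT band (3 × stderr). No variance reduction is used, by design —
plain means and standard errors keep the estimator's unbiasedness
transparent.

Seeding: each run takes one root seed; independent streams for
trajectories, curves and comparisons are derived with
`numpy.random.SeedSequence.spawn`, so outputs are reproducible
byte-for-byte and chains are independent. Vectorised multi-chain
simulation uses one stream with a fixed draw order (one uniform per chain
per trial), which is equally reproducible.

Degenerate but informative corner: with a shared ϑ and λ all eight
operators coincide, the chain is deterministic, the per-trial mean follows
`λ + ϑⁿ(x₀ − λ)` exactly and all Monte Carlo standard errors are zero.
Tests that need genuine stochasticity use heterogeneous parameter sets.

## Synthetic parameter sampling

`sample_params` draws parameter sets uniformly over the valid box — the
natural neutral choice since the tradition fixes no canonical values.
With `require_contraction` it rejection-samples until `K₁* < 1`; under
the full box only ≈1 draw in 10⁴ qualifies (contraction forces small ϑ
and λ), so candidates are drawn in vectorised batches with a 200 000-draw
budget, and the error message suggests narrowing the ϑ range if the
budget is exhausted. What uniform sampling does *not* emulate: real
experiments produce correlated, slowly-varying learning rates and
near-symmetric reward schedules; passing tests show the mathematics is
implemented correctly across the parameter space, not that any particular
animal's behaviour is captured.

## Problem sizes and numerical choices

Default grid 1001 nodes; oracle comparisons on 5-node grids to 1e−12;
contraction-rate checks over 50 sampled contraction sets (identity init,
tol 1e−10, 2000-sweep cap — the rate needs only the decay history, not
full convergence); Monte Carlo agreement at depth 20 with 10⁵ paths, 21
probe points and 10 seed replicates; absorption regimes over 10³ chains ×
10³ trials; closed-form learning-curve checks at 10⁴ chains. The
empirical-rate estimator drops deltas below `max(10·tol, 1e−14)` so
round-off noise does not contaminate the geometric-mean ratio. Floating
comparisons in tests use absolute tolerance 1e−12 for algebraic
identities and 3 × stderr for stochastic ones.

## Limitations

* No fitting of ϑ, λ, u to behavioural data — the package simulates and
  solves, it does not infer.
* The free-mode fixed point is degenerate by construction (see above);
  nontrivial profiles require the pinned mode and a choice of boundary
  values, which is an explicit modelling input, not an output.
* `K₁* < 1` is sufficient, not necessary: many parameter sets with
  `K₁* ≥ 1` still converge in practice (the sup-delta rate can be far
  below `K₁*`), and the solver reports rather than refuses them.
* Stability of the functional equation under perturbation (Ulam-type
  questions) is out of scope.
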