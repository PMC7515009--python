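# Methods

## Model and mean-field description

The package implements the q-voter model with anticonformity in which the
conformity and anticonformity influence groups have independent sizes
`qc` and `qa`. A randomly chosen voter anticonforms with probability `p`
(flipping against a unanimous group of `qa` distinct neighbors) and
conforms with probability `1 − p` (adopting the opinion of a unanimous
group of `qc` distinct neighbors); non-unanimous groups change nothing.
Time is measured in Monte Carlo steps, one MCS = `N` elementary updates.

On the complete graph in the thermodynamic limit the fraction `c` of
positive opinions evolves by `dc/dt = F(c) = γ₊(c) − γ₋(c)` with

    γ₊(c) = (1−p)(1−c)c^qc + p(1−c)^(qa+1)
    γ₋(c) = (1−p)c(1−c)^qc + p c^(qa+1).

`F` is antisymmetric about `c = 1/2`, which is therefore always a fixed
point; it is stable for `p > p₁*` with the lower spinodal

    p₁*(qa, qc) = 2^qa(qc−1) / [2^qa(qc−1) + 2^qc(qa+1)],

obtained equivalently from linear stability of `c = 1/2` or as the
`c_st → 1/2` limit of the inverse stationary relation

    p(c_st) = [c(1−c)^qc − (1−c)c^qc] / [c(1−c)^qc − (1−c)c^qc + (1−c)^(qa+1) − c^(qa+1)].

Both routes are computed and their agreement is asserted in the tests
(`≤ 1e−10` over `qa, qc ∈ [1,20]²`). `p₁*` and related integer-parameter
quantities are evaluated in exact rational arithmetic (`fractions`), so
statements like `p₁*(2,4) = 1/5` and `p₁*(qa,2) = p₁*(qa,3)` are exact,
not approximate.

## Transition order, spinodals, transition point

The transition is continuous for `qc < qc*` and discontinuous for
`qc > qc*`, with the tricritical size

    qc*(qa) = (5 + √(25 − 4qa + 4qa²)) / 2,

returned integer-exactly when the discriminant is a perfect square
(e.g. `qc*(3) = 6`). Classification tolerance: `|qc − qc*| < 1e−12` is
reported as `tricritical`; the degenerate `qc = 1` gives `p₁* = 0`
(no ordered phase at any `p > 0`) rather than an error.

For discontinuous transitions the upper spinodal `p₂*` is the maximum of
`p(c_st)` on `(1/2, 1)`. No closed form exists in general, so the maximum
is bracketed on a 2001-point grid and refined by bounded Brent
minimization to a maximizer tolerance of `1e−8` (achieved `~1e−10`); a
brute-force 10⁶-point grid serves as the oracle in tests.

The drift integrates to an effective potential `V(c) = −∫F dc`, kept with
the additive constant of its closed form so values are comparable across
`c`. In the order parameter `m = 2c − 1` the potential is even; its Landau
expansion `V = Am² + Bm⁴ + Cm⁶` has closed-form coefficients. `A = 0` at
`p₁*` (checked rationally) and `B = 0` at `p₁*` exactly when `qc = qc*`,
giving a second, independent route to the transition-order classification.

The discontinuous transition point `p*` is the `p ∈ (p₁*, p₂*)` at which
the disordered minimum `V(1/2)` and the ordered minima are equally deep.
The depth gap is bisected in `p` (Brent, `xtol = 1e−12`) on the bracket
`[p₁* + 1e−9, p₂* − 1e−9]`, inside which it changes sign by the
metastability structure.

**Locating the ordered minimum.** A scan-and-polish minimization of `V(m)`
fails within `~1e−7` of the upper spinodal, where the merging
minimum–maximum pair is narrower than any fixed scan resolution. Since
`V' = −F`, the ordered minimum is instead found as the largest root of
`F(c) = 0`, bracketed on `[c₊, 1)` where `c₊` is the upper-spinodal
maximizer: `F(c₊) > 0` strictly for every `p < p₂*`, so the bracket is
valid arbitrarily close to both spinodals. This is an exact reformulation,
not an approximation.

**Truncated-series diagnostics.** The sextic-series conditions
`A = B²/3C` (upper spinodal) and `A = B²/4C` (transition) are provided as
diagnostics only. `C` turns negative a few integer sizes above `qc*`
(`qc ≥ 9` at `qa = 2`), where the conditions are meaningless; the package
detects and reports this. Where `C > 0` the series is quantitatively
reliable only at the first integer above `qc*` (relative error `~0.1%`,
growing to `~3%` and `~20%` at the next two sizes at `qa = 2`), so the
full-potential route is always authoritative.

## Monte Carlo simulator

Two equivalent paths implement the microscopic rule:

- `elementary_update` mutates an explicit spin configuration, drawing the
  influence group without repetitions by rejection sampling; it supports
  arbitrary adjacency lists, applying the no-change rule when the group
  size exceeds the voter's degree. No quantitative claims are made off the
  complete graph.
- `run` uses a numba-compiled complete-graph kernel that tracks only the
  up-count, valid by exchangeability: the target is up with probability
  `n₊/N`, and group unanimity is decided by sequential hypergeometric
  draws from the remaining `N − 1` agents, short-circuiting on the first
  disagreement (identical in distribution to a full draw). Each update is
  O(q), never O(N).

Both paths are checked against the analytical rates: empirical per-update
flip frequencies at fixed composition agree with `γ±` within binomial
error (the explicit path at 2×10⁵ trials, the kernel by chi-squared
consistency at 10⁶ updates per parameter point), and ensemble mean
trajectories track the deterministic map within three standard errors at
`N = 10⁴` as in the reference setting. Finite-`N` bias of the frequencies
is O(q/N), well below the statistical bands at `N = 10⁴`.

Reproducibility: a run is bitwise reproducible given its seed; ensembles
spawn per-run seeds deterministically from a base seed via
`numpy.random.SeedSequence`. Burn-in and averaging windows are
caller-specified, since the measurement protocol is not part of the model.

## Deterministic map

Trajectories of the rate equation use the explicit map
`c ← c + F(c)/N` (default `N = 10⁴`, i.e. Δt = 10⁻⁴), iterated `N` times
per recorded MCS — deliberately the same discretization as the stochastic
dynamics rather than an adaptive ODE solver, so deterministic and
stochastic trajectories share a time axis. Iterates are clamped to
`[0, 1]`; clamping beyond `1e−9` raises, as it would indicate a defect
rather than floating-point drift. Integer powers use native integer
exponents, keeping `F(1/2) = 0` and the boundary values exact.

## What the tests do and do not show

All quantitative checks are against the complete-graph mean-field theory
and its exact finite-`N` microdynamics. Passing tests therefore validate
the implementation of the model, not the model's applicability to real
social networks: spatial correlation effects (finite degree, clustering),
which are expected to differentiate anticonformity from independence, are
outside scope, as are Langevin/Fokker–Planck finite-size corrections.

## Problem sizes

Default stochastic checks use `N = 10³–10⁴` agents, 10–20 runs and a few
hundred MCS — the same order as the reference setting (`N = 10⁴`,
100 samples) with smaller ensembles, with acceptance bands scaled to the
ensemble standard error actually measured. Analytical quantities use the
tolerances above (`1e−10` on probabilities, `1e−8` on concentrations,
`1e−12` on the equal-depth bisection).
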