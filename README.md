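# qvoter

Monte Carlo simulator and mean-field phase-transition toolkit for the
**generalized q-voter model with anticonformity** — a binary-state
opinion-dynamics model in which social influence acts through unanimous
groups, and the group sizes for conformity and anticonformity are
independent parameters.

## The model

`N` agents each hold an opinion `S_i = ±1`. In an elementary update a
random voter acts, with probability `p`, as an *anticonformist*: a group of
`q_a` distinct neighbors is drawn and, if unanimous, the voter adopts the
*opposite* opinion. With probability `1 − p` it acts as a *conformist*: a
group of `q_c` distinct neighbors is drawn and, if unanimous, the voter
adopts the group's opinion. One Monte Carlo step (MCS) is `N` elementary
updates.

On the complete graph (N → ∞) the concentration `c` of `+1` opinions obeys

```
dc/dt = F(c) = γ₊(c) − γ₋(c)
γ₊(c) = (1−p)(1−c)c^qc + p(1−c)^(qa+1)
γ₋(c) = (1−p)c(1−c)^qc + p c^(qa+1)
```

The toolkit locates, analytically where possible and numerically otherwise:

- the **lower spinodal** `p₁* = 2^qa(qc−1) / [2^qa(qc−1) + 2^qc(qa+1)]`,
  where the symmetric state `c = 1/2` changes stability (pitchfork
  bifurcation; the critical point when the transition is continuous);
- the **tricritical group size** `qc* = (5 + √(25 − 4qa + 4qa²))/2`, above
  which the transition becomes discontinuous;
- the **upper spinodal** `p₂*`, the maximum of the inverse stationary
  relation `p(c_st)` over `c_st ∈ (1/2, 1)`;
- the **discontinuous transition point** `p*`, where the three minima of the
  effective potential `V(c) = −∫F(c)dc` are equally deep;
- the Landau coefficients `A, B, C` of `V(m) = Am² + Bm⁴ + Cm⁶` in the order
  parameter `m = 2c − 1`, with `A = 0 ⇔ p = p₁*` and `B = 0` at the
  tricritical point;
- stochastic trajectories of the agent-based dynamics, reproducible by seed,
  with ensemble means and standard deviations.

## Worked example

```python
>>> import qvoter as qv
>>> qv.lower_spinodal(2, 4)                 # critical point, qa=2, qc=4
0.2
>>> qv.tricritical_qc(2)                    # transition order switches here
5.372281323269014
>>> s = qv.classify_transition(2, 8)        # qc=8 > qc*: discontinuous
>>> s.p1_star, s.p_star, s.p2_star
(0.035175879396984924, 0.05642128905768142, 0.06327094915258619)
```

For `qa=2, qc=4` the transition is continuous at `p* = p₁* = 0.2`: below it
one opinion dominates, above it the population splits evenly. For
`qa=2, qc=8` the transition is discontinuous: ordered and disordered states
coexist for `p ∈ (0.0352, 0.0633)` (social hysteresis of width
`p₂* − p₁* ≈ 0.028`), and the equal-depth transition point is
`p* ≈ 0.0564`. A stochastic run confirms the metastability — the final
state depends on the initial one:

```python
>>> params = qv.ModelParams(qa=2, qc=8, p=0.05)
>>> qv.run(params, N=10_000, c0=0.75, n_mcs=300, seed=21).trajectory.final
0.9228
>>> qv.run(params, N=10_000, c0=0.50, n_mcs=300, seed=22).trajectory.final
0.5011
```

The command-line interface exposes the same functionality
(`qvoter trajectory|simulate|stationary|potential|phase-diagram`, see
`qvoter --help`); all results are written as CSV, and a YAML config file
can supply any flag.

```sh
qvoter phase-diagram --qa 2 --qc-min 2 --qc-max 10 --out pd.csv
```

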