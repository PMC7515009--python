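"""Agent-based Monte Carlo realization of the microscopic update rules.

Each elementary update picks one voter uniformly at random. With
probability p the voter acts as an anticonformist: a group of qa distinct
agents is drawn from its neighbors, and if the group is unanimous the voter
adopts the opposite opinion. With probability 1-p it acts as a conformist:
a group of qc distinct neighbors is drawn, and if unanimous the voter
adopts the group's opinion. A non-unanimous group — or a group size
exceeding the voter's degree — changes nothing. One Monte Carlo step (MCS)
is N elementary updates.

Two equivalent paths are provided: `elementary_update` mutates an explicit
spin configuration (and supports arbitrary adjacency), while `run` uses an
O(q)-per-update complete-graph kernel that tracks only the up-count, valid
by exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import ModelParams, Trajectory

__all__ = [
    "SpinConfiguration",
    "SimResult",
    "init_config",
    "elementary_update",
    "run",
    "ensemble",
    "update_frequencies",
]


@dataclass
class SpinConfiguration:
    """Binary opinions S_i in {+1, -1} of N agents.

    ``neighbors`` is None on the complete graph (every agent is adjacent to
    every other); otherwise a list of per-agent neighbor index arrays.
    """

    states: np.ndarray
    neighbors: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.int8)
        if s.ndim != 1 or not np.all(np.isin(s, (-1, 1))):
            raise ValueError("states must be a 1-D array of +1/-1 values")
        self.states = s
        if self.neighbors is not None and len(self.neighbors) != len(s):
            raise ValueError("neighbors list must have one entry per agent")

    @property
    def N(self) -> int:
        return len(self.states)

    @property
    def concentration(self) -> float:
        """Fraction of agents holding the +1 opinion."""
        return float(np.count_nonzero(self.states == 1)) / self.N


@dataclass(frozen=True)
class SimResult:
    """A single stochastic trajectory with its full provenance."""

    trajectory: Trajectory
    params: ModelParams
    N: int
    seed: int


def init_config(
    N: int,
    c0: float,
    seed: int | np.random.Generator,
    qmax: int | None = None,
) -> SpinConfiguration:
    """Random configuration with exactly round(c0*N) up-spins.

    ``qmax``, when given, is the largest influence-group size the dynamics
    will use; N must exceed it so a group can be formed.
    """
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if qmax is not None and N < qmax + 1:
        raise ValueError(
            f"N={N} too small to draw an influence group of size {qmax} "
            "from the remaining agents"
        )
    if not 0.0 <= c0 <= 1.0:
        raise ValueError(f"c0 must lie in [0, 1], got {c0!r}")
    rng = np.random.default_rng(seed)
    n_up = int(round(c0 * N))
    states = np.full(N, -1, dtype=np.int8)
    states[rng.choice(N, size=n_up, replace=False)] = 1
    return SpinConfiguration(states=states)


def _draw_group(rng: np.random.Generator, pool_size: int, exclude: int, q: int,
                pool: np.ndarray | None) -> np.ndarray:
    """q distinct indices from the pool, never the target, by rejection."""
    chosen = np.empty(q, dtype=np.int64)
    k = 0
    while k < q:
        j = int(rng.integers(pool_size))
        cand = int(pool[j]) if pool is not None else j
        if cand == exclude:
            continue
        if cand in chosen[:k]:
            continue
        chosen[k] = cand
        k += 1
    return chosen


def elementary_update(
    config: SpinConfiguration,
    params: ModelParams,
    rng: np.random.Generator,
) -> int:
    """One microscopic update, in place; returns the up-count change (-1/0/+1).

    On the complete graph the group is drawn from all other agents; with
    explicit adjacency it is drawn from the target's neighbors, and a group
    size exceeding the degree leaves the state unchanged.
    """
    states = config.states
    N = config.N
    target = int(rng.integers(N))
    anticonf = rng.random() < params.p
    q = params.qa if anticonf else params.qc
    if config.neighbors is None:
        if q > N - 1:
            return 0
        group = _draw_group(rng, N, target, q, None)
    else:
        pool = config.neighbors[target]
        if q > len(pool):
            return 0
        group = _draw_group(rng, len(pool), target, q, pool)
    group_states = states[group]
    s = int(group_states[0])
    if not np.all(group_states == s):
        return 0
    new_state = -s if anticonf else s
    old = int(states[target])
    states[target] = new_state
    return (new_state - old) // 2


def run(
    params: ModelParams,
    N: int,
    c0: float,
    n_mcs: int,
    seed: int,
    record_every: int = 1,
) -> SimResult:
    """Simulate the complete-graph dynamics for n_mcs Monte Carlo steps.

    Records the concentration at t=0 and every ``record_every`` MCS;
    bitwise reproducible for a fixed seed.
    """
    qmax = max(params.qa, params.qc)
    if N < qmax + 1:
        raise ValueError(f"N={N} too small for influence groups of size {qmax}")
    if n_mcs < 1:
        raise ValueError(f"n_mcs must be >= 1, got {n_mcs}")
    if not 0.0 <= c0 <= 1.0:
        raise ValueError(f"c0 must lie in [0, 1], got {c0!r}")
    n_up0 = int(round(c0 * N))
    conc = _kernels.run_complete_graph(
        int(N), params.qa, params.qc, params.p, n_up0,
        int(n_mcs), int(record_every), int(seed) % (2**32),
    )
    times = np.concatenate(
        [[0.0], np.arange(record_every, n_mcs + 1, record_every, dtype=float)]
    )
    return SimResult(
        trajectory=Trajectory(times=times, concentrations=conc),
        params=params, N=int(N), seed=int(seed),
    )


def ensemble(
    params: ModelParams,
    N: int,
    c0: float,
    n_mcs: int,
    n_runs: int,
    base_seed: int,
    record_every: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent runs with seeds spawned deterministically from base_seed.

    Returns (times, mean concentration, pointwise standard deviation across
    runs).
    """
    if n_runs < 2:
        raise ValueError(f"n_runs must be >= 2, got {n_runs}")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_runs)
    trajs = []
    times = None
    for s in seeds:
        res = run(params, N, c0, n_mcs, seed=int(s), record_every=record_every)
        trajs.append(res.trajectory.concentrations)
        times = res.trajectory.times
    stacked = np.vstack(trajs)
    return times, stacked.mean(axis=0), stacked.std(axis=0, ddof=0)


def update_frequencies(
    params: ModelParams, N: int, c: float, n_trials: int, seed: int
) -> tuple[float, float, float]:
    """Empirical (up, down, hold) frequencies of independent single updates.

    Samples n_trials elementary updates at fixed composition round(c*N)
    up-spins; converges to the infinite-graph rates (gamma+, gamma-,
    gamma0) as N grows.
    """
    n_up = int(round(c * N))
    npl, nmi, nze = _kernels.sample_update_counts(
        int(N), n_up, params.qa, params.qc, params.p,
        int(n_trials), int(seed) % (2**32),
    )
    return npl / n_trials, nmi / n_trials, nze / n_trials
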