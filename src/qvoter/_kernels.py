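"""Numba-compiled inner loops for the deterministic map and the Monte Carlo run.

The complete-graph Monte Carlo kernel exploits exchangeability: on the
complete graph the dynamics depend on the configuration only through the
number of up-spins, so each elementary update is O(q) regardless of N.
Group unanimity is decided by sequential hypergeometric draws (sampling the
q group members one by one without replacement from the N-1 non-target
agents), short-circuiting as soon as the group is mixed — identical in
distribution to drawing the full group.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "iterate_map",
    "run_complete_graph",
    "sample_update_counts",
]


@njit(cache=False)
def iterate_map(c0, qa, qc, p, n_mcs, n_scale):
    """Iterate c <- c + [gamma+(c) - gamma-(c)] / n_scale, recording once per MCS.

    Returns (concentrations, max_boundary_violation); the caller decides
    whether a violation is within floating-point rounding.
    """
    out = np.empty(n_mcs + 1)
    c = c0
    out[0] = c
    worst = 0.0
    for step in range(n_mcs):
        for _ in range(n_scale):
            gp = (1.0 - p) * (1.0 - c) * c**qc + p * (1.0 - c) ** (qa + 1)
            gm = (1.0 - p) * c * (1.0 - c) ** qc + p * c ** (qa + 1)
            c = c + (gp - gm) / n_scale
            if c < 0.0:
                if -c > worst:
                    worst = -c
                c = 0.0
            elif c > 1.0:
                if c - 1.0 > worst:
                    worst = c - 1.0
                c = 1.0
        out[step + 1] = c
    return out, worst


@njit(cache=False)
def _group_unanimity(rem_up, rem, q):
    """Draw q agents without replacement from rem agents (rem_up of them up).

    Returns +1 if the group is unanimously up, -1 unanimously down,
    0 if mixed.
    """
    ups = 0
    downs = 0
    for j in range(q):
        p_up = (rem_up - ups) / (rem - j)
        if np.random.random() < p_up:
            ups += 1
            if downs > 0:
                return 0
        else:
            downs += 1
            if ups > 0:
                return 0
    if ups == q:
        return 1
    return -1


@njit(cache=False)
def run_complete_graph(n_agents, qa, qc, p, n_up0, n_mcs, record_every, seed):
    """Monte Carlo dynamics on the complete graph, one concentration per record.

    Records c at t=0 and then every ``record_every`` MCS; one MCS is
    n_agents elementary updates.
    """
    np.random.seed(seed)
    n_up = n_up0
    n_rec = n_mcs // record_every + 1
    out = np.empty(n_rec)
    out[0] = n_up / n_agents
    k = 1
    for step in range(n_mcs):
        for _ in range(n_agents):
            target_up = np.random.random() * n_agents < n_up
            anticonf = np.random.random() < p
            q = qa if anticonf else qc
            rem_up = n_up - 1 if target_up else n_up
            verdict = _group_unanimity(rem_up, n_agents - 1, q)
            if verdict == 1:  # unanimous up
                if anticonf:
                    if target_up:
                        n_up -= 1
                else:
                    if not target_up:
                        n_up += 1
            elif verdict == -1:  # unanimous down
                if anticonf:
                    if not target_up:
                        n_up += 1
                else:
                    if target_up:
                        n_up -= 1
        if (step + 1) % record_every == 0:
            out[k] = n_up / n_agents
            k += 1
    return out


@njit(cache=False)
def sample_update_counts(n_agents, n_up, qa, qc, p, n_trials, seed):
    """Sample n_trials independent elementary updates at fixed composition.

    Returns counts (n_plus, n_minus, n_zero) of updates that would raise,
    lower, or keep the up-count. Used for consistency checks against the
    infinite-graph rates.
    """
    np.random.seed(seed)
    n_plus = 0
    n_minus = 0
    for _ in range(n_trials):
        target_up = np.random.random() * n_agents < n_up
        anticonf = np.random.random() < p
        q = qa if anticonf else qc
        rem_up = n_up - 1 if target_up else n_up
        verdict = _group_unanimity(rem_up, n_agents - 1, q)
        if verdict == 1:
            if anticonf and target_up:
                n_minus += 1
            elif not anticonf and not target_up:
                n_plus += 1
        elif verdict == -1:
            if anticonf and not target_up:
                n_plus += 1
            elif not anticonf and target_up:
                n_minus += 1
    return n_plus, n_minus, n_trials - n_plus - n_minus
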