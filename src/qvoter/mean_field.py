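"""Mean-field rates, drift, and deterministic time evolution.

On the infinite complete graph the per-update probabilities of raising or
lowering the concentration c of +1 opinions are

    gamma+(c) = (1-p)(1-c) c^qc + p (1-c)^(qa+1)
    gamma-(c) = (1-p) c (1-c)^qc + p c^(qa+1)

and the expected concentration follows the rate equation
dc/dt = F(c) = gamma+(c) - gamma-(c). The deterministic map
c(t + 1/N) = c(t) + F(c)/N discretizes this with one Monte Carlo step
(MCS) equal to N elementary updates.
"""

from __future__ import annotations

import numpy as np

from ._kernels import iterate_map
from .params import ModelParams, RateTriple, Trajectory

__all__ = ["transition_rates", "drift", "integrate_trajectory"]

# drift beyond this after clamping indicates a bug, not float rounding
_BOUNDARY_TOL = 1e-9


def _check_concentration(c: float, name: str = "c") -> float:
    c = float(c)
    if not np.isfinite(c) or not 0.0 <= c <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {c!r}")
    return c


def transition_rates(c: float, params: ModelParams) -> RateTriple:
    """Elementary-update probabilities (gamma+, gamma-, gamma0) at concentration c.

    Integer powers keep the evaluation exact at c in {0, 1/2, 1}.
    """
    c = _check_concentration(c)
    p, qa, qc = params.p, params.qa, params.qc
    gp = (1.0 - p) * (1.0 - c) * c**qc + p * (1.0 - c) ** (qa + 1)
    gm = (1.0 - p) * c * (1.0 - c) ** qc + p * c ** (qa + 1)
    return RateTriple(gamma_plus=gp, gamma_minus=gm, gamma_zero=1.0 - gp - gm)


def drift(c: float, params: ModelParams) -> float:
    """Effective force F(c) = gamma+(c) - gamma-(c); antisymmetric about c=1/2."""
    c = _check_concentration(c)
    p, qa, qc = params.p, params.qa, params.qc
    return (1.0 - p) * ((1.0 - c) * c**qc - c * (1.0 - c) ** qc) + p * (
        (1.0 - c) ** (qa + 1) - c ** (qa + 1)
    )


def integrate_trajectory(
    c0: float,
    params: ModelParams,
    n_mcs: int,
    N: int = 10_000,
) -> Trajectory:
    """Evolve the deterministic map from c0 for n_mcs Monte Carlo steps.

    Parameters
    ----------
    c0 : float
        Initial concentration in [0, 1].
    params : ModelParams
        Model parameters.
    n_mcs : int
        Number of Monte Carlo steps; the map is iterated N*n_mcs times and
        one point per MCS is recorded (plus the initial point).
    N : int
        Step scale of the map (Delta t = 1/N); plays the role of the system
        size in the stochastic dynamics.

    Returns
    -------
    Trajectory
        times 0..n_mcs (in MCS) and the corresponding concentrations.
    """
    c0 = _check_concentration(c0, "c0")
    if n_mcs < 1:
        raise ValueError(f"n_mcs must be >= 1, got {n_mcs}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    concentrations, worst = iterate_map(
        c0, params.qa, params.qc, params.p, int(n_mcs), int(N)
    )
    if worst > _BOUNDARY_TOL:
        raise RuntimeError(
            f"deterministic map left [0, 1] by {worst:.3e}; "
            "this exceeds floating-point drift and indicates a bug"
        )
    return Trajectory(
        times=np.arange(n_mcs + 1, dtype=float), concentrations=concentrations
    )
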