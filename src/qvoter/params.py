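"""Core parameter and result containers for the q-voter model with anticonformity.

The model has three parameters: the anticonformity influence-group size
``qa``, the conformity influence-group size ``qc`` (both positive integers)
and the probability ``p`` with which a randomly chosen voter acts as an
anticonformist rather than a conformist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelParams", "RateTriple", "Trajectory"]


def _check_group_size(value: int, name: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be a positive integer, got {value!r}")
    if value < 1:
        raise ValueError(f"{name} must be >= 1, got {value}")
    return int(value)


@dataclass(frozen=True)
class ModelParams:
    """Complete parameterization of the dynamics.

    Parameters
    ----------
    qa : int
        Size of the influence group for anticonformity (>= 1).
    qc : int
        Size of the influence group for conformity (>= 1).
    p : float
        Probability of an anticonformity update, in [0, 1].
    """

    qa: int
    qc: int
    p: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "qa", _check_group_size(self.qa, "qa"))
        object.__setattr__(self, "qc", _check_group_size(self.qc, "qc"))
        p = float(self.p)
        if not np.isfinite(p) or not 0.0 <= p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p!r}")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class RateTriple:
    """Elementary-update probabilities at a given concentration.

    ``gamma_plus`` raises the concentration of +1 opinions by 1/N,
    ``gamma_minus`` lowers it, ``gamma_zero`` leaves it unchanged;
    they sum to one.
    """

    gamma_plus: float
    gamma_minus: float
    gamma_zero: float

    def __post_init__(self) -> None:
        for name in ("gamma_plus", "gamma_minus", "gamma_zero"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        total = self.gamma_plus + self.gamma_minus + self.gamma_zero
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"rates must sum to 1, got {total!r}")


@dataclass(frozen=True)
class Trajectory:
    """Time series of the concentration c(t).

    Times are measured in Monte Carlo steps (1 MCS = N elementary updates,
    so a single update advances time by 1/N).
    """

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError("concentrations must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final(self) -> float:
        """Last recorded concentration."""
        return float(self.concentrations[-1])
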