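"""Stationary states, linear stability, spinodals, and the tricritical condition.

The symmetric state c = 1/2 is always stationary; it loses stability at the
lower spinodal

    p1*(qa, qc) = 2^qa (qc-1) / [2^qa (qc-1) + 2^qc (qa+1)],

a pitchfork bifurcation point. Nontrivial stationary concentrations cst are
described through the inverse relation p = p(cst); for a discontinuous
transition p(cst) has two symmetric maxima at c+ > 1/2 and c- = 1 - c+,
whose common value is the upper spinodal p2*. The transition switches from
continuous to discontinuous at the tricritical group size

    qc*(qa) = (5 + sqrt(25 - 4 qa + 4 qa^2)) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import minimize_scalar

from .params import ModelParams

__all__ = [
    "StationaryBranch",
    "TransitionSummary",
    "lower_spinodal",
    "stability_derivative",
    "stationary_p_of_c",
    "upper_spinodal",
    "tricritical_qc",
    "classify_transition",
    "stationary_diagram",
]

_CST_TOL = 1e-8  # location tolerance for the upper-spinodal maximizer
_TRICRITICAL_TOL = 1e-12


def _check_sizes(qa: int, qc: int) -> tuple[int, int]:
    for name, v in (("qa", qa), ("qc", qc)):
        if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
            raise TypeError(f"{name} must be a positive integer, got {v!r}")
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    return int(qa), int(qc)


def lower_spinodal(qa: int, qc: int, exact: bool = False):
    """Lower spinodal p1* — where c=1/2 changes stability.

    Computed in exact rational arithmetic; returns a float by default or the
    exact ``Fraction`` when ``exact=True``. Equals 0 iff qc == 1 (no ordered
    phase for any p > 0).
    """
    qa, qc = _check_sizes(qa, qc)
    value = Fraction(2**qa * (qc - 1), 2**qa * (qc - 1) + 2**qc * (qa + 1))
    return value if exact else float(value)


def stability_derivative(c: float, params: ModelParams) -> float:
    """dF/dc at concentration c; negative means the fixed point is stable.

    At c = 1/2 this reduces to 2[(1-p)(qc-1)/2^qc - p(qa+1)/2^qa], whose
    zero defines the lower spinodal.
    """
    c = float(c)
    if not 0.0 < c < 1.0:
        raise ValueError(f"c must lie strictly inside (0, 1), got {c!r}")
    p, qa, qc = params.p, params.qa, params.qc
    d_plus = (1.0 - p) * (-(c**qc) + qc * (1.0 - c) * c ** (qc - 1)) - p * (
        qa + 1
    ) * (1.0 - c) ** qa
    d_minus = (1.0 - p) * ((1.0 - c) ** qc - qc * c * (1.0 - c) ** (qc - 1)) + p * (
        qa + 1
    ) * c**qa
    return d_plus - d_minus


def stationary_p_of_c(cst, qa: int, qc: int, at_half: str = "limit"):
    """Anticonformity probability p at which cst is a stationary concentration.

    Inverts the stationarity condition F(cst; p) = 0. The relation is
    symmetric under cst -> 1 - cst. cst = 1/2 is a removable singularity;
    by default the closed-form limit (the lower spinodal) is inserted there,
    or a ValueError is raised when ``at_half="raise"``.

    Accepts scalars or numpy arrays.
    """
    qa, qc = _check_sizes(qa, qc)
    if at_half not in ("limit", "raise"):
        raise ValueError(f"at_half must be 'limit' or 'raise', got {at_half!r}")
    c = np.asarray(cst, dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    if np.any((c <= 0.0) | (c >= 1.0)):
        raise ValueError("cst must lie strictly inside (0, 1)")
    half = c == 0.5
    if half.any() and at_half == "raise":
        raise ValueError("cst = 1/2 is a removable singularity of p(cst)")
    num = c * (1.0 - c) ** qc - (1.0 - c) * c**qc
    den = num + (1.0 - c) ** (qa + 1) - c ** (qa + 1)
    out = np.empty_like(c)
    np.divide(num, den, out=out, where=~half)
    out[half] = lower_spinodal(qa, qc)
    return float(out[0]) if scalar else out


def tricritical_qc(qa: int) -> float:
    """Tricritical conformity group size qc*(qa) = (5 + sqrt(25-4qa+4qa^2))/2.

    The transition is continuous for qc < qc* and discontinuous for qc > qc*.
    The result is integer-exact when the discriminant is a perfect square
    (e.g. qa=3 -> 6.0).
    """
    qa, _ = _check_sizes(qa, 1)
    disc = 25 - 4 * qa + 4 * qa * qa
    root = math.isqrt(disc)
    if root * root == disc and (5 + root) % 2 == 0:
        return float((5 + root) // 2)
    return (5.0 + math.sqrt(disc)) / 2.0


@dataclass(frozen=True)
class UpperSpinodal:
    """Upper spinodal p2* and its maximizer c+ (> 1/2); continuous cases
    collapse to (p1*, 1/2)."""

    p2_star: float
    c_plus: float
    continuous: bool

    def __iter__(self):
        return iter((self.p2_star, self.c_plus))


def upper_spinodal(qa: int, qc: int, grid_size: int = 2001) -> UpperSpinodal:
    """Maximize p(cst) over cst in (1/2, 1) to locate the upper spinodal.

    For a continuous transition (qc <= qc*(qa)) the maximum sits at
    cst = 1/2 and equals the lower spinodal; returns that with the
    continuity flag set. Otherwise the maximum is bracketed on a dense grid
    (>= 2001 points) and refined by bounded golden-section/Brent search to
    a maximizer tolerance of 1e-8.
    """
    qa, qc = _check_sizes(qa, qc)
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    p1 = lower_spinodal(qa, qc)
    if qc <= tricritical_qc(qa):
        return UpperSpinodal(p2_star=p1, c_plus=0.5, continuous=True)
    grid = np.linspace(0.5 + 1e-9, 1.0 - 1e-9, grid_size)
    values = stationary_p_of_c(grid, qa, qc)
    i = int(np.argmax(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    res = minimize_scalar(
        lambda c: -stationary_p_of_c(c, qa, qc),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": _CST_TOL * 1e-2},
    )
    p2 = float(-res.fun)
    if not p2 > p1:
        raise RuntimeError(
            f"discontinuous classification for (qa={qa}, qc={qc}) but no "
            "maximum of p(cst) above the lower spinodal was found"
        )
    return UpperSpinodal(p2_star=p2, c_plus=float(res.x), continuous=False)


@dataclass(frozen=True)
class TransitionSummary:
    """Full characterization of the phase transition at given (qa, qc)."""

    qa: int
    qc: int
    p1_star: float
    p2_star: float
    p_star: float
    qc_star: float
    transition_type: str  # "continuous" | "discontinuous" | "tricritical"
    c_plus: float | None = None
    c_minus: float | None = None

    @property
    def width(self) -> float:
        """Hysteresis width p2* - p1* (0 unless discontinuous)."""
        return self.p2_star - self.p1_star


def classify_transition(qa: int, qc: int) -> TransitionSummary:
    """Classify the transition and assemble spinodals and transition point.

    Continuous (qc < qc*): p* = p1* = p2*. Tricritical (|qc - qc*| below
    1e-12, only possible when qc* is an integer): same collapse, labelled
    separately. Discontinuous (qc > qc*): p* is obtained from the
    equal-depth condition on the effective potential.
    """
    qa, qc = _check_sizes(qa, qc)
    p1 = lower_spinodal(qa, qc)
    qc_star = tricritical_qc(qa)
    if abs(qc - qc_star) < _TRICRITICAL_TOL:
        kind = "tricritical"
    elif qc < qc_star:
        kind = "continuous"
    else:
        kind = "discontinuous"
    if kind != "discontinuous":
        return TransitionSummary(
            qa=qa, qc=qc, p1_star=p1, p2_star=p1, p_star=p1,
            qc_star=qc_star, transition_type=kind,
        )
    spin = upper_spinodal(qa, qc)
    from .landau import transition_point  # deferred: landau builds on this module

    p_star = transition_point(qa, qc)
    return TransitionSummary(
        qa=qa, qc=qc, p1_star=p1, p2_star=spin.p2_star, p_star=p_star,
        qc_star=qc_star, transition_type=kind,
        c_plus=spin.c_plus, c_minus=1.0 - spin.c_plus,
    )


@dataclass(frozen=True)
class StationaryBranch:
    """Stationary concentrations with the p at which each is stationary and
    a per-point stability label (True = stable)."""

    cst_values: np.ndarray
    p_values: np.ndarray
    stability: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.cst_values) == len(self.p_values) == len(self.stability)):
            raise ValueError("branch arrays must have equal length")


def stationary_diagram(qa: int, qc: int, grid_size: int = 2001) -> StationaryBranch:
    """Tabulate the stationary diagram cst(p) as one branch table.

    Evaluates p(cst) on a uniform cst grid over (0, 1) — the removable
    point cst = 1/2 carries the lower-spinodal limit — and appends the
    trivial branch cst = 1/2 for a uniform p grid, whose stability switches
    at p1*. Stability of nontrivial points comes from the sign of dF/dc.
    """
    qa, qc = _check_sizes(qa, qc)
    if grid_size < 101:
        raise ValueError("grid_size must be >= 101")
    cst = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]  # open interval
    cst[np.abs(cst - 0.5).argmin()] = 0.5  # removable point carries the limit
    p_vals = stationary_p_of_c(cst, qa, qc)
    stable = np.empty(len(cst), dtype=bool)
    for i, (c, p) in enumerate(zip(cst, p_vals)):
        p_clipped = min(max(float(p), 0.0), 1.0)
        stable[i] = (
            stability_derivative(float(c), ModelParams(qa=qa, qc=qc, p=p_clipped)) < 0
        )
    p1 = lower_spinodal(qa, qc)
    p_grid = np.linspace(0.0, 1.0, grid_size)
    trivial_c = np.full(grid_size, 0.5)
    trivial_stable = p_grid > p1
    return StationaryBranch(
        cst_values=np.concatenate([cst, trivial_c]),
        p_values=np.concatenate([p_vals, p_grid]),
        stability=np.concatenate([stable, trivial_stable]),
    )
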