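"""Effective potential, Landau coefficients, and the discontinuous transition point.

The drift F(c) derives from an effective potential, V(c) = -int F(c) dc,
with the closed form

    V(c) = (1-p)/[(qc+1)(qc+2)] * [c^(qc+1)(c(qc+1) - qc - 2)
           - (1-c)^(qc+1)(c(qc+1) + 1)] + p/(qa+2) * [c^(qa+2) + (1-c)^(qa+2)].

In the order parameter m = 2c - 1 the potential is even, V(m) = V(-m), and
its Landau expansion V = A m^2 + B m^4 + C m^6 has closed-form coefficients
in (qa, qc, p). A changes sign at the lower spinodal; B's sign at p1*
decides the transition order (B = 0 is the tricritical condition); the
sextic-series conditions A = B^2/3C (spinodal) and A = B^2/4C (transition)
hold only while C > 0, which fails shortly above the tricritical point, so
the discontinuous transition point is always computed from the full
potential: it is the p at which the three minima of V(m) are equally deep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams
from .stationary import lower_spinodal, tricritical_qc, upper_spinodal

__all__ = [
    "LandauCoefficients",
    "potential_c",
    "potential_m",
    "landau_abc",
    "transition_point",
    "hysteresis_width",
    "series_estimates",
    "SeriesEstimates",
]

_DEPTH_TOL = 1e-12  # equal-depth bisection tolerance on p


def potential_c(c, params: ModelParams):
    """Effective potential V(c); minima are stable fixed points of the drift.

    The additive constant is fixed by the closed form (no re-zeroing), so
    values are directly comparable across c at fixed parameters. Accepts
    scalars or arrays.
    """
    c = np.asarray(c, dtype=float)
    if np.any((c < 0.0) | (c > 1.0)):
        raise ValueError("c must lie in [0, 1]")
    p, qa, qc = params.p, params.qa, params.qc
    conf = (1.0 - p) / ((qc + 1) * (qc + 2)) * (
        c ** (qc + 1) * (c * (qc + 1) - qc - 2)
        - (1.0 - c) ** (qc + 1) * (c * (qc + 1) + 1)
    )
    anti = p / (qa + 2) * (c ** (qa + 2) + (1.0 - c) ** (qa + 2))
    out = conf + anti
    return float(out) if out.ndim == 0 else out


def potential_m(m, params: ModelParams):
    """Effective potential in the order parameter m = 2c - 1; even in m."""
    m = np.asarray(m, dtype=float)
    if np.any(np.abs(m) > 1.0):
        raise ValueError("m must lie in [-1, 1]")
    p, qa, qc = params.p, params.qa, params.qc
    conf = (1.0 - p) / ((qc + 1) * (qc + 2) * 2 ** (qc + 2)) * (
        (1.0 + m) ** (qc + 1) * ((1.0 + m) * (qc + 1) - 2 * qc - 4)
        - (1.0 - m) ** (qc + 1) * ((1.0 + m) * (qc + 1) + 2)
    )
    anti = p / ((qa + 2) * 2 ** (qa + 2)) * (
        (1.0 + m) ** (qa + 2) + (1.0 - m) ** (qa + 2)
    )
    out = conf + anti
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LandauCoefficients:
    """Coefficients of V(m) = A m^2 + B m^4 + C m^6 about m = 0."""

    A: float
    B: float
    C: float


def landau_abc(params: ModelParams) -> LandauCoefficients:
    """Closed-form Landau coefficients of the sextic expansion of V(m)."""
    p, qa, qc = params.p, params.qa, params.qc
    A = 0.25 * (p * (qa + 1) / 2**qa - (1.0 - p) * (qc - 1) / 2**qc)
    B = (1.0 / 48.0) * (
        p * (qa - 1) * qa * (qa + 1) / 2**qa
        - (1.0 - p) * (qc - 5) * (qc - 1) * qc / 2**qc
    )
    C = (1.0 / 1440.0) * (
        p * (qa - 3) * (qa - 2) * (qa - 1) * qa * (qa + 1) / 2**qa
        - (1.0 - p) * (qc - 9) * (qc - 3) * (qc - 2) * (qc - 1) * qc / 2**qc
    )
    return LandauCoefficients(A=A, B=B, C=C)


def _drift(c: float, qa: int, qc: int, p: float) -> float:
    return (1.0 - p) * ((1.0 - c) * c**qc - c * (1.0 - c) ** qc) + p * (
        (1.0 - c) ** (qa + 1) - c ** (qa + 1)
    )


def _ordered_minimum(qa: int, qc: int, p: float, c_plus: float) -> float:
    """Concentration of the ordered stable fixed point for p below p2*.

    V' = -F, so the ordered minimum of V is the largest root of F on
    (1/2, 1). For p < p2* the drift is positive at c_plus (the
    upper-spinodal maximizer, where the stable and unstable roots merge as
    p -> p2*) and negative at 1, giving a robust bracket at every p in the
    metastable window — including arbitrarily close to the spinodals, where
    grid scans of V fail to resolve the shallow minimum.
    """
    lo, hi = c_plus, 1.0 - 1e-13
    if not _drift(lo, qa, qc, p) > 0.0:
        raise RuntimeError(
            f"no ordered fixed point bracketed for qa={qa}, qc={qc}, p={p}; "
            "inconsistent spinodal classification"
        )
    return brentq(_drift, lo, hi, args=(qa, qc, p), xtol=1e-15)


def transition_point(qa: int, qc: int) -> float:
    """Phase-transition point p*.

    Continuous or tricritical case: p* = p1* (spinodals and transition
    collapse). Discontinuous case: the unique p in (p1*, p2*) at which the
    disordered minimum V(m=0) and the ordered minima V(m+) are equally
    deep, found by bisecting the depth difference V(0) - V(m+) on p.
    """
    p1 = lower_spinodal(qa, qc)
    if qc <= tricritical_qc(qa):
        return p1
    spin = upper_spinodal(qa, qc)

    def depth_gap(p: float) -> float:
        c_ord = _ordered_minimum(qa, qc, p, spin.c_plus)
        params = ModelParams(qa=qa, qc=qc, p=p)
        return potential_c(0.5, params) - potential_c(c_ord, params)

    # gap > 0 just above p1* (ordered phase deeper), < 0 just below p2*
    return float(
        brentq(depth_gap, p1 + 1e-9, spin.p2_star - 1e-9, xtol=_DEPTH_TOL)
    )


def hysteresis_width(qa: int, qc: int) -> float:
    """Spinodal separation p2* - p1*; zero for continuous transitions."""
    spin = upper_spinodal(qa, qc)
    return max(spin.p2_star - lower_spinodal(qa, qc), 0.0)


@dataclass(frozen=True)
class SeriesEstimates:
    """Diagnostic sextic-series estimates of the transition point and upper
    spinodal, valid only while C > 0 near the transition."""

    p_star_series: float | None
    p2_star_series: float | None
    c_is_negative: bool


def series_estimates(qa: int, qc: int) -> SeriesEstimates:
    """Solve the truncated-series conditions A = B^2/4C and A = B^2/3C for p.

    These reproduce the full-potential transition point and upper spinodal
    close above the tricritical point, but the sextic coefficient C turns
    negative a few qc above qc*; in that case the estimates are meaningless
    and ``c_is_negative`` is set with both values None.
    """
    p1 = lower_spinodal(qa, qc)
    if qc <= tricritical_qc(qa):
        raise ValueError(
            "series estimates apply to discontinuous transitions only "
            f"(qa={qa}, qc={qc} is not above the tricritical point)"
        )
    if landau_abc(ModelParams(qa=qa, qc=qc, p=p1)).C <= 0:
        return SeriesEstimates(p_star_series=None, p2_star_series=None,
                               c_is_negative=True)
    p2 = upper_spinodal(qa, qc).p2_star

    def gap(p: float, denom: float) -> float:
        abc = landau_abc(ModelParams(qa=qa, qc=qc, p=p))
        return abc.A - abc.B * abc.B / (denom * abc.C)

    hi = min(2.0 * p2, 1.0)
    p_star = brentq(gap, p1, hi, args=(4.0,), xtol=1e-14)
    p2_star = brentq(gap, p1, hi, args=(3.0,), xtol=1e-14)
    return SeriesEstimates(p_star_series=float(p_star),
                           p2_star_series=float(p2_star), c_is_negative=False)
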