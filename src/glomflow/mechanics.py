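"""Single-capillary physics: the leaky-vessel (transmission-line) pressure
profile, Poiseuille resistance, filtration-resistance balance, and the flow
and concentration profiles along one segment.

The axial pressure in a filtering capillary obeys

    d²p/dx² − a² p = −a² p_BS,        a² = R / (R_f L²),

where R is the Poiseuille flow resistance of the segment, R_f its
resistance to transmural filtration, L its length and p_BS the Bowman's
space pressure outside the wall.  The closed-form solution is a
cosh/sinh combination pinned to the end pressures; all integrals used by
the solver (excess transmural pressure, cumulative filtration, mean flow)
have closed forms as well, evaluated in a scaled representation that stays
finite for large aL.

All functions here are unit-consistent: pressures, resistances and flows
may be supplied in any single coherent unit system (the network solver
uses the µg/s/µm working units; tests often use reported units directly).
Only :func:`poiseuille_resistance` performs unit conversion, since the
128µL/(πD⁴) formula mixes viscosity, geometry and resistance scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import to_working, from_working

__all__ = [
    "SegmentProfile",
    "FlowProfile",
    "poiseuille_resistance",
    "leakage_coefficient",
    "solve_pressure_profile",
    "excess_pressure_integral",
    "flow_profile",
    "update_filtration_resistance",
    "concentration_profile",
]

_GAUSS_ORDER = 16
_GX, _GW = np.polynomial.legendre.leggauss(_GAUSS_ORDER)


def gauss_points(length: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes and weights mapped onto [0, length]."""
    x = 0.5 * length * (_GX + 1.0)
    w = 0.5 * length * _GW
    return x, w


def poiseuille_resistance(mu_cp: float, diameter_um: float, length_um: float) -> float:
    """Poiseuille flow resistance R = 128 µ L / (π D⁴) of one segment.

    Inputs in reported units (cP, µm); returns mmHg·min/nL.  The
    evaluation itself happens in working units.
    """
    if mu_cp <= 0 or diameter_um <= 0 or length_um <= 0:
        raise ValueError("viscosity, diameter and length must be positive")
    mu_w = to_working(mu_cp, "viscosity")
    r_w = 128.0 * mu_w * length_um / (math.pi * diameter_um**4)
    return from_working(r_w, "resistance")


def leakage_coefficient(resistance: float, r_f: float, length: float) -> float:
    """Leakage coefficient a = sqrt(R / (R_f L²)), units 1/length.

    R and R_f must be in the same (resistance) units; a → 0 as the wall
    becomes impermeable (R_f → ∞).
    """
    if resistance <= 0 or r_f <= 0 or length <= 0:
        raise ValueError("resistance, filtration resistance and length must be positive")
    return math.sqrt(resistance / (r_f * length**2))


# -- stable hyperbolic building blocks --------------------------------------
# For aL <= 20 direct hyperbolics are exact; beyond that everything is
# rewritten in terms of exp(-a·(non-negative)) so nothing overflows.

def _phi(a: float, x, length: float):
    """sinh(a x) / sinh(a L); -> x/L as a -> 0."""
    x = np.asarray(x, dtype=float)
    al = a * length
    if al < 1e-8:
        return x / length
    if al <= 20.0:
        return np.sinh(a * x) / math.sinh(al)
    return np.exp(-a * (length - x)) * (1.0 - np.exp(-2.0 * a * x)) / (
        1.0 - math.exp(-2.0 * al)
    )


def _psi(a: float, x, length: float):
    """∫₀ˣ φ = (cosh(a x) − 1)/(a sinh(a L)); -> x²/(2L) as a -> 0."""
    x = np.asarray(x, dtype=float)
    al = a * length
    if al < 1e-8:
        return x * x / (2.0 * length)
    if al <= 20.0:
        return (np.cosh(a * x) - 1.0) / (a * math.sinh(al))
    num = np.exp(-a * (length - x)) * (1.0 + np.exp(-2.0 * a * x)) - 2.0 * np.exp(
        -a * length
    )
    return num / (a * (1.0 - math.exp(-2.0 * al)))


def _half_tanh_over_a(a: float, length: float) -> float:
    """tanh(aL/2)/a = ∫₀ᴸ φ dx; -> L/2 as a -> 0."""
    al = a * length
    if al < 1e-8:
        return length / 2.0
    return math.tanh(al / 2.0) / a


@dataclass(frozen=True)
class SegmentProfile:
    """Closed-form pressure profile p(x) on one capillary segment.

    x runs from 0 (the p_i end) to ``length`` (the p_j end).
    """

    p_i: float
    p_j: float
    a: float         # leakage coefficient, 1/length
    length: float
    p_bs: float

    def pressure(self, x):
        """p(x) = p_BS + (p_i−p_BS)·φ(L−x) + (p_j−p_BS)·φ(x)."""
        x = np.asarray(x, dtype=float)
        out = (
            self.p_bs
            + (self.p_i - self.p_bs) * _phi(self.a, self.length - x, self.length)
            + (self.p_j - self.p_bs) * _phi(self.a, x, self.length)
        )
        return float(out) if out.ndim == 0 else out

    def cumulative_excess(self, x):
        """S(x) = ∫₀ˣ (p(u) − p_BS) du, closed form."""
        x = np.asarray(x, dtype=float)
        psi_l = _psi(self.a, self.length, self.length)
        out = (self.p_i - self.p_bs) * (
            psi_l - _psi(self.a, self.length - x, self.length)
        ) + (self.p_j - self.p_bs) * _psi(self.a, x, self.length)
        return float(out) if out.ndim == 0 else out

    def mean_pressure(self) -> float:
        """Length-mean of p(x)."""
        return self.p_bs + excess_pressure_integral(self) / self.length


def solve_pressure_profile(
    p_i: float, p_j: float, a: float, length: float, p_bs: float
) -> SegmentProfile:
    """Closed-form solution of the leaky-vessel ODE with end pressures p_i, p_j.

    a = 0 degenerates to the linear (pure Poiseuille) interpolant.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if a < 0:
        raise ValueError("leakage coefficient must be non-negative")
    return SegmentProfile(p_i=p_i, p_j=p_j, a=a, length=length, p_bs=p_bs)


def excess_pressure_integral(profile: SegmentProfile) -> float:
    """∫₀ᴸ (p(x) − p_BS) dx, closed form.

    Equals [(p_i−p_BS) + (p_j−p_BS)]·tanh(aL/2)/a; for a = 0 this is the
    trapezoid value L·((p_i+p_j)/2 − p_BS).
    """
    w = _half_tanh_over_a(profile.a, profile.length)
    return ((profile.p_i - profile.p_bs) + (profile.p_j - profile.p_bs)) * w


@dataclass(frozen=True)
class FlowProfile:
    """Blood flow Q(x) along a filtering segment.

    dQ/dx = −(p(x) − p_BS)/(L R_f); Q(0) = q_in.  The total loss
    Q(0) − Q(L) is the capillary-segment filtration rate (CSGFR).
    """

    profile: SegmentProfile
    r_f: float
    q_in: float

    def flow(self, x):
        out = self.q_in - self.profile.cumulative_excess(x) / (
            self.profile.length * self.r_f
        )
        return out

    @property
    def q_out(self) -> float:
        return float(self.flow(self.profile.length))

    @property
    def csgfr(self) -> float:
        """Filtration rate of the segment = ∫(p−p_BS)dx / (L R_f)."""
        return excess_pressure_integral(self.profile) / (
            self.profile.length * self.r_f
        )

    def mean_abs_flow(self) -> float:
        """Length-average of |Q(x)| (Gauss quadrature on the closed form)."""
        x, w = gauss_points(self.profile.length)
        return float(np.dot(w, np.abs(self.flow(x))) / self.profile.length)


def flow_profile(profile: SegmentProfile, r_f: float, q_in: float) -> FlowProfile:
    """Flow profile for a converged pressure profile and filtration resistance."""
    if r_f <= 0:
        raise ValueError("filtration resistance must be positive")
    return FlowProfile(profile=profile, r_f=r_f, q_in=q_in)


def update_filtration_resistance(
    profile: SegmentProfile,
    oncotic_at,
    k: float,
    diameter: float,
    r_f_max: float = 1e15,
) -> tuple[float, bool]:
    """Filtration-resistance update balancing pressure against filtration.

    R_f = ∫(p−p_BS)dx / (k π L D ∫(p−p_BS−Π)dx), with both integrals taken
    over the previous iterate's profiles.  ``oncotic_at`` maps x -> Π(x)
    (same pressure units as the profile); pass ``lambda x: 0`` for
    protein-free plasma, in which case R_f = 1/(kπLD) exactly.

    Returns ``(r_f, clamped)``; a non-positive denominator (whole-segment
    filtration equilibrium or net reabsorption) clamps R_f to ``r_f_max``
    and flags the segment as effectively non-filtering.  Local reabsorption
    (Π exceeding the transmural pressure pointwise) is permitted.
    """
    if k <= 0 or diameter <= 0:
        raise ValueError("k and diameter must be positive")
    length = profile.length
    numerator = excess_pressure_integral(profile)
    x, w = gauss_points(length)
    pi_int = float(np.dot(w, np.asarray(oncotic_at(x), dtype=float)))
    denominator = k * math.pi * length * diameter * (numerator - pi_int)
    if denominator <= 0.0 or numerator <= 0.0:
        return r_f_max, True
    r_f = numerator / denominator
    if r_f > r_f_max:
        return r_f_max, True
    return r_f, False


def concentration_profile(c_in: float, q_plasma_in: float, flowp: FlowProfile,
                          q_rbc: float):
    """Protein concentration along the segment from plasma mass conservation.

    C(x) = C_in · Q_plasma(0) / Q_plasma(x) with Q_plasma(x) = Q(x) − Q_RBC
    (erythrocyte flow is constant along a segment; filtrate is protein-free).
    Returns a callable x -> C(x).  Raises if plasma flow is exhausted
    anywhere on the segment (non-physical input).
    """
    if q_plasma_in <= 0:
        raise ValueError("inlet plasma flow must be positive")

    def c_at(x):
        qp = flowp.flow(x) - q_rbc
        if np.any(np.asarray(qp) <= 0):
            raise ValueError("plasma flow exhausted within the segment")
        return c_in * q_plasma_in / qp

    return c_at
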