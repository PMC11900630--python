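"""Constitutive laws: apparent blood viscosity, colloid osmotic pressure,
and erythrocyte/protein routing at network nodes.

Three empirical relations are used, each behind a coefficient set that can
be overridden in the run config:

* colloid osmotic (oncotic) pressure — Landis–Pappenheimer cubic in the
  plasma protein concentration C (g/dL):
  ``Pi = a1*C + a2*C**2 + a3*C**3`` mmHg, defaults (2.1, 0.16, 0.009);
* apparent in-vitro blood viscosity — the Pries–Neuhaus–Gaehtgens tube-flow
  law giving relative viscosity as a function of tube diameter (µm) and
  discharge hematocrit, multiplied by a plasma viscosity that rises
  linearly with protein concentration;
* phase separation of erythrocytes at diverging bifurcations — the Pries
  empirical logit law relating the fractional erythrocyte flow into a
  daughter branch to its fractional blood flow, the parent diameter and
  hematocrit, and the daughter diameter ratio.

Plasma protein is confined to plasma (sieving coefficient 0): filtrate is
protein-free water, so protein mass and RBC volume are conserved at every
node operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RheologyCoefficients",
    "BloodState",
    "colloid_osmotic_pressure",
    "plasma_viscosity",
    "relative_viscosity",
    "apparent_viscosity",
    "split_erythrocytes",
    "mix_at_converging_node",
]


@dataclass(frozen=True)
class RheologyCoefficients:
    """Coefficient set for the three empirical laws (reported units)."""

    # oncotic cubic, mmHg per (g/dL)^n
    oncotic: tuple[float, float, float] = (2.1, 0.16, 0.009)
    # plasma viscosity µ_p = base + slope*C, cP
    plasma_visc_base: float = 0.9
    plasma_visc_slope: float = 0.0614
    # phase separation logit-law coefficients
    ps_a: float = -6.96   # × ln(D_alpha/D_beta)/D_f
    ps_b: float = 6.98    # B = 1 + ps_b (1-H)/D_f
    ps_x0: float = 0.4    # X0 = ps_x0/D_f

    def as_dict(self) -> dict:
        return {
            "oncotic": list(self.oncotic),
            "plasma_visc_base": self.plasma_visc_base,
            "plasma_visc_slope": self.plasma_visc_slope,
            "ps_a": self.ps_a,
            "ps_b": self.ps_b,
            "ps_x0": self.ps_x0,
        }


DEFAULT_COEFFS = RheologyCoefficients()


@dataclass(frozen=True)
class BloodState:
    """Composition of blood at a point: hematocrit, protein, viscosity."""

    hematocrit: float       # fraction
    protein_conc: float     # g/dL
    viscosity: float | None = None  # cP, if evaluated

    def __post_init__(self) -> None:
        if not 0.0 <= self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.protein_conc < 0:
            raise ValueError("protein concentration must be non-negative")


def colloid_osmotic_pressure(
    protein_conc, coeffs: RheologyCoefficients = DEFAULT_COEFFS
):
    """Oncotic pressure Pi (mmHg) for plasma protein concentration C (g/dL).

    Cubic with positive coefficients: Pi(0) = 0, strictly increasing and
    convex for C > 0.  Accepts scalars or arrays.
    """
    c = np.asarray(protein_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("protein concentration must be non-negative")
    a1, a2, a3 = coeffs.oncotic
    out = c * (a1 + c * (a2 + c * a3))
    return float(out) if np.isscalar(protein_conc) else out


def plasma_viscosity(protein_conc, coeffs: RheologyCoefficients = DEFAULT_COEFFS):
    """Plasma viscosity (cP), rising linearly with protein concentration."""
    c = np.asarray(protein_conc, dtype=float)
    out = coeffs.plasma_visc_base + coeffs.plasma_visc_slope * c
    return float(out) if np.isscalar(protein_conc) else out


def relative_viscosity(diameter, hematocrit):
    """In-vitro relative apparent viscosity of blood in a tube.

    Pries–Neuhaus–Gaehtgens law: relative viscosity as a function of tube
    diameter D (µm) and discharge hematocrit H.  Exhibits the
    Fåhræus–Lindqvist minimum near capillary diameters.  Returns 1 at H=0.
    """
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(hematocrit, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    if np.any(h < 0) or np.any(h >= 1):
        raise ValueError("hematocrit must lie in [0, 1)")
    eta45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    dampen = 1.0 / (1.0 + 1e-11 * d**12)
    cshape = (0.8 + np.exp(-0.075 * d)) * (dampen - 1.0) + dampen
    # at H = 0.45 the bracket is 1 by construction
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = ((1.0 - h) ** cshape - 1.0) / ((1.0 - 0.45) ** cshape - 1.0)
    out = 1.0 + (eta45 - 1.0) * frac
    if out.ndim == 0:
        return float(out)
    return out


def apparent_viscosity(
    diameter, hematocrit, protein_conc,
    coeffs: RheologyCoefficients = DEFAULT_COEFFS,
):
    """Apparent blood viscosity µ (cP) in a tube of diameter D.

    µ = plasma_viscosity(C) × relative_viscosity(D, H); reduces to the
    plasma viscosity at H = 0 and increases monotonically with H.
    """
    return plasma_viscosity(protein_conc, coeffs) * relative_viscosity(
        diameter, hematocrit
    )


def _logit(x):
    return np.log(x / (1.0 - x))


def _phase_fraction(
    fq_blood: float, h_parent: float, d_parent: float,
    d_alpha: float, d_beta: float, coeffs: RheologyCoefficients,
) -> float:
    """Fractional erythrocyte flow into daughter alpha (Pries logit law)."""
    x0 = coeffs.ps_x0 / d_parent
    if fq_blood <= x0:
        return 0.0
    if fq_blood >= 1.0 - x0:
        return 1.0
    a = coeffs.ps_a * np.log(d_alpha / d_beta) / d_parent
    b = 1.0 + coeffs.ps_b * (1.0 - h_parent) / d_parent
    logit_in = _logit((fq_blood - x0) / (1.0 - 2.0 * x0))
    z = a + b * logit_in
    return float(1.0 / (1.0 + np.exp(-z)))


def split_erythrocytes(
    parent: BloodState,
    parent_flow: float,
    daughters: list[tuple[float, float]],
    parent_diameter: float = 7.0,
    coeffs: RheologyCoefficients = DEFAULT_COEFFS,
    max_hematocrit: float = 0.95,
) -> list[float]:
    """Distribute erythrocytes from a parent stream into daughter branches.

    Parameters
    ----------
    parent : BloodState
        Composition of the feeding stream.
    parent_flow : float
        Blood flow of the feeding stream (any consistent unit).
    daughters : list of (flow_fraction, diameter)
        Fractional blood flow (must sum to 1) and diameter (µm) of each
        daughter branch.
    parent_diameter : float
        Feeding-vessel diameter (µm) used by the empirical law.

    Returns
    -------
    list of float
        Daughter hematocrits.  RBC volume is conserved:
        sum(flow_k * H_k) == parent_flow * parent.hematocrit.

    Notes
    -----
    The empirical law is binary; with more than two daughters it is applied
    sequentially in descending flow order, which preserves conservation.
    """
    fracs = np.array([f for f, _ in daughters], dtype=float)
    if np.any(fracs <= 0):
        raise ValueError("daughter flow fractions must be positive")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"daughter flow fractions sum to {fracs.sum()}, not 1")

    order = np.argsort(-fracs)
    h = np.zeros(len(daughters))
    rem_frac = 1.0            # remaining blood-flow fraction of parent
    rem_h = parent.hematocrit  # hematocrit of the remaining stream
    rem_d = parent_diameter
    for idx_pos, i in enumerate(order):
        if idx_pos == len(order) - 1:
            h[i] = min(rem_h, max_hematocrit)
            break
        f_alpha = fracs[i] / rem_frac
        d_beta = float(np.mean([daughters[j][1] for j in order[idx_pos + 1:]]))
        fq_e = _phase_fraction(
            min(max(f_alpha, 0.0), 1.0), rem_h, rem_d,
            daughters[i][1], d_beta, coeffs,
        )
        rbc_rem = rem_frac * rem_h
        h_alpha = min(fq_e * rbc_rem / fracs[i], max_hematocrit)
        h[i] = h_alpha
        rbc_rem -= fracs[i] * h_alpha
        rem_frac = max(rem_frac - fracs[i], 1e-15)
        rem_h = max(rbc_rem, 0.0) / rem_frac
    # the empirical law can pile erythrocytes into a slow daughter beyond
    # the hematocrit cap; redistribute any clipped excess so that RBC
    # volume is conserved exactly (unless the parent itself is at the cap)
    deficit = parent.hematocrit - float(np.dot(fracs, h))
    if deficit > 1e-15:
        for j in np.argsort(h):  # most capacity first
            cap = (max_hematocrit - h[j]) * fracs[j]
            take = min(cap, deficit)
            if take > 0:
                h[j] += take / fracs[j]
                deficit -= take
            if deficit <= 1e-15:
                break
    return [float(x) for x in h]


def mix_at_converging_node(
    inflows: list[tuple[BloodState, float]],
) -> BloodState:
    """Perfectly mix converging streams; conserves RBC volume and protein mass.

    ``inflows`` is a list of (state, blood flow) pairs with positive flows.
    The mixed hematocrit is the blood-flow-weighted mean; the mixed protein
    concentration is the plasma-flow-weighted mean (protein travels in
    plasma only).
    """
    if not inflows:
        raise ValueError("no inflows")
    flows = np.array([q for _, q in inflows], dtype=float)
    if np.any(flows <= 0):
        raise ValueError("inflows must be positive")
    h = np.array([s.hematocrit for s, _ in inflows])
    c = np.array([s.protein_conc for s, _ in inflows])
    q_tot = flows.sum()
    h_mix = float(np.dot(flows, h) / q_tot)
    qp = flows * (1.0 - h)
    c_mix = float(np.dot(qp, c) / qp.sum())
    return BloodState(hematocrit=h_mix, protein_conc=c_mix)
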