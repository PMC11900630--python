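"""Working-unit system and fixed physiological constants.

All internal arithmetic runs in a (µg, s, µm) working-unit system chosen so
that every model variable has magnitude comfortably far from the double
underflow regime.  Reported (literature) units are converted on the way in
by multiplication with a fixed factor, and back out by division.  Only the
ten quantities the model actually uses are covered; this is deliberately not
a general unit-algebra layer.

Derived factors are stored as exact ratios of their parents (resistance =
pressure/flow, hydraulic conductivity = flow/pressure) rather than as the
rounded display values, so that e.g. Ohm's-law arithmetic performed in
working units is internally consistent to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "WORKING_FACTORS",
    "PhysioConstants",
    "to_working",
    "from_working",
]

# reported unit -> working (µg, s, µm) multiplier
_PRESSURE = 133322.0          # mmHg -> µg s^-2 µm^-1
_FLOW = 16666.67              # nL/min -> µm^3 s^-1  (1e6/60, printed convention)
_SHEAR = 100.0                # dyn/cm^2 -> µg s^-2 µm^-1
_HOOP = 1.0e6                 # kPa -> µg s^-2 µm^-1

WORKING_FACTORS: dict[str, float] = {
    "diameter": 1.0,                      # µm
    "length": 1.0,                        # µm
    "pressure": _PRESSURE,                # mmHg
    "flow": _FLOW,                        # nL/min
    "resistance": _PRESSURE / _FLOW,      # mmHg/(nL/min); prints as 8
    "shear_stress": _SHEAR,               # dyn/cm^2
    "hoop_stress": _HOOP,                 # kPa
    "viscosity": 1.0,                     # cP == µg s^-1 µm^-1
    "csgfr": _FLOW,                       # nL/min
    "hydraulic_conductivity": _FLOW / _PRESSURE,  # nL/min/mmHg/µm^2; prints 0.125
}


def to_working(value: float, quantity: str) -> float:
    """Convert ``value`` from its reported unit to working (µg, s, µm) units."""
    try:
        return value * WORKING_FACTORS[quantity]
    except KeyError:
        raise KeyError(
            f"unknown quantity {quantity!r}; known: {sorted(WORKING_FACTORS)}"
        ) from None


def from_working(value: float, quantity: str) -> float:
    """Inverse of :func:`to_working`."""
    try:
        return value / WORKING_FACTORS[quantity]
    except KeyError:
        raise KeyError(
            f"unknown quantity {quantity!r}; known: {sorted(WORKING_FACTORS)}"
        ) from None


@dataclass(frozen=True)
class PhysioConstants:
    """Fixed physiological boundary constants, in reported units.

    Parameters
    ----------
    p_bs : float
        Bowman's-space (capsular) pressure opposing filtration, mmHg.
    p_downstream : float
        Pressure downstream of the efferent resistor, mmHg.
    systemic_hematocrit : float
        Hematocrit of blood entering the afferent arteriole (fraction).
        Rat micropuncture convention; not a measured input.
    afferent_protein_conc : float
        Plasma protein concentration entering the glomerulus, g/dL.
    wall_thickness_default : float
        Capillary wall thickness used when the network file does not
        provide one, µm.  Hoop-stress magnitudes scale as 1/t, so reports
        echo this value.
    """

    p_bs: float = 14.0
    p_downstream: float = 15.0
    systemic_hematocrit: float = 0.5
    afferent_protein_conc: float = 5.7
    wall_thickness_default: float = 0.2

    def __post_init__(self) -> None:
        if self.p_bs <= 0 or self.p_downstream <= 0:
            raise ValueError("pressures must be strictly positive")
        if not 0.0 < self.systemic_hematocrit < 1.0:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.afferent_protein_conc < 0:
            raise ValueError("protein concentration must be non-negative")
        if self.wall_thickness_default <= 0:
            raise ValueError("wall thickness must be positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "p_bs": self.p_bs,
            "p_downstream": self.p_downstream,
            "systemic_hematocrit": self.systemic_hematocrit,
            "afferent_protein_conc": self.afferent_protein_conc,
            "wall_thickness_default": self.wall_thickness_default,
        }
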