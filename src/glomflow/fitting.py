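"""Fitting arteriolar resistances and hydraulic conductivity to
micropuncture hemodynamic targets.

For each experimental condition the mean arterial pressure (MAP) is taken
as given and three parameters are adjusted: the afferent and efferent
arteriolar resistances R_A and R_E until the mean capillary pressure P_GC
and the glomerular plasma flow Q_A match their targets, and the capillary
hydraulic conductivity k until the single-nephron GFR matches its target.
The two stages alternate; they decouple almost completely because changes
in k barely move P_GC and Q_A (the capillary network resistance is small
next to the arteriolar resistors), so the loop converges in a few passes.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .network import BoundaryConditions, GlomerularNetwork
from .rheology import RheologyCoefficients, DEFAULT_COEFFS
from .solver import (
    NetworkSolution,
    SolverOptions,
    fit_hydraulic_conductivity,
    solve_network,
)
from .units import PhysioConstants

__all__ = [
    "HemodynamicTargets",
    "FittedCondition",
    "FitError",
    "fit_arteriolar_resistances",
    "fit_condition",
    "read_conditions",
    "write_conditions",
    "packaged_conditions",
]

RESISTANCE_BOUNDS = (1e-4, 1e3)  # mmHg·min/nL


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class HemodynamicTargets:
    """One experimental condition's hemodynamic targets (reported units).

    Q_A is glomerular *plasma* flow (micropuncture convention).
    """

    condition: str
    map_pressure: float     # mmHg
    p_gc: float             # mmHg
    q_a: float              # nL/min plasma
    sngfr: float            # nL/min
    tolerance: float = 0.005  # relative, per quantity

    def __post_init__(self) -> None:
        if not self.map_pressure > self.p_gc:
            raise ValueError("MAP must exceed the target P_GC")
        if not self.q_a > self.sngfr > 0:
            raise ValueError("require Q_A > SNGFR > 0")


@dataclass
class FittedCondition:
    """Fit result for one condition: parameters, solution, diagnostics."""

    targets: HemodynamicTargets
    r_a: float
    r_e: float
    k: float
    solution: NetworkSolution
    passes: int
    achieved: dict[str, float] = field(default_factory=dict)

    @property
    def relative_errors(self) -> dict[str, float]:
        t = self.targets
        s = self.solution
        return {
            "p_gc": abs(s.p_gc - t.p_gc) / t.p_gc,
            "q_a": abs(s.q_a_plasma - t.q_a) / t.q_a,
            "sngfr": abs(s.sngfr - t.sngfr) / t.sngfr,
        }


def _initial_resistances(targets: HemodynamicTargets,
                         bc: BoundaryConditions) -> tuple[float, float]:
    """Two-resistor algebra ignoring filtration: a good Newton seed."""
    q_blood = targets.q_a / (1.0 - bc.hematocrit_in)
    r_a0 = (targets.map_pressure - targets.p_gc) / q_blood
    q_eff = q_blood - targets.sngfr
    r_e0 = (targets.p_gc - bc.p_downstream) / max(q_eff, 0.1 * q_blood)
    lo, hi = RESISTANCE_BOUNDS
    return min(max(r_a0, lo * 10), hi / 10), min(max(r_e0, lo * 10), hi / 10)


def fit_arteriolar_resistances(
    network: GlomerularNetwork,
    bc: BoundaryConditions,
    p_gc_target: float,
    q_a_target: float,
    k: float,
    options: SolverOptions | None = None,
    coeffs: RheologyCoefficients = DEFAULT_COEFFS,
    x0: tuple[float, float] | None = None,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Find (R_A, R_E) achieving the target (P_GC, Q_A) at fixed k.

    Root-find on log-resistances with a trust-region quasi-Newton method;
    the map is monotone (raising R_A lowers both P_GC and Q_A, raising R_E
    raises P_GC and lowers Q_A), so the relative-residual root is unique
    within the physiological bounds.
    """
    if not bc.map_pressure > p_gc_target > bc.p_downstream:
        raise FitError(
            f"infeasible targets: require MAP ({bc.map_pressure}) > P_GC "
            f"({p_gc_target}) > downstream pressure ({bc.p_downstream})"
        )
    if q_a_target <= 0:
        raise FitError("target Q_A must be positive")

    if x0 is None:
        dummy = HemodynamicTargets(
            "seed", bc.map_pressure, p_gc_target, q_a_target,
            0.2 * q_a_target,
        )
        x0 = _initial_resistances(dummy, bc)
    lo, hi = np.log(RESISTANCE_BOUNDS[0]), np.log(RESISTANCE_BOUNDS[1])

    def residual(z: np.ndarray) -> np.ndarray:
        r_a, r_e = np.exp(np.clip(z, lo, hi))
        sol = solve_network(network, bc, k, r_a, r_e, options, coeffs)
        return np.array(
            [(sol.p_gc - p_gc_target) / p_gc_target,
             (sol.q_a_plasma - q_a_target) / q_a_target]
        )

    z0 = np.log(np.array(x0))
    res = optimize.root(residual, z0, method="hybr",
                        options={"xtol": tol, "maxfev": 120})
    r = residual(res.x)
    if not res.success and float(np.max(np.abs(r))) > 1e-4:
        # the residual surface has small branch discontinuities (discrete
        # erythrocyte routing); fall back on the monotone structure with
        # alternating scalar bisections: R_A -> Q_A, R_E -> P_GC
        return _alternating_resistance_fit(
            network, bc, p_gc_target, q_a_target, k,
            np.exp(np.clip(res.x, lo, hi)), options, coeffs,
        )
    r_a, r_e = np.exp(np.clip(res.x, lo, hi))
    return float(r_a), float(r_e)


def _alternating_resistance_fit(network, bc, p_gc_target, q_a_target, k,
                                start, options, coeffs,
                                rtol=5e-4, max_outer=6):
    from scipy.optimize import brentq

    r_a, r_e = float(start[0]), float(start[1])
    lo, hi = RESISTANCE_BOUNDS

    def solve_at(ra, re_):
        return solve_network(network, bc, k, ra, re_, options, coeffs)

    def bracket_root(f, x_start, decreasing):
        # f monotone in log x; expand a bracket around x_start
        sgn = -1.0 if decreasing else 1.0
        a = b = math.log(x_start)
        fa = fb = f(x_start)
        step = 0.4
        for _ in range(30):
            if sgn * fa < 0 <= sgn * fb or sgn * fb < 0 <= sgn * fa:
                break
            if sgn * fa > 0:
                a = max(a - step, math.log(lo))
                fa = f(math.exp(a))
            else:
                b = min(b + step, math.log(hi))
                fb = f(math.exp(b))
            step *= 1.5
        else:
            raise FitError("could not bracket the resistance root")
        if a == b:
            return math.exp(a)
        return math.exp(brentq(lambda z: f(math.exp(z)), a, b, xtol=2e-4))

    err = (math.inf, math.inf)
    for _ in range(max_outer):
        r_a = bracket_root(
            lambda ra: solve_at(ra, r_e).q_a_plasma - q_a_target,
            r_a, decreasing=True,
        )
        r_e = bracket_root(
            lambda re_: solve_at(r_a, re_).p_gc - p_gc_target,
            r_e, decreasing=False,
        )
        sol = solve_at(r_a, r_e)
        err = (abs(sol.p_gc - p_gc_target) / p_gc_target,
               abs(sol.q_a_plasma - q_a_target) / q_a_target)
        if max(err) < rtol:
            return float(r_a), float(r_e)
    if max(err) < 5e-3:
        return float(r_a), float(r_e)
    raise FitError(
        f"resistance fit failed: relative residuals (P_GC, Q_A) = {err}"
    )


def fit_condition(
    network: GlomerularNetwork,
    targets: HemodynamicTargets,
    physio: PhysioConstants | None = None,
    options: SolverOptions | None = None,
    coeffs: RheologyCoefficients = DEFAULT_COEFFS,
    k_init: float = 2e-5,
    max_passes: int = 10,
) -> FittedCondition:
    """Alternate the (R_A, R_E) and k fits until all three targets are met.

    Converges in a few passes because P_GC and Q_A are nearly insensitive
    to k.  Raises :class:`FitError` with per-pass diagnostics if the
    stated tolerance is not reached within ``max_passes``.
    """
    physio = physio or PhysioConstants()
    bc = BoundaryConditions(
        map_pressure=targets.map_pressure,
        p_downstream=physio.p_downstream,
        p_bs=physio.p_bs,
        hematocrit_in=physio.systemic_hematocrit,
        protein_conc_in=physio.afferent_protein_conc,
    )
    k = k_init
    x0 = None
    diagnostics = []
    for n_pass in range(1, max_passes + 1):
        r_a, r_e = fit_arteriolar_resistances(
            network, bc, targets.p_gc, targets.q_a, k,
            options, coeffs, x0=x0,
        )
        k = fit_hydraulic_conductivity(
            network, bc, targets.sngfr, r_a, r_e,
            options=options, coeffs=coeffs,
        )
        sol = solve_network(network, bc, k, r_a, r_e, options, coeffs)
        errs = {
            "p_gc": abs(sol.p_gc - targets.p_gc) / targets.p_gc,
            "q_a": abs(sol.q_a_plasma - targets.q_a) / targets.q_a,
            "sngfr": abs(sol.sngfr - targets.sngfr) / targets.sngfr,
        }
        diagnostics.append({"pass": n_pass, "r_a": r_a, "r_e": r_e, "k": k, **errs})
        if max(errs.values()) < targets.tolerance:
            fitted = FittedCondition(
                targets=targets, r_a=r_a, r_e=r_e, k=k,
                solution=sol, passes=n_pass,
                achieved={"p_gc": sol.p_gc, "q_a": sol.q_a_plasma,
                          "sngfr": sol.sngfr},
            )
            return fitted
        x0 = (r_a, r_e)
    raise FitError(
        f"condition {targets.condition!r} did not converge in {max_passes} "
        f"passes; diagnostics: {diagnostics}"
    )


# ---------------------------------------------------------------------------
# conditions-table I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["condition", "MAP", "P_GC", "Q_A", "SNGFR"]


def read_conditions(path: str | Path) -> list[HemodynamicTargets]:
    """Read a conditions table (CSV: condition,MAP,P_GC,Q_A,SNGFR)."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"conditions file missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("conditions file contains no rows")
    return [
        HemodynamicTargets(
            condition=str(r["condition"]),
            map_pressure=float(r["MAP"]),
            p_gc=float(r["P_GC"]),
            q_a=float(r["Q_A"]),
            sngfr=float(r["SNGFR"]),
        )
        for _, r in df.iterrows()
    ]


def write_conditions(conditions: list[HemodynamicTargets], path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "condition": [c.condition for c in conditions],
            "MAP": [c.map_pressure for c in conditions],
            "P_GC": [c.p_gc for c in conditions],
            "Q_A": [c.q_a for c in conditions],
            "SNGFR": [c.sngfr for c in conditions],
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def packaged_conditions() -> list[HemodynamicTargets]:
    """The four packaged purinergic-blockade study conditions.

    Sham, Sham + NF449 (P2X1 antagonist), AngII-induced hypertension, and
    AngII + NF449, with MAP and the (P_GC, Q_A, SNGFR) targets from the
    underlying rat micropuncture data.
    """
    ref = importlib.resources.files("glomflow.data").joinpath("conditions.csv")
    with importlib.resources.as_file(ref) as path:
        return read_conditions(path)
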