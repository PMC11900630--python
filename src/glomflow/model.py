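"""Model/Results facade over the network solver and fitting machinery.

:class:`GlomerulusModel` bundles a capillary network with the
physiological constants and rheology coefficients of a study.  Its
``solve`` method runs one forward simulation; ``fit`` adjusts the
arteriolar resistances and hydraulic conductivity to a condition's
hemodynamic targets and returns a :class:`ConditionFitResults` carrying
the estimates, fit diagnostics, the converged solution and a ``summary()``
table, with the per-capillary stress report hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fitting import FittedCondition, HemodynamicTargets, fit_condition
from .network import BoundaryConditions, GlomerularNetwork, read_network
from .rheology import RheologyCoefficients, DEFAULT_COEFFS
from .solver import NetworkSolution, SolverOptions, solve_network
from .stress import StressReport, build_stress_report
from .synthetic import GeneratorSpec, generate_network
from .units import PhysioConstants

__all__ = ["GlomerulusModel", "ConditionFitResults"]


class GlomerulusModel:
    """Blood flow and filtration in one glomerular capillary network.

    Parameters
    ----------
    network : GlomerularNetwork
        Validated capillary graph with one afferent entry and one
        efferent exit.
    physio : PhysioConstants, optional
        Boundary constants (Bowman's-space pressure, downstream pressure,
        afferent hematocrit and protein concentration).
    coeffs : RheologyCoefficients, optional
        Coefficients of the empirical viscosity/oncotic/phase-separation
        laws.
    options : SolverOptions, optional
        Numerical options of the fixed-point solver.

    Examples
    --------
    >>> from glomflow import GlomerulusModel
    >>> model = GlomerulusModel.from_generator(seed=1)
    >>> res = model.fit_named_condition("Sham")
    >>> round(res.solution.p_gc, 1)
    46.8
    """

    def __init__(
        self,
        network: GlomerularNetwork,
        physio: PhysioConstants | None = None,
        coeffs: RheologyCoefficients = DEFAULT_COEFFS,
        options: SolverOptions | None = None,
    ):
        network.validate()
        self.network = network
        self.physio = physio or PhysioConstants()
        self.coeffs = coeffs
        self.options = options or SolverOptions()

    @classmethod
    def from_generator(cls, spec: GeneratorSpec | None = None,
                       seed: int | None = None, **kwargs) -> "GlomerulusModel":
        """Build on a synthetic network (default scale: 320 segments/193 nodes)."""
        if spec is None:
            spec = GeneratorSpec(seed=seed if seed is not None else 1)
        return cls(generate_network(spec), **kwargs)

    @classmethod
    def from_file(cls, path, **kwargs) -> "GlomerulusModel":
        physio = kwargs.get("physio") or PhysioConstants()
        net = read_network(
            path, default_wall_thickness=physio.wall_thickness_default
        )
        return cls(net, **kwargs)

    def boundary_conditions(self, map_pressure: float) -> BoundaryConditions:
        return BoundaryConditions(
            map_pressure=map_pressure,
            p_downstream=self.physio.p_downstream,
            p_bs=self.physio.p_bs,
            hematocrit_in=self.physio.systemic_hematocrit,
            protein_conc_in=self.physio.afferent_protein_conc,
        )

    def solve(self, map_pressure: float, k: float, r_a: float,
              r_e: float) -> NetworkSolution:
        """One forward simulation at given parameters (reported units)."""
        return solve_network(
            self.network, self.boundary_conditions(map_pressure),
            k, r_a, r_e, self.options, self.coeffs,
        )

    def fit(self, targets: HemodynamicTargets, **kwargs) -> "ConditionFitResults":
        """Fit (R_A, R_E, k) to one condition's hemodynamic targets."""
        fitted = fit_condition(
            self.network, targets, physio=self.physio,
            options=self.options, coeffs=self.coeffs, **kwargs,
        )
        return ConditionFitResults(self, fitted)

    def fit_named_condition(self, name: str, **kwargs) -> "ConditionFitResults":
        """Fit one of the packaged study conditions by name (e.g. "Sham")."""
        from .fitting import packaged_conditions

        for t in packaged_conditions():
            if t.condition == name:
                return self.fit(t, **kwargs)
        raise KeyError(f"no packaged condition named {name!r}")


@dataclass
class ConditionFitResults:
    """Fitted parameters, diagnostics and converged state for one condition."""

    model: GlomerulusModel
    fitted: FittedCondition

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"r_a": self.fitted.r_a, "r_e": self.fitted.r_e, "k": self.fitted.k},
            name=self.fitted.targets.condition,
        )

    @property
    def solution(self) -> NetworkSolution:
        return self.fitted.solution

    def stress_report(self) -> StressReport:
        return build_stress_report(
            self.solution, self.model.network,
            condition=self.fitted.targets.condition,
        )

    def summary(self) -> str:
        t = self.fitted.targets
        s = self.solution
        e = self.fitted.relative_errors
        lines = [
            f"Condition fit: {t.condition}",
            "=" * 46,
            f"  MAP (input)              {t.map_pressure:10.1f} mmHg",
            f"  fitted R_A               {self.fitted.r_a:10.4f} mmHg·min/nL",
            f"  fitted R_E               {self.fitted.r_e:10.4f} mmHg·min/nL",
            f"  fitted k                 {self.fitted.k:10.3e} nL/min/mmHg/µm²",
            "-" * 46,
            "  quantity      target    achieved   rel.err",
            f"  P_GC   mmHg  {t.p_gc:8.1f} {s.p_gc:10.2f} {e['p_gc']:9.2e}",
            f"  Q_A  nL/min  {t.q_a:8.1f} {s.q_a_plasma:10.2f} {e['q_a']:9.2e}",
            f"  SNGFR nL/min {t.sngfr:8.1f} {s.sngfr:10.2f} {e['sngfr']:9.2e}",
            "-" * 46,
            f"  outer passes {self.fitted.passes}; solver iterations "
            f"{s.iterations}; segments clamped "
            f"{int(s.segments['clamped'].sum())}/{len(s.segments)}",
            f"  hematocrit_in={s.bc.hematocrit_in}, "
            f"protein_in={s.bc.protein_conc_in} g/dL (conventions, not data)",
        ]
        return "\n".join(lines)
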