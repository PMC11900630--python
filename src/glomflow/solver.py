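"""Coupled network solver: node pressures, hematocrit/protein transport,
and the fixed-point iteration over filtration resistance and viscosity.

Each capillary's closed-form leaky-vessel solution makes its two end flows
linear in the end pressures, so conservation of blood volume at every node
(sum of segment flows = 0, boundary resistors included) is a symmetric
linear system in the node pressures.  Around that linear solve runs a
fixed-point loop: solve pressures -> propagate erythrocytes and plasma
protein through the solved flow field -> update each segment's apparent
viscosity and filtration resistance -> repeat until both converge.

All arithmetic inside the loop is in the (µg, s, µm) working units; the
returned :class:`NetworkSolution` is in reported units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import rheology
from .mechanics import (
    FlowProfile,
    SegmentProfile,
    excess_pressure_integral,
    solve_pressure_profile,
    _GX, _GW,
)
from .network import BoundaryConditions, GlomerularNetwork
from .rheology import RheologyCoefficients, DEFAULT_COEFFS
from .units import to_working, from_working

__all__ = [
    "SolverOptions",
    "ConvergenceError",
    "NetworkSolution",
    "assemble_and_solve_node_pressures",
    "solve_network",
    "compute_pgc",
    "fit_hydraulic_conductivity",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries residual history."""

    def __init__(self, message: str, history: list[tuple[float, float]]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class SolverOptions:
    """Numerical options of the fixed-point solver.

    tol
        Convergence threshold on the max relative change of both the
        per-segment filtration resistance and viscosity.
    max_iter
        Iteration cap; exceeding it raises :class:`ConvergenceError`.
    relaxation
        Under-relaxation factor blended in automatically when the
        residual sequence oscillates.
    r_f_max
        Clamp (reported units, mmHg·min/nL) marking a segment as
        effectively non-filtering when its net filtration pressure
        integral is non-positive.
    pgc_mode
        Averaging convention for the mean capillary pressure:
        ``length`` (length-weighted, default), ``segment`` (unweighted
        mean of segment means) or ``flow`` (inflow-weighted).
    afferent_diameter
        Feeding-vessel diameter (µm) used by the phase-separation law at
        the entry node, where the feeding vessel is the afferent
        arteriole rather than a capillary.
    """

    tol: float = 1e-6
    max_iter: int = 400
    relaxation: float = 0.5
    r_f_max: float = 1e9
    pgc_mode: str = "length"
    afferent_diameter: float = 20.0
    max_hematocrit: float = 0.95
    max_protein: float = 20.0


# ---------------------------------------------------------------------------
# compiled (dense-indexed) network
# ---------------------------------------------------------------------------

class _Compiled:
    """Array view of a network: label-free dense indexing for the solver."""

    def __init__(self, network: GlomerularNetwork):
        self.node_ids = [n.node_id for n in network.nodes]
        self.index = {nid: i for i, nid in enumerate(self.node_ids)}
        self.entry = self.index[network.aa_entry]
        self.exit = self.index[network.ea_exit]
        segs = network.segments
        self.seg_ids = [s.segment_id for s in segs]
        self.u = np.array([self.index[s.from_node] for s in segs])
        self.v = np.array([self.index[s.to_node] for s in segs])
        self.length = np.array([s.length for s in segs])
        self.diameter = np.array([s.diameter for s in segs])
        self.wall = np.array([s.wall_thickness for s in segs])
        self.n_nodes = len(self.node_ids)
        self.n_segs = len(segs)


# ---------------------------------------------------------------------------
# vectorised hyperbolic helpers (per-row a; mirror mechanics._phi/_psi)
# ---------------------------------------------------------------------------

def _coefficients(a: np.ndarray, length: np.ndarray, resistance: np.ndarray):
    """End-flow coefficients (c_self, c_other) of every segment.

    Flow out of node u into segment uv is
    ``c_self*(p_u − p_BS) − c_other*(p_v − p_BS)`` (symmetrically at v);
    for a = 0 both collapse to 1/R.
    """
    al = a * length
    small = al < 1e-8
    als = np.where(small, 1.0, al)
    with np.errstate(over="ignore"):
        c_self = np.where(small, 1.0, als / np.tanh(np.minimum(als, 30.0)))
        c_other = np.where(small, 1.0, als / np.sinh(np.minimum(als, 30.0)))
    # beyond al=30, coth -> 1 and 1/sinh -> 0 to double precision
    big = al > 30.0
    c_self = np.where(big, al, c_self)
    c_other = np.where(big, 2.0 * al * np.exp(-al.clip(max=700)), c_other)
    return c_self / resistance, c_other / resistance


def _cumulative_excess(pi_: np.ndarray, pj_: np.ndarray, a: np.ndarray,
                       length: np.ndarray, x: np.ndarray) -> np.ndarray:
    """S(x) = ∫₀ˣ(p−p_BS) for all segments at once; x has shape (n, m)."""
    al = (a * length)[:, None]
    ax = a[:, None] * x
    alx = a[:, None] * (length[:, None] - x)
    small = al < 1e-8
    med = (~small) & (al <= 20.0)
    out = np.empty_like(x)
    # small-a: S(x) = pi*(x - x²/(2L)) + pj*x²/(2L)
    l2 = length[:, None]
    out_small = pi_[:, None] * (x - x * x / (2 * l2)) + pj_[:, None] * x * x / (2 * l2)
    with np.errstate(over="ignore", invalid="ignore"):
        sinh_al = np.sinh(np.minimum(al, 25.0))
        psi_x = (np.cosh(np.minimum(ax, 25.0)) - 1.0) / (a[:, None] * sinh_al)
        psi_lx = (np.cosh(np.minimum(alx, 25.0)) - 1.0) / (a[:, None] * sinh_al)
        psi_l = (np.cosh(np.minimum(al, 25.0)) - 1.0) / (a[:, None] * sinh_al)
        out_med = pi_[:, None] * (psi_l - psi_lx) + pj_[:, None] * psi_x
    big = al > 20.0
    if np.any(big):
        # exp-scaled form, exact to double precision for large aL
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            e = np.exp
            a_safe = np.where(a[:, None] == 0.0, 1.0, a[:, None])
            denom = a_safe * (1.0 - e(-2.0 * al.clip(max=700)))
            denom = np.where(denom == 0.0, 1.0, denom)
            psi_x_b = (e(-alx.clip(max=700)) * (1.0 + e(-2.0 * ax.clip(max=700)))
                       - 2.0 * e(-al.clip(max=700))) / denom
            psi_lx_b = (e(-ax.clip(max=700)) * (1.0 + e(-2.0 * alx.clip(max=700)))
                        - 2.0 * e(-al.clip(max=700))) / denom
            psi_l_b = (1.0 + e(-2.0 * al.clip(max=700))
                       - 2.0 * e(-al.clip(max=700))) / denom
            out_big = pi_[:, None] * (psi_l_b - psi_lx_b) + pj_[:, None] * psi_x_b
    else:
        out_big = out_med
    out = np.where(small, out_small, np.where(med, out_med, out_big))
    return out


def _excess_integral(pi_: np.ndarray, pj_: np.ndarray, a: np.ndarray,
                     length: np.ndarray) -> np.ndarray:
    """∫₀ᴸ(p−p_BS)dx = (pi+pj)·tanh(aL/2)/a, vectorised."""
    al = a * length
    small = al < 1e-8
    als = np.where(small, 1.0, a)
    w = np.where(small, length / 2.0, np.tanh(al / 2.0) / als)
    return (pi_ + pj_) * w


# ---------------------------------------------------------------------------
# linear node-pressure solve
# ---------------------------------------------------------------------------

def _solve_pressures(comp: _Compiled, c_self, c_other, p_map, r_a, r_e,
                     p_down, p_bs):
    n = comp.n_nodes
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    np.add.at(A, (comp.u, comp.u), c_self)
    np.add.at(A, (comp.v, comp.v), c_self)
    np.add.at(A, (comp.u, comp.v), -c_other)
    np.add.at(A, (comp.v, comp.u), -c_other)
    leak = c_self - c_other
    np.add.at(rhs, comp.u, leak * p_bs)
    np.add.at(rhs, comp.v, leak * p_bs)
    A[comp.entry, comp.entry] += 1.0 / r_a
    rhs[comp.entry] += p_map / r_a
    A[comp.exit, comp.exit] += 1.0 / r_e
    rhs[comp.exit] += p_down / r_e
    try:
        return np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular node-conservation system (disconnected network?)"
        ) from exc


def assemble_and_solve_node_pressures(
    network: GlomerularNetwork,
    a: np.ndarray,
    resistance: np.ndarray,
    map_pressure: float,
    r_a: float,
    r_e: float,
    p_downstream: float,
    p_bs: float,
) -> dict[str, float]:
    """Solve the node-conservation linear system for given per-segment a, R.

    All quantities in reported units (mmHg, mmHg·min/nL, 1/µm); segment
    order follows ``network.segments``.  Returns node-id -> pressure.
    """
    comp = _Compiled(network)
    a = np.asarray(a, dtype=float)
    resistance = np.asarray(resistance, dtype=float)
    if np.any(resistance <= 0):
        raise ValueError("segment resistances must be positive")
    c_self, c_other = _coefficients(a, comp.length, resistance)
    p = _solve_pressures(comp, c_self, c_other, map_pressure, r_a, r_e,
                         p_downstream, p_bs)
    return dict(zip(comp.node_ids, p))


# ---------------------------------------------------------------------------
# solution container
# ---------------------------------------------------------------------------

@dataclass
class NetworkSolution:
    """Converged state of one forward solve, in reported units.

    Attributes
    ----------
    node_pressures : pandas.Series
        mmHg, indexed by node id.
    segments : pandas.DataFrame
        Per-segment converged state: upstream/downstream node (solved flow
        direction), inflow/outflow (nL/min blood), CSGFR (nL/min),
        filtration resistance (mmHg·min/nL), viscosity (cP), inlet
        hematocrit and protein concentration, mean pressure (mmHg),
        leakage coefficient (1/µm) and the non-filtering clamp flag.
    sngfr, q_a_plasma, q_a_blood, q_e_plasma, p_gc
        Whole-glomerulus summaries (nL/min, mmHg).
    """

    node_pressures: pd.Series
    segments: pd.DataFrame
    sngfr: float
    q_a_plasma: float
    q_a_blood: float
    q_e_plasma: float
    q_e_blood: float
    p_gc: float
    k: float
    r_a: float
    r_e: float
    bc: BoundaryConditions
    iterations: int
    residual_history: list[tuple[float, float]]
    warnings: list[str] = field(default_factory=list)

    def segment_profile(self, segment_id: str) -> tuple[SegmentProfile, FlowProfile]:
        """Rebuild the closed-form pressure and flow profile of one segment.

        Profiles are in reported units, oriented along the solved flow
        direction (x = 0 at the upstream end).
        """
        row = self.segments.set_index("segment_id").loc[segment_id]
        prof = solve_pressure_profile(
            float(self.node_pressures[row["upstream"]]),
            float(self.node_pressures[row["downstream"]]),
            float(row["a_per_um"]),
            float(row["length_um"]),
            self.bc.p_bs,
        )
        return prof, FlowProfile(prof, float(row["r_f"]), float(row["q_in"]))

    def conservation_report(self) -> dict[str, float]:
        """Max relative conservation residuals of the converged state."""
        seg = self.segments
        inflow: dict[str, float] = {}
        outflow: dict[str, float] = {}
        for _, r in seg.iterrows():
            outflow[r["upstream"]] = outflow.get(r["upstream"], 0.0) + r["q_in"]
            inflow[r["downstream"]] = inflow.get(r["downstream"], 0.0) + r["q_out"]
        scale = max(self.q_a_blood, 1e-30)
        worst = 0.0
        for nid in self.node_pressures.index:
            fin = inflow.get(nid, 0.0)
            fout = outflow.get(nid, 0.0)
            if nid == self._entry_id:
                fin += self.q_a_blood
            if nid == self._exit_id:
                fout += self.q_e_blood
            worst = max(worst, abs(fin - fout) / scale)
        rbc_in = self.q_a_blood * self.bc.hematocrit_in
        rbc_out = sum(r["q_out"] * r["h_out"] for _, r in seg.iterrows()
                      if r["downstream"] == self._exit_id)
        protein_in = self.q_a_plasma * self.bc.protein_conc_in
        protein_out = sum(
            (r["q_out"] * (1 - r["h_out"])) * r["c_out"]
            for _, r in seg.iterrows() if r["downstream"] == self._exit_id
        )
        return {
            "node_blood": worst,
            "rbc": abs(rbc_in - rbc_out) / max(rbc_in, 1e-30),
            "protein": abs(protein_in - protein_out) / max(protein_in, 1e-30),
            "sngfr_vs_plasma": abs(
                (self.q_a_plasma - self.q_e_plasma) - self.sngfr
            ) / max(self.sngfr, 1e-30),
        }

    _entry_id: str = ""
    _exit_id: str = ""


# ---------------------------------------------------------------------------
# the fixed-point loop
# ---------------------------------------------------------------------------

def solve_network(
    network: GlomerularNetwork,
    bc: BoundaryConditions,
    k: float,
    r_a: float | None = None,
    r_e: float | None = None,
    options: SolverOptions | None = None,
    coeffs: RheologyCoefficients = DEFAULT_COEFFS,
    init_state: dict | None = None,
    _fallback: int = 0,
) -> NetworkSolution:
    """Run the fixed-point iteration to a converged network state.

    Parameters in reported units: ``k`` in nL/min/mmHg/µm², resistances in
    mmHg·min/nL (default to the values stored on the network).
    ``init_state`` optionally warm-starts the loop from a previous
    converged state (used by the fitting loops); the converged answer is
    the same fixed point either way.
    """
    opts = options or SolverOptions()
    r_a = network.r_a if r_a is None else r_a
    r_e = network.r_e if r_e is None else r_e
    if r_a <= 0 or r_e <= 0:
        raise ValueError("boundary resistances must be positive for a solve")
    if k <= 0:
        raise ValueError("hydraulic conductivity must be positive")

    comp = _Compiled(network)
    ns, nn = comp.n_segs, comp.n_nodes

    # working-unit boundary values
    p_map = to_working(bc.map_pressure, "pressure")
    p_bs = to_working(bc.p_bs, "pressure")
    p_down = to_working(bc.p_downstream, "pressure")
    r_a_w = to_working(r_a, "resistance")
    r_e_w = to_working(r_e, "resistance")
    k_w = to_working(k, "hydraulic_conductivity")
    r_f_max_w = to_working(opts.r_f_max, "resistance")

    h_in, c_in = bc.hematocrit_in, bc.protein_conc_in

    if init_state is None:
        mu = np.asarray(
            rheology.apparent_viscosity(comp.diameter, h_in, c_in, coeffs),
            dtype=float,
        )
        g = np.zeros(ns)  # filtration conductance 1/R_f; first pass impermeable
        h_up = np.full(ns, h_in)
        c_up = np.full(ns, c_in)
    else:
        mu = init_state["mu"].copy()
        g = init_state["g"].copy()
        h_up = init_state["h_up"].copy()
        c_up = init_state["c_up"].copy()

    # per-segment conductance scale: g = k·π·L·D at zero oncotic pressure
    g_cap = k_w * math.pi * comp.length * comp.diameter
    g_min = 1.0 / r_f_max_w

    gauss_x = 0.5 * (_GX + 1.0)          # (m,) on [0,1]
    gauss_w = 0.5 * _GW
    from collections import deque

    warnings: list[str] = []
    history: list[tuple[float, float]] = []
    best_val = math.inf
    best_it = 0
    recent: deque = deque(maxlen=16)
    stalled = False
    converged = False
    relax = 1.0
    oncotic = coeffs.oncotic
    press_factor = to_working(1.0, "pressure")

    p = None
    for it in range(1, opts.max_iter + 1):
        resistance = 128.0 * mu * comp.length / (math.pi * comp.diameter**4)
        a = np.sqrt(resistance * g) / comp.length
        c_self, c_other = _coefficients(a, comp.length, resistance)
        p = _solve_pressures(comp, c_self, c_other, p_map, r_a_w, r_e_w,
                             p_down, p_bs)

        # end flows: out of u / out of v
        pu = p[comp.u] - p_bs
        pv = p[comp.v] - p_bs
        q_out_u = c_self * pu - c_other * pv
        q_out_v = c_self * pv - c_other * pu
        forward = q_out_u >= q_out_v  # True: flow u -> v
        up_node = np.where(forward, comp.u, comp.v)
        dn_node = np.where(forward, comp.v, comp.u)
        q_up = np.where(forward, q_out_u, q_out_v)
        q_dn = np.where(forward, -q_out_v, -q_out_u)
        q_up = np.maximum(q_up, 1e-30)
        q_dn_pos = np.maximum(q_dn, 1e-12 * q_up)

        # -- transport pass (Gauss-Seidel in topological order) -------------
        h_dn = np.clip(h_up * q_up / q_dn_pos, 0.0, opts.max_hematocrit)
        qp_up = q_up * (1.0 - h_up)
        qp_dn = np.maximum(q_dn_pos - q_up * h_up, 1e-12 * qp_up)
        c_dn = np.minimum(c_up * qp_up / qp_dn, opts.max_protein)

        h_prev, c_prev = h_up.copy(), c_up.copy()
        order = _node_order(comp, up_node, dn_node, p)
        in_segs: list[list[int]] = [[] for _ in range(nn)]
        out_segs: list[list[int]] = [[] for _ in range(nn)]
        for s in range(ns):
            out_segs[up_node[s]].append(s)
            in_segs[dn_node[s]].append(s)

        q_entry = (p_map - p[comp.entry]) / r_a_w
        for node in order:
            flows, hs, cs, ds = [], [], [], []
            if node == comp.entry:
                flows.append(q_entry)
                hs.append(h_in)
                cs.append(c_in)
                ds.append(opts.afferent_diameter)
            for s in in_segs[node]:
                flows.append(q_dn_pos[s])
                hs.append(h_dn[s])
                cs.append(c_dn[s])
                ds.append(comp.diameter[s])
            if not flows:
                continue  # unreachable in a valid solve; keep previous state
            flows = np.asarray(flows)
            hs = np.asarray(hs)
            cs = np.asarray(cs)
            q_tot = flows.sum()
            h_node = float(np.dot(flows, hs) / q_tot)
            qp = flows * (1.0 - hs)
            c_node = float(np.dot(qp, cs) / qp.sum())
            d_feed = float(np.dot(flows, ds) / q_tot)

            outs = out_segs[node]
            if len(outs) == 1:
                s = outs[0]
                h_up[s] = h_node
                c_up[s] = c_node
            elif len(outs) > 1:
                q_outs = q_up[list(outs)]
                fr = q_outs / q_outs.sum()
                daughters = [(float(fr[i]), float(comp.diameter[outs[i]]))
                             for i in range(len(outs))]
                try:
                    hsplit = rheology.split_erythrocytes(
                        rheology.BloodState(min(h_node, 0.949), c_node),
                        1.0, daughters, parent_diameter=d_feed,
                        coeffs=coeffs, max_hematocrit=opts.max_hematocrit,
                    )
                except ValueError:
                    hsplit = [h_node] * len(outs)
                for i, s in enumerate(outs):
                    h_up[s] = hsplit[i]
                    c_up[s] = c_node
            # update downstream-end states for segments fed by this node
            for s in outs:
                h_dn[s] = min(h_up[s] * q_up[s] / q_dn_pos[s], opts.max_hematocrit)
                qpu = q_up[s] * (1.0 - h_up[s])
                qpd = max(q_dn_pos[s] - q_up[s] * h_up[s], 1e-12 * qpu)
                c_dn[s] = min(c_up[s] * qpu / qpd, opts.max_protein)

        # -- constitutive updates -------------------------------------------
        p_up = p[up_node] - p_bs
        p_dn = p[dn_node] - p_bs
        x = comp.length[:, None] * gauss_x[None, :]
        s_x = _cumulative_excess(p_up, p_dn, a, comp.length, x)
        q_x = q_up[:, None] - s_x * (g / comp.length)[:, None]
        q_rbc = q_up * h_up
        qp_x = q_x - q_rbc[:, None]
        qp_in = (q_up * (1.0 - h_up))[:, None]
        qp_x = np.maximum(qp_x, 1e-6 * qp_in)
        c_x = np.minimum(c_up[:, None] * qp_in / qp_x, opts.max_protein)
        a1, a2, a3 = oncotic
        pi_x = press_factor * c_x * (a1 + c_x * (a2 + c_x * a3))
        pi_int = comp.length * (pi_x @ gauss_w)

        numerator = _excess_integral(p_up, p_dn, a, comp.length)
        # conductance update: g = g_cap·(1 − ∫Π/∫(p−p_BS)); smooth and
        # bounded, so near-equilibrium segments cannot blow the iteration up
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(numerator > 0.0, pi_int / numerator, np.inf)
        g_new = np.clip(g_cap * (1.0 - frac), g_min, g_cap)
        clamped = g_new <= g_min * (1.0 + 1e-9)

        h_mean = 0.5 * (h_up + h_dn)
        c_mean = 0.5 * (c_up + c_dn)
        mu_new = np.asarray(
            rheology.apparent_viscosity(comp.diameter, h_mean, c_mean, coeffs),
            dtype=float,
        )

        res_g = float(np.max(np.abs(g_new - g) / g_cap))
        res_mu = float(np.max(np.abs(mu_new - mu) / mu_new))
        history.append((res_g, res_mu))

        # under-relax the conductance update; deepen the damping when the
        # residual sequence rises (oncotic feedback near filtration
        # equilibrium otherwise limit-cycles), let it recover when it falls
        if len(history) >= 2 and history[-1][0] > history[-2][0]:
            relax = max(relax * 0.7, 0.05)
        elif len(history) >= 2:
            relax = min(relax * 1.1, 1.0)
        if it > 1:
            w = min(relax, opts.relaxation)
            g = w * g_new + (1.0 - w) * g
            mu = w * mu_new + (1.0 - w) * mu
            # damp the transported composition too: bifurcation routing can
            # otherwise flip-flop across the plasma-skimming threshold
            h_up = w * h_up + (1.0 - w) * h_prev
            c_up = w * c_up + (1.0 - w) * c_prev
        else:
            g = g_new
            mu = mu_new

        if max(res_g, res_mu) < best_val:
            best_val = max(res_g, res_mu)
            best_it = it
        recent.append((g.copy(), mu.copy(), h_up.copy(), c_up.copy()))

        if res_g < opts.tol and res_mu < opts.tol:
            converged = True
            break
        if best_val < 0.5 and it - best_it > 60:
            # residual plateau: a shallow limit cycle of the discrete
            # routing map; go heavy (level 0) or accept the average
            stalled = _fallback >= 1
            break

    if not converged and not stalled:
        import dataclasses as _dc

        if _fallback == 0:
            # stiff cases (extreme probes near plasma exhaustion) converge
            # under heavy constant damping; retry deterministically
            heavy = _dc.replace(opts, relaxation=0.1,
                                max_iter=opts.max_iter)
            return solve_network(network, bc, k, r_a, r_e, heavy, coeffs,
                                 init_state=init_state, _fallback=1)
        if best_val < 0.5:
            stalled = True
        else:
            raise ConvergenceError(
                f"no convergence in {opts.max_iter} iterations "
                f"(last residuals g={history[-1][0]:.2e}, "
                f"mu={history[-1][1]:.2e}; best combined {best_val:.2e})",
                history,
            )

    if stalled:
        # discrete erythrocyte-routing toggles (phase separation near its
        # plasma-skimming threshold coupled to viscosity) admit no exact
        # fixed point: accept the limit cycle's mean state, assembled via
        # one consistent pressure/transport pass
        import dataclasses as _dc

        avg_state = {
            "g": np.mean([r[0] for r in recent], axis=0),
            "mu": np.mean([r[1] for r in recent], axis=0),
            "h_up": np.mean([r[2] for r in recent], axis=0),
            "c_up": np.mean([r[3] for r in recent], axis=0),
        }
        once = _dc.replace(opts, tol=math.inf, max_iter=1)
        sol = solve_network(network, bc, k, r_a, r_e, once, coeffs,
                            init_state=avg_state, _fallback=2)
        sol.warnings.append(
            f"routing limit cycle: accepted cycle-averaged state "
            f"(best residual {best_val:.2e}, tol {opts.tol:.0e})"
        )
        return sol

    if np.all(clamped):
        warnings.append("all segments clamped non-filtering; SNGFR = 0")
    elif np.any(clamped):
        warnings.append(f"{int(clamped.sum())} segment(s) clamped non-filtering")

    r_f = 1.0 / np.maximum(g, g_min)

    # -- assemble reported-unit solution ------------------------------------
    # CSGFR from the solved end flows: exactly consistent with node
    # conservation, so SNGFR = sum(CSGFR) = blood in - blood out telescopes.
    csgfr_w = q_up - q_dn
    sngfr_w = float(csgfr_w.sum())
    q_a_blood_w = float((p_map - p[comp.entry]) / r_a_w)
    q_e_blood_w = float((p[comp.exit] - p_down) / r_e_w)

    mean_p = p_bs + numerator / comp.length
    if opts.pgc_mode == "length":
        p_gc_w = float(np.dot(comp.length, mean_p) / comp.length.sum())
    elif opts.pgc_mode == "segment":
        p_gc_w = float(np.mean(mean_p))
    elif opts.pgc_mode == "flow":
        p_gc_w = float(np.dot(q_up, mean_p) / q_up.sum())
    else:
        raise ValueError(f"unknown pgc_mode {opts.pgc_mode!r}")

    flow_f = to_working(1.0, "flow")
    node_press = pd.Series(
        from_working(p, "pressure"), index=comp.node_ids, name="pressure_mmHg"
    )
    segments = pd.DataFrame(
        {
            "segment_id": comp.seg_ids,
            "upstream": [comp.node_ids[i] for i in up_node],
            "downstream": [comp.node_ids[i] for i in dn_node],
            "length_um": comp.length,
            "diameter_um": comp.diameter,
            "wall_thickness_um": comp.wall,
            "q_in": q_up / flow_f,
            "q_out": (q_up - csgfr_w) / flow_f,
            "csgfr": csgfr_w / flow_f,
            "r_f": from_working(r_f, "resistance"),
            "mu_cp": mu,
            "h_in": h_up,
            "h_out": h_dn,
            "c_in": c_up,
            "c_out": c_dn,
            "mean_pressure_mmHg": from_working(mean_p, "pressure"),
            "a_per_um": a,
            "clamped": clamped,
        }
    )

    at_exit = dn_node == comp.exit
    rbc_exit = float(np.sum(q_dn_pos[at_exit] * h_dn[at_exit]))
    q_exit_blood = float(np.sum(q_dn_pos[at_exit]))
    h_exit = rbc_exit / max(q_exit_blood, 1e-30)
    q_e_plasma_w = q_e_blood_w * (1.0 - h_exit)

    sol = NetworkSolution(
        node_pressures=node_press,
        segments=segments,
        sngfr=sngfr_w / flow_f,
        q_a_plasma=q_a_blood_w * (1.0 - h_in) / flow_f,
        q_a_blood=q_a_blood_w / flow_f,
        q_e_plasma=q_e_plasma_w / flow_f,
        q_e_blood=q_e_blood_w / flow_f,
        p_gc=from_working(p_gc_w, "pressure"),
        k=k,
        r_a=r_a,
        r_e=r_e,
        bc=bc,
        iterations=it,
        residual_history=history,
        warnings=warnings,
    )
    sol._entry_id = comp.node_ids[comp.entry]
    sol._exit_id = comp.node_ids[comp.exit]
    sol._state = {"mu": mu.copy(), "g": g.copy(),
                  "h_up": h_up.copy(), "c_up": c_up.copy()}
    return sol


def _node_order(comp: _Compiled, up_node, dn_node, p) -> list[int]:
    """Topological order of the solved flow digraph, or pressure-descending
    order if the flow field contains a cycle."""
    g = nx.DiGraph()
    g.add_nodes_from(range(comp.n_nodes))
    g.add_edges_from(zip(up_node.tolist(), dn_node.tolist()))
    try:
        return list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        return list(np.argsort(-p))


def compute_pgc(solution: NetworkSolution, mode: str = "length") -> float:
    """Mean glomerular capillary pressure under a chosen averaging mode."""
    seg = solution.segments
    if mode == "length":
        w = seg["length_um"].to_numpy()
    elif mode == "segment":
        w = np.ones(len(seg))
    elif mode == "flow":
        w = seg["q_in"].to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.dot(w, seg["mean_pressure_mmHg"]) / w.sum())


def fit_hydraulic_conductivity(
    network: GlomerularNetwork,
    bc: BoundaryConditions,
    target_sngfr: float,
    r_a: float | None = None,
    r_e: float | None = None,
    bounds: tuple[float, float] = (1e-8, 1e-3),
    options: SolverOptions | None = None,
    coeffs: RheologyCoefficients = DEFAULT_COEFFS,
    xtol_log10: float = 1e-7,
) -> float:
    """Fit k (nL/min/mmHg/µm²) so the converged SNGFR matches the target.

    SNGFR is nondecreasing in k, so a bracketing scalar search on log10(k)
    is valid.  Raises if the target exceeds the SNGFR attainable at the
    upper bound (filtration-pressure limited).
    """
    from scipy.optimize import brentq

    if target_sngfr <= 0:
        raise ValueError("target SNGFR must be positive; 0 means no filtration")
    lo, hi = bounds

    def sngfr_at(log10k: float) -> float:
        # cold start each evaluation: keeps every probe on the same
        # deterministic solution branch as the final verification solve
        sol = solve_network(network, bc, 10.0**log10k, r_a, r_e,
                            options, coeffs)
        return sol.sngfr

    # expand the upper bracket only as far as the target requires: very
    # large k drives most of the bed to filtration equilibrium, a stiff
    # and physiologically irrelevant regime
    k_hi = min(1e-4, hi)
    f_hi = sngfr_at(math.log10(k_hi)) - target_sngfr
    while f_hi < 0 and k_hi < hi:
        k_hi = min(4.0 * k_hi, hi)
        f_hi = sngfr_at(math.log10(k_hi)) - target_sngfr
    if f_hi < 0:
        raise ValueError(
            f"target SNGFR {target_sngfr} unattainable: max attainable at "
            f"k={k_hi} is {f_hi + target_sngfr:.4g} nL/min"
        )
    f_lo = sngfr_at(math.log10(lo)) - target_sngfr
    if f_lo > 0:
        raise ValueError(f"target SNGFR {target_sngfr} below the k lower bound")
    log10k = brentq(lambda z: sngfr_at(z) - target_sngfr,
                    math.log10(lo), math.log10(k_hi), xtol=xtol_log10)
    return float(10.0**log10k)
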