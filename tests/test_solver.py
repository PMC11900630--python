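"""Network solver: linear node-pressure assembly, the fixed-point loop,
conservation, limits, and equivalence with a monolithic simultaneous solve
of all coupled equations on tiny networks.

The monolithic oracle works entirely in reported units (mmHg, nL/min,
mmHg·min/nL) with its own cosh/sinh formulas and adaptive quadrature, so
it shares no code path with the solver's working-unit vectorised loop.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import fsolve

import glomflow.rheology as rheology
from glomflow.mechanics import poiseuille_resistance
from glomflow.network import BoundaryConditions
from glomflow.solver import (
    NetworkSolution,
    SolverOptions,
    assemble_and_solve_node_pressures,
    compute_pgc,
    fit_hydraulic_conductivity,
    solve_network,
)

from conftest import make_network

P_BS = 14.0
P_DOWN = 15.0


# ---------------------------------------------------------------------------
# independent segment formulas (reported units)
# ---------------------------------------------------------------------------

def _end_flows(p_i, p_j, a, length, resistance, p_bs=P_BS):
    """(flow out of node i, flow out of node j) from the closed form."""
    pi_, pj_ = p_i - p_bs, p_j - p_bs
    al = a * length
    if al < 1e-12:
        q = (p_i - p_j) / resistance
        return q, -q
    coth, csch = 1 / math.tanh(al), 1 / math.sinh(al)
    qi = (length * a / resistance) * (pi_ * coth - pj_ * csch)
    qj = (length * a / resistance) * (pj_ * coth - pi_ * csch)
    return qi, qj


def _pressure_at(x, p_i, p_j, a, length, p_bs=P_BS):
    if a * length < 1e-12:
        return p_i + (p_j - p_i) * x / length
    s = math.sinh(a * length)
    return (p_bs + (p_i - p_bs) * math.sinh(a * (length - x)) / s
            + (p_j - p_bs) * math.sinh(a * x) / s)


class TestLinearAssembly:
    def test_single_segment_voltage_divider(self):
        net = make_network([("s0", "AA", "EA", 50.0, 8.0, 0.2)])
        r = 0.4
        p = assemble_and_solve_node_pressures(
            net, np.array([0.0]), np.array([r]),
            map_pressure=100.0, r_a=0.4, r_e=0.4,
            p_downstream=P_DOWN, p_bs=P_BS,
        )
        # hand-solved series circuit: I = (MAP − p_down)/(3R)
        current = (100.0 - P_DOWN) / (3 * 0.4)
        assert p["AA"] == pytest.approx(100.0 - 0.4 * current, rel=1e-12)
        assert p["EA"] == pytest.approx(P_DOWN + 0.4 * current, rel=1e-12)

    def test_no_leak_network_conserves_total_flow(self, diamond_network):
        n = diamond_network.n_segments
        resist = np.full(n, 0.2)
        p = assemble_and_solve_node_pressures(
            diamond_network, np.zeros(n), resist, 100.0, 0.5, 0.3, P_DOWN, P_BS
        )
        q_in = (100.0 - p["AA"]) / 0.5
        q_out = (p["EA"] - P_DOWN) / 0.3
        assert q_in == pytest.approx(q_out, rel=1e-12)

    # fsolve warns about its slow tail at xtol=1e-13; the returned root is
    # verified against the residuals directly below
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_five_segment_toy_against_generic_root_finder(self):
        net = make_network(
            [
                ("s0", "AA", "a", 50.0, 9.0, 0.2),
                ("s1", "a", "b1", 60.0, 7.0, 0.2),
                ("s2", "a", "b2", 45.0, 8.0, 0.2),
                ("s3", "b1", "EA", 55.0, 7.5, 0.2),
                ("s4", "b2", "EA", 52.0, 8.5, 0.2),
            ]
        )
        a_arr = np.array([0.004, 0.006, 0.005, 0.0, 0.007])
        r_arr = np.array([0.2, 0.5, 0.3, 0.45, 0.25])
        sol = assemble_and_solve_node_pressures(
            net, a_arr, r_arr, 110.0, 0.6, 0.25, P_DOWN, P_BS
        )
        order = ["AA", "a", "b1", "b2", "EA"]
        segs = [("AA", "a", 0), ("a", "b1", 1), ("a", "b2", 2),
                ("b1", "EA", 3), ("b2", "EA", 4)]
        lengths = [50.0, 60.0, 45.0, 55.0, 52.0]

        def residuals(p_vec):
            p = dict(zip(order, p_vec))
            out = {n: 0.0 for n in order}
            for u, v, i in segs:
                qi, qj = _end_flows(p[u], p[v], a_arr[i], lengths[i], r_arr[i])
                out[u] += qi
                out[v] += qj
            out["AA"] -= (110.0 - p["AA"]) / 0.6
            out["EA"] += (p["EA"] - P_DOWN) / 0.25
            return [out[n] for n in order]

        p_ref = fsolve(residuals, np.array([90.0, 60.0, 45.0, 45.0, 30.0]),
                       xtol=1e-13)
        for n, p_val in zip(order, p_ref):
            assert sol[n] == pytest.approx(p_val, rel=1e-10)
        # node conservation residuals at the returned solution
        res = residuals([sol[n] for n in order])
        assert np.max(np.abs(res)) < 1e-10 * (110.0 - P_DOWN) / 0.6


# ---------------------------------------------------------------------------
# monolithic oracle for the full coupled problem
# ---------------------------------------------------------------------------

def _segment_state_residuals(p_i, p_j, r_f, mu, h_up, c_up, length, diameter,
                             k, q_in):
    """Residuals of the filtration-resistance and viscosity equations for
    one segment, all by quadrature in reported units.  Returns
    (rf_residual_rel, mu_residual_rel, q_out, h_dn, c_dn)."""
    r = poiseuille_resistance(mu, diameter, length)
    a = math.sqrt(r / (r_f * length**2))
    p_at = lambda x: _pressure_at(x, p_i, p_j, a, length)
    num, _ = quad(lambda x: p_at(x) - P_BS, 0, length, epsabs=1e-12)
    q_rbc = q_in * h_up
    qp_in = q_in * (1 - h_up)

    def c_at(x):
        loss, _ = quad(lambda u: (p_at(u) - P_BS) / (length * r_f), 0, x,
                       epsabs=1e-13)
        return c_up * qp_in / (q_in - loss - q_rbc)

    pi_int, _ = quad(lambda x: rheology.colloid_osmotic_pressure(c_at(x)),
                     0, length, epsabs=1e-10, limit=100)
    r_f_target = num / (k * math.pi * length * diameter * (num - pi_int))
    q_out = q_in - num / (length * r_f)
    h_dn = h_up * q_in / q_out
    c_dn = c_up * qp_in / (q_out - q_rbc)
    mu_target = rheology.apparent_viscosity(
        diameter, (h_up + h_dn) / 2, (c_up + c_dn) / 2
    )
    return ((r_f - r_f_target) / r_f_target, (mu - mu_target) / mu_target,
            q_out, h_dn, c_dn)


def _chain_residuals(z, net, bc, k, r_a, r_e):
    """Full coupled residual vector for the 3-segment chain (16 unknowns:
    4 pressures, then per segment r_f, mu, h_up, c_up)."""
    p = z[:4]
    r_f, mu, h_up, c_up = z[4:7], z[7:10], z[10:13], z[13:16]
    segs = net.segments
    res = []
    # node conservation with closed-form end flows
    q_entry = (bc.map_pressure - p[0]) / r_a
    q_prev = q_entry
    carry_h, carry_c = bc.hematocrit_in, bc.protein_conc_in
    transport = []
    q_ins = []
    for i, s in enumerate(segs):
        r = poiseuille_resistance(mu[i], s.diameter, s.length)
        a = math.sqrt(r / (r_f[i] * s.length**2))
        qi, qj = _end_flows(p[i], p[i + 1], a, s.length, r)
        res.append(q_prev - qi)              # inflow feeds this segment
        transport.append((h_up[i] - carry_h, c_up[i] - carry_c))
        rf_res, mu_res, q_out, h_dn, c_dn = _segment_state_residuals(
            p[i], p[i + 1], r_f[i], mu[i], h_up[i], c_up[i],
            s.length, s.diameter, k, qi,
        )
        q_ins.append(qi)
        res.extend([rf_res, mu_res])
        q_prev = q_out
        carry_h, carry_c = h_dn, c_dn
    res.append(q_prev - (p[3] - bc.p_downstream) / r_e)
    for th, tc in transport:
        res.extend([th, tc])
    return np.array(res)


class TestMonolithicOracle:
    def test_chain_matches_simultaneous_solve(self, chain_network):
        bc = BoundaryConditions(map_pressure=100.0)
        k, r_a, r_e = 2e-5, 0.5, 0.3
        sol = solve_network(chain_network, bc, k, r_a, r_e,
                            SolverOptions(tol=1e-12, max_iter=2000))
        seg = sol.segments.set_index("segment_id")
        order = ["AA", "n1", "n2", "EA"]
        z_impl = np.concatenate([
            [sol.node_pressures[n] for n in order],
            seg["r_f"].to_numpy(), seg["mu_cp"].to_numpy(),
            seg["h_in"].to_numpy(), seg["c_in"].to_numpy(),
        ])
        # (a) the converged state solves the independently coded system
        res = _chain_residuals(z_impl, chain_network, bc, k, r_a, r_e)
        flows = np.abs(res[:7])  # flow-balance entries, nL/min scale
        assert np.max(np.abs(res)) < 1e-6 * max(1.0, sol.q_a_blood)
        # (b) a generic root-finder from a perturbed start lands on the
        # same solution
        rng = np.random.default_rng(0)
        z0 = z_impl * (1 + 0.03 * rng.standard_normal(z_impl.size))
        z_ref = fsolve(
            lambda z: _chain_residuals(z, chain_network, bc, k, r_a, r_e),
            z0, xtol=1e-12, maxfev=4000,
        )
        assert np.max(np.abs(z_ref - z_impl) / np.abs(z_impl)) < 1e-6

    def test_diamond_symmetric_paths_identical(self, diamond_network):
        bc = BoundaryConditions(map_pressure=105.0)
        sol = solve_network(diamond_network, bc, 2e-5, 0.5, 0.3)
        seg = sol.segments.set_index("segment_id")
        for a_id, b_id in (("d1", "d2"), ("d3", "d4")):
            for col in ("q_in", "csgfr", "r_f", "mu_cp", "h_in", "c_in"):
                assert seg.loc[a_id, col] == pytest.approx(
                    seg.loc[b_id, col], rel=1e-9
                )


class TestFixedPointSolve:
    def test_conservation_on_generated_network(self, small_network):
        bc = BoundaryConditions(map_pressure=110.0)
        sol = solve_network(small_network, bc, 2e-5, 0.4, 0.2)
        rep = sol.conservation_report()
        assert rep["node_blood"] < 1e-8
        assert rep["rbc"] < 1e-8
        assert rep["protein"] < 1e-8
        assert rep["sngfr_vs_plasma"] < 1e-6
        # SNGFR equals the sum of per-segment filtration rates
        assert sol.sngfr == pytest.approx(sol.segments["csgfr"].sum(), rel=1e-12)

    def test_pressures_bounded_by_boundaries(self, small_network):
        bc = BoundaryConditions(map_pressure=110.0)
        sol = solve_network(small_network, bc, 2e-5, 0.4, 0.2)
        assert sol.node_pressures.max() < 110.0
        assert sol.node_pressures.min() > bc.p_downstream

    def test_vanishing_conductivity_limit(self, small_network):
        bc = BoundaryConditions(map_pressure=110.0)
        sol = solve_network(small_network, bc, 1e-12, 0.4, 0.2)
        assert sol.sngfr < 1e-4
        # pressures agree with the purely resistive (a = 0) linear solve
        # at the converged viscosities: no transmural leakage remains
        seg_order = [s.segment_id for s in small_network.segments]
        seg = sol.segments.set_index("segment_id").loc[seg_order]
        resist = np.array(
            [poiseuille_resistance(m, s.diameter, s.length)
             for m, s in zip(seg["mu_cp"], small_network.segments)]
        )
        p_ref = assemble_and_solve_node_pressures(
            small_network, np.zeros(small_network.n_segments), resist,
            110.0, 0.4, 0.2, bc.p_downstream, bc.p_bs,
        )
        for nid, p_val in p_ref.items():
            assert sol.node_pressures[nid] == pytest.approx(p_val, rel=1e-6)

    def test_determinism_bitwise(self, small_network):
        bc = BoundaryConditions(map_pressure=110.0)
        a = solve_network(small_network, bc, 2e-5, 0.4, 0.2)
        b = solve_network(small_network, bc, 2e-5, 0.4, 0.2)
        assert (a.node_pressures.to_numpy() == b.node_pressures.to_numpy()).all()
        pd.testing.assert_frame_equal(a.segments, b.segments, check_exact=True)

    def test_sngfr_monotone_in_k(self, small_network):
        bc = BoundaryConditions(map_pressure=110.0)
        vals = [solve_network(small_network, bc, k, 0.4, 0.2).sngfr
                for k in (5e-6, 1e-5, 2e-5, 4e-5)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_k_separability_from_pressure_and_flow(self, small_network):
        # doubling k barely moves P_GC and Q_A (the basis for fitting the
        # resistances separately from the conductivity)
        bc = BoundaryConditions(map_pressure=110.0)
        s1 = solve_network(small_network, bc, 2e-5, 0.4, 0.2)
        s2 = solve_network(small_network, bc, 4e-5, 0.4, 0.2)
        assert abs(s2.p_gc - s1.p_gc) / s1.p_gc < 0.02
        assert abs(s2.q_a_plasma - s1.q_a_plasma) / s1.q_a_plasma < 0.02


class TestConductivityFit:
    def test_recovers_known_conductivity(self, small_network):
        bc = BoundaryConditions(map_pressure=110.0)
        k_true = 2e-5
        target = solve_network(small_network, bc, k_true, 0.4, 0.2).sngfr
        k_fit = fit_hydraulic_conductivity(small_network, bc, target, 0.4, 0.2)
        assert k_fit == pytest.approx(k_true, rel=1e-3)

    def test_zero_target_rejected(self, small_network):
        bc = BoundaryConditions(map_pressure=110.0)
        with pytest.raises(ValueError):
            fit_hydraulic_conductivity(small_network, bc, 0.0, 0.4, 0.2)

    def test_unattainable_target_reports_maximum(self, small_network):
        bc = BoundaryConditions(map_pressure=110.0)
        with pytest.raises(ValueError, match="unattainable"):
            fit_hydraulic_conductivity(small_network, bc, 1e5, 0.4, 0.2)


class TestMeanCapillaryPressure:
    def _fake_solution(self, lengths, means, flows):
        seg = pd.DataFrame(
            {"length_um": lengths, "mean_pressure_mmHg": means, "q_in": flows}
        )
        return NetworkSolution(
            node_pressures=pd.Series(dtype=float), segments=seg,
            sngfr=0.0, q_a_plasma=0.0, q_a_blood=0.0, q_e_plasma=0.0,
            q_e_blood=0.0, p_gc=0.0, k=0.0, r_a=0.0, r_e=0.0,
            bc=None, iterations=0, residual_history=[],
        )

    def test_uniform_field(self):
        sol = self._fake_solution([10, 20, 30], [48.0, 48.0, 48.0], [1, 2, 3])
        for mode in ("length", "segment", "flow"):
            assert compute_pgc(sol, mode) == pytest.approx(48.0)

    def test_length_weighting(self):
        sol = self._fake_solution([50, 50], [50.0, 40.0], [1.0, 1.0])
        assert compute_pgc(sol, "length") == pytest.approx(45.0)
        sol2 = self._fake_solution([75, 25], [50.0, 40.0], [1.0, 1.0])
        assert compute_pgc(sol2, "length") == pytest.approx(47.5)

    def test_matches_profile_quadrature(self, chain_network):
        bc = BoundaryConditions(map_pressure=100.0)
        sol = solve_network(chain_network, bc, 2e-5, 0.5, 0.3)
        total, wsum = 0.0, 0.0
        for sid in sol.segments["segment_id"]:
            prof, _ = sol.segment_profile(sid)
            val, _ = quad(prof.pressure, 0, prof.length, epsabs=1e-10)
            total += val
            wsum += prof.length
        assert sol.p_gc == pytest.approx(total / wsum, rel=1e-9)
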