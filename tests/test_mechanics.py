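"""Single-segment closed forms: pressure profile, integrals, flow and
filtration-resistance updates, all against quadrature or hand arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from glomflow.mechanics import (
    concentration_profile,
    excess_pressure_integral,
    flow_profile,
    leakage_coefficient,
    poiseuille_resistance,
    solve_pressure_profile,
    update_filtration_resistance,
)

P_BS = 14.0


class TestPoiseuilleResistance:
    def test_fourth_power_diameter_scaling(self):
        r1 = poiseuille_resistance(3.0, 7.0, 50.0)
        assert poiseuille_resistance(3.0, 14.0, 50.0) == pytest.approx(r1 / 16)

    def test_linear_length_scaling(self):
        r1 = poiseuille_resistance(3.0, 7.0, 50.0)
        assert poiseuille_resistance(3.0, 7.0, 100.0) == pytest.approx(2 * r1)

    def test_hand_evaluation_in_si_units(self):
        # independent evaluation: SI throughout, then convert to
        # mmHg·min/nL (1 mmHg = 133.322 Pa, 1 nL/min = 1e-12/60 m^3/s)
        mu, d, length = 3e-3, 7e-6, 50e-6  # Pa·s, m, m
        r_si = 128 * mu * length / (math.pi * d**4)  # Pa·s/m^3
        r_expected = r_si * (1e-12 / 60) / 133.322
        assert poiseuille_resistance(3.0, 7.0, 50.0) == pytest.approx(
            r_expected, rel=1e-6
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_resistance(0.0, 7.0, 50.0)


class TestLeakageCoefficient:
    def test_forced_value(self):
        assert leakage_coefficient(4.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_impermeable_limit(self):
        assert leakage_coefficient(1.0, 1e12, 50.0) < 1e-6

    def test_consistency_with_poiseuille_form(self):
        # a^2 = R/(R_f L^2) must equal 128µ/(π D^4 R_f L) for the same
        # segment (both in working units)
        from glomflow.units import to_working

        mu, d, length, r_f = 3.0, 7.0, 50.0, 200.0  # r_f reported
        r = poiseuille_resistance(mu, d, length)
        a = leakage_coefficient(r, r_f, length)
        mu_w = to_working(mu, "viscosity")
        r_f_w = to_working(r_f, "resistance")
        a2 = 128 * mu_w / (math.pi * d**4 * r_f_w * length)
        assert a**2 == pytest.approx(a2, rel=1e-12)


class TestPressureProfile:
    def test_laplace_limit_is_linear(self):
        prof = solve_pressure_profile(50.0, 45.0, 0.0, 100.0, P_BS)
        x = np.linspace(0, 100, 11)
        assert prof.pressure(x) == pytest.approx(50.0 - 0.05 * x)

    def test_equilibrium_profile_constant(self):
        prof = solve_pressure_profile(P_BS, P_BS, 0.02, 80.0, P_BS)
        assert prof.pressure(np.linspace(0, 80, 9)) == pytest.approx(
            np.full(9, P_BS)
        )

    def test_finite_difference_residual(self):
        # d²p/dx² − a²(p − p_BS) = 0 on a 1000-point grid
        length, a = 100.0, 0.005  # aL = 0.5
        prof = solve_pressure_profile(50.0, 45.0, a, length, P_BS)
        x = np.linspace(0, length, 1000)
        p = prof.pressure(x)
        h = x[1] - x[0]
        d2 = (p[2:] - 2 * p[1:-1] + p[:-2]) / h**2
        residual = d2 - a**2 * (p[1:-1] - P_BS)
        scale = a**2 * np.max(np.abs(p - P_BS))
        assert np.max(np.abs(residual)) / scale < 1e-6

    def test_boundary_values_pinned(self):
        prof = solve_pressure_profile(52.0, 41.0, 0.01, 75.0, P_BS)
        assert prof.pressure(0.0) == pytest.approx(52.0, rel=1e-12)
        assert prof.pressure(75.0) == pytest.approx(41.0, rel=1e-12)

    @pytest.mark.parametrize("al", [30.0, 80.0, 300.0])
    def test_large_al_numerically_stable(self, al):
        length = 50.0
        prof = solve_pressure_profile(55.0, 40.0, al / length, length, P_BS)
        x = np.linspace(0, length, 101)
        p = prof.pressure(x)
        assert np.all(np.isfinite(p))
        # the interior collapses to p_BS (boundary influence ~ e^(-aL/2))
        assert p[50] == pytest.approx(P_BS, abs=100 * math.exp(-al / 2))
        assert excess_pressure_integral(prof) > 0


class TestIntegrals:
    def test_zero_at_equilibrium(self):
        prof = solve_pressure_profile(P_BS, P_BS, 0.01, 50.0, P_BS)
        assert excess_pressure_integral(prof) == pytest.approx(0.0, abs=1e-12)

    def test_trapezoid_value_at_zero_leakage(self):
        prof = solve_pressure_profile(50.0, 44.0, 0.0, 80.0, P_BS)
        assert excess_pressure_integral(prof) == pytest.approx(
            80.0 * ((50.0 + 44.0) / 2 - P_BS)
        )

    def test_matches_adaptive_quadrature(self):
        prof = solve_pressure_profile(51.0, 43.0, 0.008, 90.0, P_BS)
        ref, _ = quad(lambda x: prof.pressure(x) - P_BS, 0, 90.0,
                      epsabs=1e-12, epsrel=1e-12)
        assert excess_pressure_integral(prof) == pytest.approx(ref, rel=1e-8)

    def test_cumulative_excess_matches_quadrature(self):
        prof = solve_pressure_profile(51.0, 43.0, 0.008, 90.0, P_BS)
        for xq in (13.0, 47.0, 88.0):
            ref, _ = quad(lambda x: prof.pressure(x) - P_BS, 0, xq,
                          epsabs=1e-12, epsrel=1e-12)
            assert prof.cumulative_excess(xq) == pytest.approx(ref, rel=1e-8)


class TestFlowProfile:
    def test_no_filtration_constant_flow(self):
        prof = solve_pressure_profile(50.0, 45.0, 0.0, 60.0, P_BS)
        fp = flow_profile(prof, 1e9, 120.0)
        assert fp.flow(np.linspace(0, 60, 7)) == pytest.approx(np.full(7, 120.0))

    def test_conservation_identity(self):
        prof = solve_pressure_profile(52.0, 44.0, 0.006, 70.0, P_BS)
        r_f = 300.0
        fp = flow_profile(prof, r_f, 90.0)
        assert fp.q_in - fp.q_out == pytest.approx(fp.csgfr, rel=1e-9)
        assert fp.csgfr == pytest.approx(
            excess_pressure_integral(prof) / (70.0 * r_f), rel=1e-12
        )

    def test_matches_cumulative_quadrature(self):
        prof = solve_pressure_profile(52.0, 44.0, 0.006, 70.0, P_BS)
        fp = flow_profile(prof, 300.0, 90.0)
        for xq in (10.0, 35.0, 69.0):
            loss, _ = quad(lambda x: (prof.pressure(x) - P_BS) / (70.0 * 300.0),
                           0, xq, epsabs=1e-13)
            assert fp.flow(xq) == pytest.approx(90.0 - loss, rel=1e-8)

    @settings(deadline=None, max_examples=30)
    @given(p_up=st.floats(30.0, 70.0), dp=st.floats(0.0, 15.0),
           al=st.floats(0.0, 2.0))
    def test_raising_upstream_pressure_never_reduces_filtration(self, p_up, dp, al):
        length = 60.0
        a = al / length
        lo = flow_profile(solve_pressure_profile(p_up, p_up - dp, a, length, P_BS),
                          200.0, 50.0).csgfr
        hi = flow_profile(solve_pressure_profile(p_up + 5, p_up - dp, a, length, P_BS),
                          200.0, 50.0).csgfr
        assert hi >= lo - 1e-12


class TestFiltrationResistanceUpdate:
    def test_protein_free_closed_form(self):
        # with Pi = 0 the integrals cancel: R_f = 1/(k π L D) exactly
        prof = solve_pressure_profile(50.0, 45.0, 0.004, 60.0, P_BS)
        k, d = 2e-5, 7.0
        r_f, clamped = update_filtration_resistance(prof, lambda x: 0.0 * x, k, d)
        assert not clamped
        assert r_f == pytest.approx(1.0 / (k * math.pi * 60.0 * d), rel=1e-12)

    def test_halving_k_doubles_resistance(self):
        prof = solve_pressure_profile(50.0, 45.0, 0.004, 60.0, P_BS)
        pi_at = lambda x: 18.0 + 0.05 * x
        r1, _ = update_filtration_resistance(prof, pi_at, 2e-5, 7.0)
        r2, _ = update_filtration_resistance(prof, pi_at, 1e-5, 7.0)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_matches_quadrature_oracle(self):
        prof = solve_pressure_profile(52.0, 46.0, 0.006, 80.0, P_BS)
        pi_at = lambda x: 16.0 + 0.002 * np.asarray(x) ** 2 / 80.0
        k, d = 1.5e-5, 8.0
        r_f, clamped = update_filtration_resistance(prof, pi_at, k, d)
        num, _ = quad(lambda x: prof.pressure(x) - P_BS, 0, 80.0, epsabs=1e-12)
        den, _ = quad(lambda x: prof.pressure(x) - P_BS - pi_at(x), 0, 80.0,
                      epsabs=1e-12)
        assert not clamped
        assert r_f == pytest.approx(num / (k * math.pi * 80.0 * d * den), rel=1e-9)

    def test_equilibrium_segment_clamped(self):
        prof = solve_pressure_profile(30.0, 29.0, 0.004, 60.0, P_BS)
        r_f, clamped = update_filtration_resistance(
            prof, lambda x: 40.0 + 0.0 * np.asarray(x), 2e-5, 7.0, r_f_max=1e9
        )
        assert clamped and r_f == 1e9


class TestConcentrationProfile:
    def test_no_filtration_constant(self):
        prof = solve_pressure_profile(50.0, 45.0, 0.0, 60.0, P_BS)
        fp = flow_profile(prof, 1e9, 100.0)
        c_at = concentration_profile(5.7, 55.0, fp, 45.0)
        assert c_at(np.linspace(0, 60, 5)) == pytest.approx(np.full(5, 5.7))

    def test_protein_mass_flux_constant(self):
        prof = solve_pressure_profile(52.0, 44.0, 0.006, 70.0, P_BS)
        fp = flow_profile(prof, 150.0, 90.0)
        q_rbc = 40.0
        c_at = concentration_profile(5.7, 50.0, fp, q_rbc)
        x = np.linspace(0, 70, 9)
        flux = c_at(x) * (fp.flow(x) - q_rbc)
        assert np.max(np.abs(flux - flux[0])) / flux[0] < 1e-10

    def test_exhausted_plasma_rejected(self):
        prof = solve_pressure_profile(60.0, 55.0, 0.02, 70.0, P_BS)
        fp = flow_profile(prof, 0.5, 10.0)  # drains far more than available
        c_at = concentration_profile(5.7, 5.0, fp, 5.0)
        with pytest.raises(ValueError, match="plasma"):
            c_at(70.0)
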