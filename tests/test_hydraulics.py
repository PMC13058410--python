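"""Hydraulic supply, water cost and stomatal optimization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from canopyabl.hydraulics import (GS_MAX, GS_MIN, HydraulicParams,
                                  SupplyCurve, _objective_chain,
                                  conductance_at_psi, critical_flow,
                                  leaf_water_potential, optimize_gs,
                                  water_cost)
from canopyabl.leaf import LeafEnvironment, PhotosynthesisParams


@pytest.fixture(scope="module")
def hyd():
    return HydraulicParams()


@pytest.fixture(scope="module")
def supply(hyd):
    return SupplyCurve(hyd)


@pytest.fixture(scope="module")
def midday_env():
    return LeafEnvironment(Ra=800.0, Tair=303.0, ea=2200.0, wind=2.0,
                           par_absorbed=1500.0, emissivity=0.85)


class TestVulnerabilityCurve:
    def test_saturated_conductance(self, hyd):
        assert conductance_at_psi(hyd, 0.0) == hyd.Kmax

    def test_half_loss_at_psi50(self, hyd):
        assert conductance_at_psi(hyd, hyd.psi50) == pytest.approx(
            hyd.Kmax / 2, rel=1e-12)

    def test_sigmoidal_closed_form(self):
        p = HydraulicParams(shape=2.0)
        # psi = 2 psi50 -> Kmax / (1 + 2^2)
        assert conductance_at_psi(p, 2 * p.psi50) == pytest.approx(
            p.Kmax / 5.0, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(psi=st.floats(-8.0, -1e-3))
    def test_monotone_decline(self, hyd, psi):
        assert conductance_at_psi(hyd, psi) < conductance_at_psi(
            hyd, psi * 0.5)

    def test_rejects_positive_psi(self, hyd):
        with pytest.raises(ValueError):
            conductance_at_psi(hyd, 0.5)


class TestLeafWaterPotential:
    def test_no_flow_equilibrium(self, hyd):
        assert leaf_water_potential(hyd, 0.0, -0.5) == -0.5

    def test_linear_darcy_limit(self):
        # effectively constant Kp: psi50 far below operating range
        p = HydraulicParams(Kmax=0.002, psi50=-500.0, shape=6.0)
        psiL = leaf_water_potential(p, 0.001, -0.5)
        assert psiL == pytest.approx(-0.5 - 0.001 / 0.002, rel=1e-4)

    def test_quadrature_oracle_round_trip(self, hyd):
        ecrit = critical_flow(hyd, -0.5)
        e = 0.5 * ecrit
        psiL = leaf_water_potential(hyd, e, -0.5)
        supply_back, _ = integrate.quad(
            lambda x: conductance_at_psi(hyd, x), psiL, -0.5)
        assert supply_back == pytest.approx(e, rel=1e-6)

    def test_hydraulic_failure_raises(self, hyd):
        ecrit = critical_flow(hyd, -0.5)
        with pytest.raises(FloatingPointError):
            leaf_water_potential(hyd, 1.01 * ecrit, -0.5)

    def test_supply_table_matches_quadrature(self, hyd, supply):
        for e in (0.0005, 0.002, 0.003):
            exact = leaf_water_potential(hyd, e, -0.5)
            assert float(supply.psi_leaf(e, -0.5)) == pytest.approx(
                exact, abs=1e-4)


class TestWaterCost:
    def test_zero_at_saturation(self, hyd):
        assert water_cost(hyd, 0.0) == 0.0

    def test_half_cost_at_psi50(self, hyd):
        assert water_cost(hyd, hyd.psi50) == pytest.approx(hyd.cw / 2)

    def test_arithmetic(self):
        p = HydraulicParams(cw=4.0)
        # Kp/Kmax = 0.2 -> Theta = 3.2
        psi = p.psi50 * 4.0 ** (1.0 / p.shape)  # where (psi/psi50)^s = 4
        assert water_cost(p, psi) == pytest.approx(3.2, rel=1e-9)

    def test_bounded_by_cw(self, hyd):
        psi = np.linspace(-30.0, 0.0, 50)
        theta = water_cost(hyd, psi)
        assert np.all((theta >= 0) & (theta <= hyd.cw))
        assert np.all(np.diff(theta) < 1e-12)  # increasing in |psi|


class TestOptimization:
    def test_matches_brute_force_grid(self, hyd, supply, midday_env):
        pp = PhotosynthesisParams()
        gs, state, hs = optimize_gs(midday_env, pp, hyd, -0.5, supply)
        grid = np.linspace(GS_MIN, GS_MAX, 2000)
        gains = _objective_chain(grid, midday_env, pp, hyd, -0.5, supply)[0]
        assert abs(float(gs) - grid[np.argmax(gains)]) < 1e-3
        own = _objective_chain(float(gs), midday_env, pp, hyd, -0.5,
                               supply)[0]
        assert own >= np.max(gains) - 1e-4

    def test_no_cost_opens_fully_with_fixed_kinetics(self):
        # with kinetics pinned at 25 C, carbon gain is monotone in gs, so
        # a zero water price drives stomata to the search bound (mild
        # evaporative demand: the hydraulic supply limit stays slack)
        from canopyabl.leaf import esat
        p = HydraulicParams(cw=0.0)
        pp = PhotosynthesisParams(temperature_dependent=False)
        env = LeafEnvironment(Ra=500.0, Tair=298.0, ea=0.9 * float(esat(298.0)),
                              wind=2.0, par_absorbed=1500.0, emissivity=0.85)
        gs, _, _ = optimize_gs(env, pp, p, -0.5, SupplyCurve(p))
        assert float(gs) == pytest.approx(GS_MAX, abs=5e-3)

    def test_dark_closes_to_minimum(self, hyd, supply):
        env = LeafEnvironment(Ra=300.0, Tair=300.0, ea=2200.0, wind=2.0,
                              par_absorbed=0.0, emissivity=0.85)
        gs, _, _ = optimize_gs(env, PhotosynthesisParams(), hyd, -0.5,
                               supply)
        assert float(gs) == pytest.approx(GS_MIN, abs=2e-3)

    def test_conservative_syndrome_closes_stomata(self, midday_env):
        pp = PhotosynthesisParams()
        got = []
        for cw in (0.5, 1.0, 2.0, 4.0):
            p = HydraulicParams(cw=cw)
            gs, _, _ = optimize_gs(midday_env, pp, p, -0.5, SupplyCurve(p))
            got.append(float(gs))
        assert all(a >= b - 1e-6 for a, b in zip(got, got[1:]))

    def test_drier_soil_closes_stomata(self, hyd, supply, midday_env):
        pp = PhotosynthesisParams()
        got = [float(optimize_gs(midday_env, pp, hyd, ps, supply)[0])
               for ps in (-0.2, -0.8, -1.4)]
        assert all(a >= b - 1e-6 for a, b in zip(got, got[1:]))

    def test_interior_optimum_marginal_condition(self, hyd, supply,
                                                 midday_env):
        """At an interior optimum, marginal carbon gain equals marginal
        water cost (finite-difference check through the full chain)."""
        pp = PhotosynthesisParams()
        gs, _, _ = optimize_gs(midday_env, pp, hyd, -0.5, supply)
        g = float(gs)
        assert GS_MIN + 0.01 < g < GS_MAX - 0.01
        h = 5e-3
        _, _, _, _, an_p, psi_p, th_p = _objective_chain(
            g + h, midday_env, pp, hyd, -0.5, supply)
        _, _, _, _, an_m, psi_m, th_m = _objective_chain(
            g - h, midday_env, pp, hyd, -0.5, supply)
        dan = (an_p - an_m) / (2 * h)
        dth = (th_p - th_m) / (2 * h)
        assert float(dan) == pytest.approx(float(dth), abs=0.5)


class TestValidation:
    def test_parameter_guards(self):
        with pytest.raises(ValueError):
            HydraulicParams(psi50=1.0)
        with pytest.raises(ValueError):
            HydraulicParams(Kmax=-1.0)
        with pytest.raises(ValueError):
            HydraulicParams(cw=-0.5)
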