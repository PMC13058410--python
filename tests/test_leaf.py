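"""Farquhar kinetics, intercellular CO2 and the leaf energy budget."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from canopyabl import leaf
from canopyabl.leaf import (LeafEnvironment, PhotosynthesisParams,
                            electron_transport, esat,
                            kinetics_at_temperature, net_assimilation,
                            solve_ci, solve_leaf_energy_balance)

SIGMA = 5.670374419e-8


class TestKinetics:
    def test_identity_at_reference_temperature(self):
        p = PhotosynthesisParams()
        k = kinetics_at_temperature(p, 298.15)
        assert k["Vcmax"] == pytest.approx(p.Vcmax25, rel=1e-12)
        assert k["Kc"] == pytest.approx(p.Kc25, rel=1e-12)
        assert k["GammaStar"] == pytest.approx(p.GammaStar25, rel=1e-12)

    def test_fixed_kinetics_ignore_leaf_temperature(self):
        p = PhotosynthesisParams(temperature_dependent=False)
        k_hot = kinetics_at_temperature(p, 310.0)
        k_ref = kinetics_at_temperature(p, 298.15)
        for key in k_ref:
            assert np.allclose(k_hot[key], k_ref[key])

    def test_arrhenius_multiplier_hand_value(self):
        # exp(65330 * 10 / (298.15 * 8.314 * 308.15)) ~ 2.352
        assert leaf._arrhenius(65330.0, 308.15) == pytest.approx(2.352,
                                                                abs=0.002)

    def test_peaked_response_declines_beyond_optimum(self):
        p = PhotosynthesisParams()
        t = np.linspace(298.15, 323.15, 60)
        v = kinetics_at_temperature(p, t)["Vcmax"]
        i_max = int(np.argmax(v))
        assert 0 < i_max < len(t) - 1  # interior thermal optimum
        assert v[-1] < v[i_max]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kinetics_at_temperature(PhotosynthesisParams(), 350.0)

    def test_jmax_ratio_guard(self):
        with pytest.raises(ValueError):
            PhotosynthesisParams(Vcmax25=50.0, Jmax25=200.0)


class TestAssimilation:
    def test_compensation_point(self):
        p = PhotosynthesisParams()
        kin = kinetics_at_temperature(p, 298.15)
        an = net_assimilation(kin, kin["GammaStar"], par_absorbed=1000.0, p=p)
        assert an == pytest.approx(-kin["Rd"], rel=1e-9)

    def test_dark_respiration_limit(self):
        p = PhotosynthesisParams()
        kin = kinetics_at_temperature(p, 298.15)
        an = net_assimilation(kin, 300.0, par_absorbed=0.0, p=p)
        assert an == pytest.approx(-kin["Rd"], rel=1e-9)

    def test_rubisco_limited_closed_form(self):
        # Vcmax=50, Km=710, GammaStar=42.75, ci=280, Rd=1
        kin = dict(Vcmax=50.0, Km=710.0, GammaStar=42.75, Rd=1.0)
        an = net_assimilation(kin, 280.0, J=1e9)
        assert an == pytest.approx(50 * (280 - 42.75) / (280 + 710) - 1,
                                   rel=1e-12)

    def test_increasing_in_ci_below_saturation(self):
        p = PhotosynthesisParams()
        kin = kinetics_at_temperature(p, 303.0)
        ci = np.linspace(50.0, 350.0, 40)
        an = net_assimilation(kin, ci, par_absorbed=1500.0, p=p)
        assert np.all(np.diff(an) > 0)


class TestSolveCi:
    def test_large_supply_approaches_ambient(self):
        p = PhotosynthesisParams()
        kin = kinetics_at_temperature(p, 303.0)
        ci, _ = solve_ci(kin, 50.0, 400.0, par_absorbed=1500.0, p=p)
        assert ci > 395.0

    def test_dark_closed_stomata_respiration_limited(self):
        p = PhotosynthesisParams()
        kin = kinetics_at_temperature(p, 298.15)
        ci, an = solve_ci(kin, 1e-3, 400.0, par_absorbed=0.0, p=p)
        # supply cannot export respired CO2: degenerate case flagged as
        # ci = ca with An = -Rd
        assert an == pytest.approx(-kin["Rd"], rel=1e-6)

    def test_matches_bisection_oracle(self):
        p = PhotosynthesisParams()
        kin = kinetics_at_temperature(p, 303.0)
        J = electron_transport(p, kin["Jmax"], 1000.0)

        def mismatch(c):
            return (0.2 / 1.6) * (400.0 - c) - net_assimilation(kin, c, J=J)

        ci_oracle = brentq(mismatch, 1e-6, 400.0, xtol=1e-10)
        ci, an = solve_ci(kin, 0.2, 400.0, J=J)
        assert ci == pytest.approx(ci_oracle, abs=1e-6)
        assert an == pytest.approx((0.2 / 1.6) * (400 - ci_oracle), rel=1e-8)

    def test_rejects_nonpositive_gs(self):
        p = PhotosynthesisParams()
        kin = kinetics_at_temperature(p, 298.15)
        with pytest.raises(ValueError):
            solve_ci(kin, 0.0, 400.0, par_absorbed=500.0, p=p)


class TestEnergyBalance:
    def test_radiative_equilibrium_returns_air_temperature(self):
        ra_eq = 2 * 0.98 * SIGMA * 303.0 ** 4
        env = LeafEnvironment(Ra=ra_eq, Tair=303.0, ea=esat(303.0), wind=2.0)
        st = solve_leaf_energy_balance(env, 1e-9)
        assert st.TL == pytest.approx(303.0, abs=1e-6)
        assert abs(st.H) < 1e-3 and st.E == pytest.approx(0.0, abs=1e-12)

    def test_residual_below_contract(self):
        env = LeafEnvironment(Ra=np.linspace(100, 900, 15), Tair=303.0,
                              ea=2000.0, wind=2.0)
        st = solve_leaf_energy_balance(env, np.linspace(0.02, 0.8, 15))
        assert np.max(np.abs(st.residual)) < 0.1

    def test_matches_bisection_oracle(self):
        gbv = 0.147 * math.sqrt(2.0 / 0.1)
        gbh = 0.135 * math.sqrt(2.0 / 0.1)
        gv = 1.0 / (1.0 / 0.2 + 1.0 / gbv)

        def resid(T):
            return (600.0 - 2 * 0.98 * SIGMA * T ** 4
                    - 44100.0 * gv * max(float(esat(T)) - 2000.0, 0.0) / 101300.0
                    - 2 * gbh * 29.2 * (T - 303.0))

        t_oracle = brentq(resid, 283.0, 333.0, xtol=1e-8)
        env = LeafEnvironment(Ra=600.0, Tair=303.0, ea=2000.0, wind=2.0)
        st = solve_leaf_energy_balance(env, 0.2)
        assert st.TL == pytest.approx(t_oracle, abs=0.01)

    def test_cooling_with_stomatal_opening(self):
        gs = np.linspace(0.01, 1.0, 25)
        env = LeafEnvironment(Ra=700.0, Tair=303.0, ea=2000.0, wind=2.0)
        st = solve_leaf_energy_balance(env, gs)
        assert np.all(np.diff(st.TL) < 0)  # TL decreasing in gs
        assert np.all(np.diff(st.E) > 0)  # E increasing in gs

    def test_unphysical_forcing_raises(self):
        env = LeafEnvironment(Ra=6000.0, Tair=300.0, ea=500.0, wind=2.0)
        with pytest.raises(FloatingPointError):
            solve_leaf_energy_balance(env, 0.1)

    def test_nonstrict_pins_at_bracket(self):
        env = LeafEnvironment(Ra=6000.0, Tair=300.0, ea=500.0, wind=2.0)
        st = solve_leaf_energy_balance(env, 0.1, strict=False)
        assert st.TL == pytest.approx(330.0)
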