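"""Two-stream canopy radiative transfer: conservation, limits, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canopyabl import radiation as rad
from canopyabl.radiation import (CanopyRadiationModel, LeafAngleDistribution,
                                 LeafOptics, beam_extinction,
                                 diffuse_extinction, extinction_and_sunlit,
                                 g_function, longwave_exchange,
                                 sunlit_orientation_classes, two_stream_band)

SIGMA = 5.670374419e-8


class TestLeafAngles:
    def test_spherical_projection_is_half(self):
        lad = LeafAngleDistribution.spherical()
        for z in (0.1, 0.6, 1.2):
            assert g_function(lad, z) == pytest.approx(0.5, abs=1e-4)

    def test_spherical_beam_extinction(self):
        lad = LeafAngleDistribution.spherical()
        for z in (0.2, 0.8):
            assert beam_extinction(lad, z) == pytest.approx(
                0.5 / math.cos(z), rel=1e-3)

    def test_erectophile_kb_against_quadrature(self):
        # independent oracle: dense trapezoid integration of the
        # azimuth-averaged projection over the leaf-angle density
        lad = LeafAngleDistribution.erectophile()
        zen = math.radians(30.0)
        th = np.linspace(1e-4, math.pi / 2 - 1e-4, 2000)
        ph = np.linspace(0, 2 * math.pi, 721)
        cosg = (math.cos(zen) * np.cos(th)[:, None]
                + math.sin(zen) * np.sin(th)[:, None] * np.cos(ph)[None, :])
        proj = np.trapezoid(np.abs(cosg), ph, axis=1) / (2 * math.pi)
        dens = lad.density(th)
        g_oracle = np.trapezoid(proj * dens, th) / np.trapezoid(dens, th)
        assert beam_extinction(lad, zen) == pytest.approx(
            g_oracle / math.cos(zen), rel=1e-3)

    def test_nighttime_signals_error(self):
        with pytest.raises(ValueError):
            beam_extinction(LeafAngleDistribution.spherical(), math.pi / 2)

    def test_density_normalized(self):
        th = np.linspace(0, math.pi / 2, 4001)
        for lad in (LeafAngleDistribution.erectophile(),
                    LeafAngleDistribution.planophile(),
                    LeafAngleDistribution.spherical()):
            assert np.trapezoid(lad.density(th), th) == pytest.approx(
                1.0, abs=1e-3)

    def test_orientation_classes_consistent_with_g(self):
        lad = LeafAngleDistribution.erectophile()
        zen = 0.5
        w, g = sunlit_orientation_classes(lad, zen, n_classes=5)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.sum(w * g) == pytest.approx(g_function(lad, zen), rel=1e-6)


class TestSunlitFraction:
    def test_top_of_canopy_fully_sunlit(self):
        lad = LeafAngleDistribution.spherical()
        kb, f = extinction_and_sunlit(lad, 0.4, np.array([0.0, 1.0, 2.0]))
        assert f[0] == pytest.approx(1.0)

    def test_exponential_decay_and_monotone(self):
        lad = LeafAngleDistribution.spherical()
        L = np.linspace(0.0, 6.0, 20)
        kb, f = extinction_and_sunlit(lad, 0.4, L)
        assert np.allclose(f, np.exp(-kb * L))
        assert np.all(np.diff(f) < 0)


class TestTwoStream:
    def test_black_leaf_beer_law(self):
        optics = LeafOptics(vis_reflectance=0.0, vis_transmittance=0.0)
        out = two_stream_band("vis", optics, [0.2] * 30, 0.0, 400.0, 0.5)
        kd = diffuse_extinction(LeafAngleDistribution.spherical())
        expected = 400.0 * np.exp(-kd * np.cumsum([0.2] * 30))
        assert np.allclose(out["down"][1:], expected, rtol=1e-12)

    def test_vanishing_canopy_transmits_everything(self):
        out = two_stream_band("vis", LeafOptics(), [1e-7] * 5, 300.0, 100.0,
                              0.3)
        assert out["down"][-1] + out["beam"][-1] == pytest.approx(400.0,
                                                                 rel=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(rho=st.floats(0.01, 0.45), tau=st.floats(0.01, 0.35),
           direct=st.floats(0.0, 800.0), diffuse=st.floats(0.0, 400.0),
           zenith=st.floats(0.0, 1.3))
    def test_energy_conservation_random_draws(self, rho, tau, direct,
                                              diffuse, zenith):
        optics = LeafOptics(vis_reflectance=rho, vis_transmittance=tau)
        out = two_stream_band("vis", optics, [0.3] * 20, direct, diffuse,
                              zenith)
        incident = direct + diffuse
        residual = (incident - out["reflected"] - out["ground_absorbed"]
                    - out["absorbed"].sum())
        assert abs(residual) <= 1e-6 * max(incident, 1.0)
        assert np.all(out["absorbed"] >= -1e-9)

    def test_against_successive_scattering_oracle(self):
        """2-layer canopy vs a brute-force multiple-scattering solver on a
        fine sublayer grid (independent implementation)."""
        rho, tau, zen = 0.1, 0.05, 0.0
        omega = rho + tau
        lai = [1.0, 1.0]
        lad = LeafAngleDistribution.spherical()
        kb = beam_extinction(lad, zen)
        kd = diffuse_extinction(lad)
        th, w_th, _ = rad._orientation_grid(lad)
        cos2 = float(np.sum(w_th * np.cos(th) ** 2))
        beta = (0.5 * omega + 0.5 * (rho - tau) * cos2) / omega
        albedo_g = 0.05
        # --- oracle: 200 thin sublayers, successive orders of scattering
        n = 200
        dl = 2.0 / n
        i_d = 1.0 - math.exp(-kd * dl)  # diffuse interception per sublayer
        beam = 400.0 * np.exp(-kb * dl * np.arange(n + 1))
        inc_dn = omega * (1.0 - beta) * (beam[:-1] - beam[1:])
        inc_up = omega * beta * (beam[:-1] - beam[1:])
        absorbed = (1.0 - omega) * (beam[:-1] - beam[1:])
        ground_abs = (1 - albedo_g) * beam[-1]
        ground_pending = albedo_g * beam[-1]
        for _ in range(400):
            new_dn = np.zeros(n)
            new_up = np.zeros(n)
            flux = 0.0
            for i in range(n):  # downward sweep
                flux += inc_dn[i]
                caught = flux * i_d
                flux -= caught
                absorbed[i] += (1 - omega) * caught
                new_dn[i] += omega * (1 - beta) * caught
                new_up[i] += omega * beta * caught
            ground_abs += (1 - albedo_g) * flux
            flux = ground_pending + albedo_g * flux
            ground_pending = 0.0
            for i in range(n - 1, -1, -1):  # upward sweep
                flux += inc_up[i]
                caught = flux * i_d
                flux -= caught
                absorbed[i] += (1 - omega) * caught
                new_up[i] += omega * (1 - beta) * caught
                new_dn[i] += omega * beta * caught
            inc_dn, inc_up = new_dn, new_up
            if inc_dn.sum() + inc_up.sum() < 1e-10:
                break
        oracle_layers = np.array([absorbed[:n // 2].sum(),
                                  absorbed[n // 2:].sum()])
        # --- implementation
        optics = LeafOptics(vis_reflectance=rho, vis_transmittance=tau)
        out = two_stream_band("vis", optics, lai, 400.0, 0.0, zen,
                              lads=[lad, lad])
        assert np.allclose(out["absorbed"], oracle_layers, rtol=0.01)


class TestLongwave:
    def test_isothermal_enclosure_zero_net(self):
        lw = longwave_exchange([300.0] * 10, SIGMA * 300.0 ** 4,
                               LeafOptics(emissivity=1.0), [0.6] * 10,
                               t_ground=300.0)
        assert np.max(np.abs(lw["net"])) < 1e-9

    def test_single_leaf_emission_value(self):
        from canopyabl.leaf import thermal_emission
        # 2 eps sigma T^4 for an isolated leaf at 300 K (hand value)
        assert thermal_emission(300.0, 0.98) == pytest.approx(900.23, abs=0.05)

    def test_cold_sky_loss_shielded_with_depth(self):
        lw = longwave_exchange([300.0] * 10, 350.0, LeafOptics(), [0.6] * 10,
                               t_ground=300.0)
        assert lw["net"][0] < 0
        assert np.all(np.diff(lw["net"]) > 0)  # loss shrinks with depth

    def test_rejects_nonphysical_temperature(self):
        with pytest.raises(ValueError):
            longwave_exchange([-5.0], 300.0, LeafOptics(), [0.5])


class TestCanopyRadiationModel:
    def test_full_solve_consistency(self):
        m = CanopyRadiationModel(n_layers=10, total_lai=6.0, n_classes=3)
        r = m.fluxes(0.4, 900.0, 0.15, 420.0, np.full(10, 302.0), 302.0)
        assert np.all(np.diff(r.sunlit_fraction) < 0)
        assert np.all(r.absorbed_vis_sunlit >= 0)
        assert r.sw_absorbed_total + r.ground_sw_absorbed < 900.0
        # sunlit leaves of steeper projection absorb more VIS
        assert np.all(np.diff(r.absorbed_vis_sunlit[0]) > 0)

    def test_rejects_too_few_layers(self):
        with pytest.raises(ValueError):
            CanopyRadiationModel(n_layers=3)
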