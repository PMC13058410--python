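"""Canopy-ABL coupling: algebraic closure and diurnal integration."""

import numpy as np
import pytest

from canopyabl.abl import ABLState, SurfaceLayerConfig
from canopyabl.canopy import CanopyConfig, CanopyModel
from canopyabl.coupler import (_SurfaceSolver, integrate_day,
                               solve_surface_state)
from canopyabl.forcing import AtmosphericProfile
from canopyabl.leaf import esat
from canopyabl.metrics import coupling_metrics, hysteresis_area

SIGMA = 5.670374419e-8


class TestSurfaceClosure:
    def test_zero_flux_fixed_point(self, small_canopy):
        """Dark equilibrium forcing: the canopy-air state relaxes to the
        slab state (no gradients, no fluxes)."""
        theta = 299.0
        # nearly saturated air so that residual cuticular evaporation
        # cannot pull the equilibrium below the slab temperature
        q = 0.95 * 0.622 * float(esat(theta)) / 101300.0
        forcing_t = {"Rsw": 0.0, "Rlw": SIGMA * theta ** 4, "fD": 1.0,
                     "zenith": 2.0, "U": 2.0, "ustar": 0.3, "ca": 4.0e-4}
        small_canopy.reset()
        st = ABLState(h=500.0, theta=theta, q=q)
        cs = solve_surface_state(small_canopy, st, forcing_t, -0.5,
                                 SurfaceLayerConfig.for_canopy(30.0))
        assert cs.Tair == pytest.approx(theta, abs=0.25)
        assert cs.qair == pytest.approx(q, abs=5e-4)

    def test_daytime_residuals_below_tolerance(self, small_canopy,
                                               noon_forcing):
        small_canopy.reset()
        st = ABLState(h=800.0, theta=301.0, q=0.016)
        cs = solve_surface_state(small_canopy, st, noon_forcing, -0.5,
                                 SurfaceLayerConfig.for_canopy(30.0),
                                 zeta=-0.5)
        assert abs(cs.residual_T) < 1e-3
        assert abs(cs.residual_q) < 1e-6

    def test_matches_grid_scan_oracle(self, small_canopy, noon_forcing):
        """Newton solution vs brute-force scan of the joint residual."""
        st = ABLState(h=800.0, theta=301.0, q=0.016)
        scfg = SurfaceLayerConfig.for_canopy(30.0)
        small_canopy.reset()
        cs = solve_surface_state(small_canopy, st, noon_forcing, -0.5, scfg)
        solver = _SurfaceSolver(small_canopy)
        tl0 = small_canopy._tl_prev.copy()
        best, arg = np.inf, None
        for ta in np.arange(cs.Tair - 1.0, cs.Tair + 1.0, 0.2):
            for qa in np.arange(cs.qair - 8e-4, cs.qair + 8e-4, 2e-4):
                f, _ = solver.residual(ta, qa, st, noon_forcing, -0.5,
                                       cs.raH, tl0)
                score = abs(f[0]) / 5e-4 + abs(f[1]) / 5e-7
                if score < best:
                    best, arg = score, (ta, qa)
        assert cs.Tair == pytest.approx(arg[0], abs=0.25)
        assert cs.qair == pytest.approx(arg[1], abs=2.5e-4)


class TestDiurnalIntegration:
    def test_midday_canopy_warmer_than_air(self, coupled_day):
        df = coupled_day.frame
        mid = df[df["time"].between(11 * 3600, 14 * 3600)]
        assert (mid["Tcan"] - mid["Tair"]).min() > 0

    def test_hysteresis_loop_with_lag(self, coupled_day):
        m = coupling_metrics(coupled_day)
        assert hysteresis_area(coupled_day) > 0.5  # open loop, K^2
        assert abs(m.lag) > 5.0  # air and canopy peaks separated

    def test_abl_height_grows_through_convective_day(self, coupled_day):
        df = coupled_day.frame
        day = df[df["Rsw"] > 50]
        assert np.all(np.diff(day["h"]) > -1e-9)
        assert day["h"].iloc[-1] > 4 * day["h"].iloc[0]

    def test_theta_plateaus_while_surface_cools(self, coupled_day):
        """Late afternoon: canopy and air temperatures decline but the
        deep mixed layer barely cools (thermal inertia)."""
        df = coupled_day.frame
        late = df[df["time"] >= 15 * 3600]
        assert late["Tair"].iloc[-1] < late["Tair"].max() - 1.0
        assert late["Tcan"].iloc[-1] < late["Tcan"].max() - 1.0
        theta_day = df[df["Rsw"] > 0]["theta"]
        assert theta_day.max() - late["theta"].iloc[-1] < 0.5

    def test_closure_recorded_below_tolerance(self, coupled_day):
        assert coupled_day.frame["closure"].abs().max() < 1e-3

    def test_vpd_nonnegative_and_peaks_midday(self, coupled_day):
        df = coupled_day.frame
        assert df["VPD"].min() >= 0
        t_peak = df.loc[df["VPD"].idxmax(), "time"]
        assert 11 * 3600 < t_peak < 17 * 3600

    def test_timestep_halving_converged(self, coupled_day, coupled_day_fine):
        m1 = coupling_metrics(coupled_day)
        m2 = coupling_metrics(coupled_day_fine)
        assert abs(m1.max_tcan - m2.max_tcan) < 0.05

    def test_slab_heat_conservation(self, coupled_day, profile):
        """Mixed-layer heat gain equals integrated surface + entrainment
        input: audited through the column-enthalpy bookkeeping."""
        df = coupled_day.frame
        h, theta = df["h"].to_numpy(), df["theta"].to_numpy()
        t = df["time"].to_numpy()
        ft = lambda z: profile.theta0 + profile.gammaT * (z - profile.h0)
        H_TOP = 4000.0
        col = h * theta + (H_TOP - h) * 0.5 * (ft(h) + ft(H_TOP))
        surf = np.trapezoid(df["wT_s"].to_numpy(), t)
        assert col[-1] - col[0] == pytest.approx(surf, rel=0.01)

    def test_prescribed_air_round_trip(self, coupled_day, forcing_day,
                                       reduced_canopy_config):
        """Driving the canopy with the air series of a coupled run must
        reproduce that run's canopy temperatures."""
        air = coupled_day.frame[["time", "Tair", "qair"]]
        out = integrate_day(forcing_day, canopy_config=reduced_canopy_config,
                            mode="prescribed_air", prescribed=air,
                            step=600.0)
        dev = np.abs(out.frame["Tcan"].to_numpy()
                     - coupled_day.frame["Tcan"].to_numpy())
        assert dev.max() < 0.1

    def test_prescribed_air_requires_series(self, forcing_day):
        with pytest.raises(ValueError):
            integrate_day(forcing_day, mode="prescribed_air")

    def test_unknown_mode_rejected(self, forcing_day):
        with pytest.raises(ValueError):
            integrate_day(forcing_day, mode="clamped")
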