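"""Multilayer canopy assembly: the FORCE step.

Stacks the radiative transfer, leaf energy budget, photosynthesis and
stomatal machinery into equal-LAI layers, each split into shaded leaves
plus sunlit orientation classes, and aggregates leaf fluxes to
canopy-scale sensible/latent heat, kinematic surface fluxes and the
canopy-top temperature

    w'theta's, w'q's, Tcan = FORCE(Tair, qair, Rsw, Rlw, fD, ze, U, psi_s)

Tcan is the LAI-weighted mean leaf temperature over the uppermost layers
down to cumulative LAI = 1 — the radiometric temperature a nadir-viewing
sensor would report.  The canopy airspace is a single well-mixed node at
(Tair, qair); within-canopy wind follows an exponential profile.
Because leaf temperatures feed back on the thermal radiation field, the
step iterates radiation <-> leaf solves to a fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .leaf import (LAMBDA_MOL, P_SURFACE, LeafEnvironment,
                   PhotosynthesisParams, electron_transport,
                   kinetics_at_temperature, solve_ci,
                   solve_leaf_energy_balance)
from .hydraulics import GS_MIN, HydraulicParams, SupplyCurve, optimize_gs
from .radiation import CanopyRadiationModel, LeafOptics

__all__ = [
    "CanopyConfig",
    "TraitParams",
    "CanopyFluxes",
    "CanopyModel",
    "wind_profile",
    "constant_gs_profile",
    "vapor_pressure_from_q",
]

CP_MASS = 1004.5  # J kg-1 K-1
R_DRY = 287.05  # J kg-1 K-1
LAMBDA_MASS = LAMBDA_MOL / 0.018  # J kg-1


def vapor_pressure_from_q(q, pressure: float = P_SURFACE):
    """Vapor pressure [Pa] from specific humidity [kg kg-1]."""
    q = np.asarray(q, dtype=float)
    return q * pressure / (0.622 + 0.378 * q)


def air_density(Tair, pressure: float = P_SURFACE):
    """Dry-air density [kg m-3]."""
    return pressure / (R_DRY * np.asarray(Tair, dtype=float))


@dataclass
class CanopyConfig:
    """Discretization and stomatal-mode settings of the canopy model.

    n_layers equal-LAI layers; sunlit leaves in n_classes orientation
    classes.  gs_mode 'optimized' runs the hydraulic-cost optimization
    per leaf; 'constant' prescribes a canopy-top conductance declining
    linearly with cumulative LAI to the cuticular floor at the base.
    wind_attenuation is the exponential in-canopy wind decay exponent.
    capacity_decay is the e-folding of photosynthetic capacity with
    cumulative LAI (Vcmax, Jmax, Rd scale together).
    """

    n_layers: int = 30
    total_lai: float = 6.0
    canopy_height: float = 30.0
    wind_attenuation: float = 2.5
    gs_mode: str = "optimized"
    gs_top: float = 0.2
    n_classes: int = 5
    capacity_decay: float = 0.2
    gs_tol: float = 2e-4
    optics: LeafOptics = field(default_factory=LeafOptics)

    def __post_init__(self) -> None:
        if self.n_layers < 5:
            raise ValueError("n_layers must be at least 5")
        if self.total_lai <= 0:
            raise ValueError("total_lai must be positive")
        if self.gs_mode not in ("optimized", "constant"):
            raise ValueError("gs_mode must be 'optimized' or 'constant'")


@dataclass
class TraitParams:
    """Plant functional traits: photosynthesis + hydraulic cost."""

    photosynthesis: PhotosynthesisParams = field(
        default_factory=PhotosynthesisParams)
    hydraulics: HydraulicParams = field(default_factory=HydraulicParams)


@dataclass
class CanopyFluxes:
    """Canopy-aggregated surface fluxes for one timestep.

    wT_s, wq_s are the kinematic heat [K m s-1] and moisture
    [kg kg-1 m s-1] fluxes that force the mixed-layer budget; H, LE in
    W m-2 ground; GPP gross (An + Rd) and net_assim net of leaf
    respiration, umol CO2 m-2 ground s-1; Tcan in K.
    """

    wT_s: float
    wq_s: float
    H: float
    LE: float
    GPP: float
    net_assim: float
    Tcan: float
    E_canopy: float  # mol H2O m-2 ground s-1
    closure_residual: float  # relative canopy energy-closure residual


def wind_profile(U_top: float, depth_fraction, attenuation: float = 2.5):
    """Exponential in-canopy wind: U(z) = U_top exp(-alpha * depth).

    depth_fraction = 1 - z/h_c, 0 at canopy top, 1 at the ground.
    """
    if U_top <= 0:
        raise ValueError("U_top must be positive")
    d = np.asarray(depth_fraction, dtype=float)
    return U_top * np.exp(-attenuation * d)


def constant_gs_profile(cfg: CanopyConfig, gs_floor: float = GS_MIN):
    """Per-layer stomatal conductance for the constant-gs mode.

    Canopy-top value cfg.gs_top declining linearly with cumulative LAI
    to the cuticular floor at the canopy base.
    """
    if cfg.gs_mode != "constant":
        raise ValueError("constant_gs_profile requires gs_mode='constant'")
    if cfg.gs_top <= 0:
        raise ValueError("gs_top must be positive")
    dl = cfg.total_lai / cfg.n_layers
    cum_mid = (np.arange(cfg.n_layers) + 0.5) * dl
    frac = cum_mid / cfg.total_lai
    return cfg.gs_top + (gs_floor - cfg.gs_top) * frac


class CanopyModel:
    """Assembled multilayer canopy, reusable across timesteps.

    Precomputes layer geometry, the radiation model, the hydraulic
    supply table and per-layer photosynthetic capacity; `force_step`
    solves one timestep given canopy-air state and external forcing.
    """

    def __init__(self, config: CanopyConfig | None = None,
                 traits: TraitParams | None = None):
        self.config = config or CanopyConfig()
        self.traits = traits or TraitParams()
        cfg = self.config
        self.radiation = CanopyRadiationModel(
            n_layers=cfg.n_layers, total_lai=cfg.total_lai,
            optics=cfg.optics, n_classes=cfg.n_classes)
        self.dl = self.radiation.dl
        self.cum_mid = self.radiation.cum_lai_mid
        self.supply = SupplyCurve(self.traits.hydraulics)
        self.capacity = np.exp(-cfg.capacity_decay * self.cum_mid)
        depth = self.cum_mid / cfg.total_lai  # leaf area as depth proxy
        self._depth = depth
        self._tl_prev: np.ndarray | None = None
        # Tcan weights: layers down to cumulative LAI = 1 (partial last)
        upper = np.clip(1.0 - (self.radiation.cum_lai_bottom - self.dl), 0.0,
                        self.dl)
        self._tcan_w = upper / upper.sum()

    # ------------------------------------------------------------------

    def _leaf_env(self, rad, Tair, qair, U_top, ca_ppm):
        n, c = self.config.n_layers, self.config.n_classes
        # columns: [shaded, sunlit class 1..c]
        ra_sw = np.concatenate([
            (rad.absorbed_vis_shaded + rad.absorbed_nir_shaded)[:, None],
            rad.absorbed_vis_sunlit + rad.absorbed_nir_sunlit], axis=1)
        par = np.concatenate([rad.par_shaded[:, None], rad.par_sunlit], axis=1)
        ra = ra_sw + rad.thermal_incident[:, None]
        wind = wind_profile(U_top, self._depth,
                            self.config.wind_attenuation)[:, None]
        ea = float(vapor_pressure_from_q(qair))
        return LeafEnvironment(Ra=ra, Tair=Tair, ea=ea, wind=wind,
                               ca=ca_ppm, par_absorbed=par,
                               emissivity=rad.emissivity_eff[:, None])

    def _area_weights(self, rad):
        """Leaf-area weights (n_layers, 1+n_classes) summing to total LAI."""
        f = rad.sunlit_fraction[:, None]
        w_sun = rad.class_weights * f * self.dl[:, None]
        w_sh = (1.0 - rad.sunlit_fraction) * self.dl
        return np.concatenate([w_sh[:, None], w_sun], axis=1)

    def force_step(self, Tair: float, qair: float, forcing_t: dict,
                   psiS: float, max_iter: int = 8, tl_tol: float = 0.005):
        """Solve one timestep; returns (CanopyFluxes, per-leaf state dict).

        forcing_t: dict with Rsw, Rlw, fD, zenith, U, ca (as produced by
        DiurnalForcing.interp).  The thermal radiation field depends on
        leaf temperatures, so the step iterates radiation <-> leaf solves
        to a fixed point on the layer radiative temperature (fourth-
        moment mean, which makes layer emission bookkeeping exact).
        """
        cfg = self.config
        rsw = float(forcing_t["Rsw"])
        zenith = float(forcing_t["zenith"])
        ca_ppm = float(forcing_t.get("ca", 4.0e-4)) * 1e6
        tl_rad = (self._tl_prev if self._tl_prev is not None
                  else np.full(cfg.n_layers, Tair))
        tl_rad = np.clip(tl_rad, Tair - 10.0, Tair + 15.0)

        gs_const = (constant_gs_profile(cfg)[:, None]
                    if cfg.gs_mode == "constant" else None)
        gs = None
        shift = math.inf

        for iteration in range(max_iter):
            rad = self.radiation.fluxes(zenith, rsw, float(forcing_t["fD"]),
                                        float(forcing_t["Rlw"]), tl_rad,
                                        t_ground=Tair)
            env = self._leaf_env(rad, Tair, qair, float(forcing_t["U"]),
                                 ca_ppm)
            daylight = rsw > 0.0
            optimize_now = (cfg.gs_mode == "optimized" and daylight
                            and (iteration == 0 or shift > 0.2))
            if optimize_now:
                gs, state, hyd = optimize_gs(
                    env, self.traits.photosynthesis, self.traits.hydraulics,
                    psiS, self.supply, tol=cfg.gs_tol,
                    capacity_scale=self.capacity[:, None])
            else:
                # stomata held at the current aperture while the thermal
                # radiation field relaxes (re-optimization moves gs by
                # less than the golden-section tolerance at this stage)
                if gs is None:
                    gs = (gs_const if gs_const is not None
                          else np.full((cfg.n_layers, 1), GS_MIN))
                state = solve_leaf_energy_balance(env, gs, strict=False)
                kin = kinetics_at_temperature(
                    self.traits.photosynthesis,
                    np.clip(state.TL, 264.0, 332.0))
                kin = {k: (v * self.capacity[:, None]
                           if k in ("Vcmax", "Jmax", "Rd") else v)
                       for k, v in kin.items()}
                J = electron_transport(self.traits.photosynthesis,
                                       kin["Jmax"], env.par_absorbed)
                ci, an = solve_ci(kin, np.maximum(gs, 1e-6), ca_ppm, J=J)
                state.An, state.ci = an, ci
                hyd = None

            w = self._area_weights(rad)
            TL = np.broadcast_to(state.TL, w.shape)
            tl_rad_new = (np.sum(TL ** 4 * w, axis=1) / self.dl) ** 0.25
            shift = float(np.max(np.abs(tl_rad_new - tl_rad)))
            tl_rad = tl_rad_new
            if shift < tl_tol:
                break
        self._tl_prev = tl_rad

        H = float(np.sum(state.H * w))
        LE = float(np.sum(state.LE * w))
        E = float(np.sum(state.E * w))
        an_total = float(np.sum(state.An * w))
        rd = kinetics_at_temperature(self.traits.photosynthesis,
                                     np.clip(TL, 264.0, 332.0))["Rd"] \
            * self.capacity[:, None]
        gpp = float(np.sum((state.An + rd) * w))
        tl_mean = np.sum(TL * w, axis=1) / self.dl
        tcan = float(np.sum(tl_mean * self._tcan_w))

        # canopy closure: net radiation from the radiation solver's own
        # bookkeeping vs turbulent fluxes from the leaf solves (exposes
        # any unconverged radiation<->temperature lag + solver residuals)
        lw_net_solver = float(np.sum(rad.thermal_incident * self.dl)) - \
            float(np.sum(2.0 * rad.emissivity_eff * 5.670374419e-8
                         * tl_rad ** 4 * self.dl))
        net_rad = rad.sw_absorbed_total + lw_net_solver
        closure = (net_rad - H - LE) / max(abs(net_rad), 100.0)

        rho = float(air_density(Tair))
        fluxes = CanopyFluxes(
            wT_s=H / (rho * CP_MASS),
            wq_s=LE / (rho * LAMBDA_MASS),
            H=H, LE=LE, GPP=gpp, net_assim=an_total, Tcan=tcan,
            E_canopy=E, closure_residual=float(closure))
        detail = {
            "TL": TL, "gs": np.broadcast_to(gs, w.shape),
            "An": np.broadcast_to(state.An, w.shape),
            "E": np.broadcast_to(state.E, w.shape),
            "H": np.broadcast_to(state.H, w.shape),
            "LE": np.broadcast_to(state.LE, w.shape),
            "residual": np.broadcast_to(state.residual, w.shape),
            "area": w, "tl_layer": tl_mean,
            "psiL": (self.supply.psi_leaf(state.E, psiS)
                     if cfg.gs_mode == "optimized" else None),
        }
        return fluxes, detail

    def reset(self) -> None:
        """Drop the warm-start leaf-temperature field."""
        self._tl_prev = None

    @staticmethod
    def detail_frame(detail: dict) -> pd.DataFrame:
        """Per-layer/class state as a tidy table (for CSV export)."""
        tl = detail["TL"]
        n, c = tl.shape
        rows = []
        for i in range(n):
            for j in range(c):
                rows.append({
                    "layer": i, "class": "shaded" if j == 0 else f"sun{j}",
                    "TL": tl[i, j], "gs": detail["gs"][i, j],
                    "An": detail["An"][i, j], "E": detail["E"][i, j],
                    "H": detail["H"][i, j], "LE": detail["LE"][i, j],
                    "leaf_area": detail["area"][i, j],
                })
        return pd.DataFrame(rows)
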