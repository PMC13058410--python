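"""Mixed-layer (slab) model of the convective atmospheric boundary layer.

The daytime ABL is reduced to its depth h, a vertically uniform
potential temperature theta and specific humidity q, evolving as

    dh/dt     = we + ws
    dtheta/dt = (w'theta'_s - w'theta'_e) / h
    dq/dt     = (w'q'_s     - w'q'_e) / h

with surface fluxes delivered by the canopy model and entrainment fluxes
from a zeroth-order jump closure: the entrainment buoyancy flux is a
fixed fraction beta of the surface buoyancy flux, and the entrainment
velocity follows we = beta * B_s / dTheta_v with the virtual-temperature
jump floored to keep encroachment growth regular.  Subsidence is
ws = -divergence * h (zero by default).

The free troposphere is a fixed linear profile anchored at the dawn
sounding: theta_ft(z) = theta0 + gammaT (z - h0), and likewise for
humidity, so the jumps grow as the slab deepens and warms more slowly
than it entrains.

The slab connects to the canopy-top air through Monin-Obukhov
surface-layer resistances (Businger-Dyer stability functions, one lagged
iteration per timestep).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forcing import AtmosphericProfile

__all__ = [
    "ABLState",
    "EntrainmentParams",
    "SurfaceLayerConfig",
    "free_troposphere_jumps",
    "entrainment",
    "tendencies",
    "aerodynamic_resistances",
    "obukhov_length",
]

VON_KARMAN = 0.4
GRAVITY = 9.81
MIN_VIRTUAL_JUMP = 0.1  # K, floor on dTheta_v in the we closure


@dataclass
class ABLState:
    """Slab state: height [m], potential temperature [K], humidity [kg/kg]."""

    h: float
    theta: float
    q: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("ABL height must be positive")
        if self.q < 0:
            raise ValueError("specific humidity must be non-negative")

    def virtual_theta(self) -> float:
        return self.theta * (1.0 + 0.61 * self.q)


@dataclass
class EntrainmentParams:
    """Closure constants: entrainment ratio beta (top/surface buoyancy
    flux) and large-scale divergence [s-1] (subsidence ws = -div * h)."""

    beta: float = 0.2
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.divergence < 0:
            raise ValueError("divergence must be non-negative")


@dataclass
class SurfaceLayerConfig:
    """Geometry for Monin-Obukhov bulk transfer above the canopy.

    Defaults follow the usual forest scaling from canopy height h_c:
    z0m = 0.1 h_c, d = 0.7 h_c, z0h = z0m / 10, reference (blending)
    height one canopy height above the top.
    """

    z_ref: float = 60.0
    z0m: float = 3.0
    z0h: float = 0.3
    d: float = 21.0

    @classmethod
    def for_canopy(cls, canopy_height: float,
                   z_ref: float | None = None) -> "SurfaceLayerConfig":
        z0m = 0.1 * canopy_height
        return cls(z_ref=z_ref or 2.0 * canopy_height, z0m=z0m,
                   z0h=0.1 * z0m, d=0.7 * canopy_height)

    def __post_init__(self) -> None:
        if self.z_ref <= self.d + self.z0m:
            raise ValueError("need z_ref > d + z0m")


def free_troposphere_jumps(state: ABLState, prof: AtmosphericProfile):
    """Inversion jumps (dTheta, dQ) between the free troposphere profile
    evaluated at the current slab top and the slab values.

    The profile is anchored at the dawn state: theta_ft(h0) = theta0.
    """
    theta_ft = prof.theta0 + prof.gammaT * (state.h - prof.h0)
    q_ft = prof.q0 + prof.gammaq * (state.h - prof.h0)
    return theta_ft - state.theta, max(q_ft, 0.0) - state.q


def entrainment(state: ABLState, jumps: tuple[float, float],
                surface_buoyancy_flux: float, p: EntrainmentParams):
    """Entrainment velocity and entrainment fluxes.

    we = beta * B_s / dTheta_v with the virtual jump floored at
    MIN_VIRTUAL_JUMP (encroachment-like growth emerges for small
    inversions); growth is suppressed when the surface buoyancy flux is
    non-positive (night / early morning).  Entrainment fluxes are
    w'x'_e = -we * dX.
    """
    if not math.isfinite(surface_buoyancy_flux):
        raise ValueError("surface buoyancy flux must be finite")
    dtheta, dq = jumps
    dthetav = dtheta * (1.0 + 0.61 * state.q) + 0.61 * state.theta * dq
    dthetav = max(dthetav, MIN_VIRTUAL_JUMP)
    if surface_buoyancy_flux <= 0.0 or p.beta == 0.0:
        we = 0.0
    else:
        we = p.beta * surface_buoyancy_flux / dthetav
    return we, -we * dtheta, -we * dq


def tendencies(state: ABLState, surface_fluxes: tuple[float, float],
               prof: AtmosphericProfile, p: EntrainmentParams):
    """Right-hand sides (dh/dt, dtheta/dt, dq/dt) of the slab budget.

    surface_fluxes: kinematic (w'theta'_s [K m s-1], w'q'_s [m s-1 kg/kg]).
    """
    wT_s, wq_s = surface_fluxes
    jumps = free_troposphere_jumps(state, prof)
    buoy = wT_s * (1.0 + 0.61 * state.q) + 0.61 * state.theta * wq_s
    we, wT_e, wq_e = entrainment(state, jumps, buoy, p)
    # encroachment: when the slab has caught up with the free-troposphere
    # profile (vanishing inversion), growth is set by surface heating
    # alone, dh/dt = w'theta'_s / (gammaT h), which keeps the jump >= 0
    # and reproduces the classic h(t) = sqrt(h0^2 + 2 F t / gammaT)
    if wT_s > 0.0 and jumps[0] < MIN_VIRTUAL_JUMP:
        we_enc = wT_s / (prof.gammaT * state.h)
        if we_enc > we:
            we = we_enc
            wT_e, wq_e = -we * jumps[0], -we * jumps[1]
    ws = -p.divergence * state.h
    return (we + ws,
            (wT_s - wT_e) / state.h,
            (wq_s - wq_e) / state.h)


def _psi_h(zeta):
    """Businger-Dyer integrated stability correction for heat."""
    zeta = np.asarray(zeta, dtype=float)
    out = np.where(zeta >= 0, -5.0 * zeta, 0.0)
    unstable = zeta < 0
    if np.any(unstable):
        x2 = np.sqrt(np.maximum(1.0 - 16.0 * zeta, 1e-12))
        out = np.where(unstable, 2.0 * np.log((1.0 + x2) / 2.0), out)
    return out


def obukhov_length(ustar: float, theta_v: float, buoyancy_flux: float) -> float:
    """Obukhov length [m]; +/- inf at vanishing buoyancy flux."""
    if abs(buoyancy_flux) < 1e-9:
        return math.inf
    return -(ustar ** 3) * theta_v / (VON_KARMAN * GRAVITY * buoyancy_flux)


def aerodynamic_resistances(ustar: float, stability_parameter: float,
                            cfg: SurfaceLayerConfig):
    """Aerodynamic resistances (raH, raq) [s m-1] for scalar transfer
    between canopy top and mixed layer.

    stability_parameter is zeta = (z_ref - d)/L.  Neutral limit
    raH = ln((z_ref - d)/z0h) / (k ustar); unstable corrections reduce
    the resistance; raq = raH (scalar similarity).
    """
    if ustar <= 0:
        raise ValueError("ustar must be positive")
    dz = cfg.z_ref - cfg.d
    zeta = float(stability_parameter)
    corr = float(_psi_h(zeta) - _psi_h(zeta * cfg.z0h / dz))
    ra = (math.log(dz / cfg.z0h) - corr) / (VON_KARMAN * ustar)
    ra = max(ra, 1.0)  # guard against unphysically small resistance
    return ra, ra
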