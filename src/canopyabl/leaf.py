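"""Leaf-level photosynthesis and energy budget.

Farquhar-type net assimilation with temperature-dependent kinetics
(Arrhenius for the Michaelis constants, the CO2 compensation point and
dark respiration; peaked Arrhenius for Vcmax and Jmax), intercellular
CO2 from Fick's law through stomata, and the nonlinear leaf energy
budget

    Ra = RL + lambda*E + H

solved for leaf temperature TL with a safeguarded Newton iteration.
Boundary-layer conductances follow the Campbell & Norman flat-leaf
forced-convection forms with a characteristic dimension of 0.1 m; heat
exchanges on both leaf sides, water vapor on one (hypostomatous leaves).

Everything is vectorized: scalar and array arguments broadcast, which is
what lets the canopy driver solve all layers, exposure classes and trial
stomatal conductances in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhotosynthesisParams",
    "LeafEnvironment",
    "LeafState",
    "kinetics_at_temperature",
    "net_assimilation",
    "electron_transport",
    "solve_ci",
    "solve_leaf_energy_balance",
    "esat",
    "boundary_layer_conductances",
    "thermal_emission",
]

R_GAS = 8.314  # J mol-1 K-1
T_REF = 298.15  # K
O2_MOLE_FRACTION = 210.0  # mmol mol-1
STEFAN_BOLTZMANN = 5.670374419e-8
LAMBDA_MOL = 44100.0  # J mol-1, latent heat of vaporization (2.45 MJ/kg)
CP_MOL = 29.2  # J mol-1 K-1, molar heat capacity of air
P_SURFACE = 101300.0  # Pa


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Farquhar parameters at 25 C with their temperature responses.

    Rates in umol m-2 s-1; Kc, GammaStar in umol mol-1; Ko in mmol
    mol-1; activation energies in J mol-1.  Jmax25 and Rd25 default to
    the empirical proportions Jmax25 = 1.67 Vcmax25 and
    Rd25 = 0.015 Vcmax25.  With ``temperature_dependent=False`` all
    kinetic outputs are clamped at their 25 C values regardless of leaf
    temperature (used to switch off biochemical thermoregulation).
    """

    Vcmax25: float = 45.0
    Jmax25: float | None = None
    Rd25: float | None = None
    Kc25: float = 404.9
    Ko25: float = 278.4
    GammaStar25: float = 42.75
    Ha_Vcmax: float = 65330.0
    Hd_Vcmax: float = 200000.0
    dS_Vcmax: float = 640.0
    Ha_Jmax: float = 43540.0
    Hd_Jmax: float = 200000.0
    dS_Jmax: float = 644.0
    Ha_Kc: float = 79430.0
    Ha_Ko: float = 36380.0
    Ha_GammaStar: float = 37830.0
    Ha_Rd: float = 46390.0
    curvature: float = 0.7  # non-rectangular hyperbola for J
    quantum_yield: float = 0.3  # mol e- per mol absorbed photons
    temperature_dependent: bool = True

    def __post_init__(self) -> None:
        if self.Jmax25 is None:
            object.__setattr__(self, "Jmax25", 1.67 * self.Vcmax25)
        if self.Rd25 is None:
            object.__setattr__(self, "Rd25", 0.015 * self.Vcmax25)
        if min(self.Vcmax25, self.Jmax25, self.Rd25, self.Kc25, self.Ko25,
               self.GammaStar25) <= 0:
            raise ValueError("all 25 C rates and constants must be positive")
        ratio = self.Jmax25 / self.Vcmax25
        if not 1.0 <= ratio <= 2.5:
            raise ValueError(f"Jmax25/Vcmax25 = {ratio:.2f} outside plausible band")

    def scaled(self, factor: float) -> "PhotosynthesisParams":
        """Copy with Vcmax25 (and proportional Jmax25, Rd25) scaled."""
        return replace(self, Vcmax25=self.Vcmax25 * factor,
                       Jmax25=self.Jmax25 * factor, Rd25=self.Rd25 * factor)


@dataclass
class LeafEnvironment:
    """Microenvironment of one leaf (broadcastable arrays allowed).

    Ra:            absorbed radiation, both sides, W m-2 leaf
    Tair:          local air temperature, K
    ea:            air vapor pressure, Pa
    wind:          local wind speed, m s-1
    ca:            ambient CO2, umol mol-1 (ppm)
    par_absorbed:  absorbed PAR, umol photons m-2 leaf s-1
    emissivity:    effective leaf thermal emissivity (canopy context may
                   pass a layer-effective value below the broadband leaf
                   emissivity)
    """

    Ra: np.ndarray | float
    Tair: np.ndarray | float
    ea: np.ndarray | float
    wind: np.ndarray | float
    ca: np.ndarray | float = 400.0
    par_absorbed: np.ndarray | float = 0.0
    emissivity: np.ndarray | float = 0.98
    pressure: float = P_SURFACE


@dataclass
class LeafState:
    """Solved leaf state: temperature, gas exchange and energy fluxes."""

    TL: np.ndarray | float  # K
    An: np.ndarray | float  # umol m-2 s-1
    ci: np.ndarray | float  # umol mol-1
    E: np.ndarray | float  # mol H2O m-2 s-1
    LE: np.ndarray | float  # W m-2 (= lambda * E)
    H: np.ndarray | float  # W m-2
    RL: np.ndarray | float  # W m-2
    gs: np.ndarray | float  # mol m-2 s-1
    residual: np.ndarray | float  # W m-2, energy budget closure


def esat(T) -> np.ndarray:
    """Saturation vapor pressure [Pa] (Campbell & Norman form)."""
    Tc = np.asarray(T, dtype=float) - 273.15
    return 611.0 * np.exp(17.502 * Tc / (Tc + 240.97))


def desat_dT(T) -> np.ndarray:
    Tc = np.asarray(T, dtype=float) - 273.15
    return esat(T) * 17.502 * 240.97 / (Tc + 240.97) ** 2


def thermal_emission(TL, emissivity=0.98) -> np.ndarray:
    """Two-sided grey-body emission per unit leaf area, 2 eps sigma TL^4."""
    return 2.0 * np.asarray(emissivity) * STEFAN_BOLTZMANN * np.asarray(TL) ** 4


def boundary_layer_conductances(wind, leaf_dim: float = 0.1):
    """Forced-convection boundary-layer conductances [mol m-2 s-1].

    Campbell & Norman flat-plate forms, per one leaf side:
    gbH = 0.135 sqrt(u/d), gbv = 0.147 sqrt(u/d).
    """
    u = np.maximum(np.asarray(wind, dtype=float), 0.05)
    root = np.sqrt(u / leaf_dim)
    return 0.135 * root, 0.147 * root


def _arrhenius(Ha, TL):
    return np.exp(Ha * (TL - T_REF) / (T_REF * R_GAS * TL))


def _peaked(Ha, Hd, dS, TL):
    num = 1.0 + np.exp((T_REF * dS - Hd) / (T_REF * R_GAS))
    den = 1.0 + np.exp((TL * dS - Hd) / (TL * R_GAS))
    return _arrhenius(Ha, TL) * num / den


def kinetics_at_temperature(p: PhotosynthesisParams, TL):
    """Kinetic parameters at leaf temperature TL [K].

    Returns dict with Vcmax, Jmax, Rd [umol m-2 s-1], Kc, GammaStar
    [umol mol-1], Ko [mmol mol-1] and Km = Kc (1 + O/Ko) [umol mol-1].
    With temperature dependence disabled the 25 C values are returned
    for any TL.
    """
    TL = np.asarray(TL, dtype=float)
    if np.any(TL <= 263.0) or np.any(TL >= 333.0):
        raise ValueError("leaf temperature outside 263-333 K: upstream divergence")
    if not p.temperature_dependent:
        TL = np.full_like(TL, T_REF)
    out = {
        "Vcmax": p.Vcmax25 * _peaked(p.Ha_Vcmax, p.Hd_Vcmax, p.dS_Vcmax, TL),
        "Jmax": p.Jmax25 * _peaked(p.Ha_Jmax, p.Hd_Jmax, p.dS_Jmax, TL),
        "Rd": p.Rd25 * _arrhenius(p.Ha_Rd, TL),
        "Kc": p.Kc25 * _arrhenius(p.Ha_Kc, TL),
        "Ko": p.Ko25 * _arrhenius(p.Ha_Ko, TL),
        "GammaStar": p.GammaStar25 * _arrhenius(p.Ha_GammaStar, TL),
    }
    out["Km"] = out["Kc"] * (1.0 + O2_MOLE_FRACTION / out["Ko"])
    return out


def electron_transport(p: PhotosynthesisParams, jmax, par_absorbed):
    """Electron transport rate J from the non-rectangular hyperbola."""
    q = np.asarray(par_absorbed, dtype=float) * p.quantum_yield
    jmax = np.asarray(jmax, dtype=float)
    theta = p.curvature
    b = q + jmax
    disc = np.sqrt(np.maximum(b * b - 4.0 * theta * q * jmax, 0.0))
    return (b - disc) / (2.0 * theta)


def net_assimilation(kin: dict, ci, par_absorbed=None, p=None, J=None):
    """Net assimilation An [umol m-2 s-1] at intercellular CO2 ci [ppm].

    An = min(Rubisco-limited, RuBP-limited) - Rd (hard minimum).  Either
    pass a precomputed electron transport J, or (p, par_absorbed).
    """
    ci = np.asarray(ci, dtype=float)
    if J is None:
        J = electron_transport(p, kin["Jmax"], par_absorbed)
    gamma = kin["GammaStar"]
    ac = kin["Vcmax"] * (ci - gamma) / (ci + kin["Km"])
    aj = (J / 4.0) * (ci - gamma) / (ci + 2.0 * gamma)
    return np.minimum(ac, aj) - kin["Rd"]


def _branch_ci(g, ca, V, K, gamma, Rd):
    """Positive root of g(ca-ci) = V(ci-gamma)/(ci+K) - Rd (ci in ppm)."""
    g = np.asarray(g, dtype=float)
    a = g
    b = V - Rd - g * (ca - K)
    c = -(g * ca * K + V * gamma + Rd * K)
    disc = np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))
    return (-b + disc) / (2.0 * a)


def solve_ci(kin: dict, gs, ca, par_absorbed=None, p=None, J=None):
    """Intercellular CO2 from Fick's law supply = Farquhar demand.

    gs is stomatal conductance to water vapor [mol m-2 s-1]; the CO2
    supply is An = (gs/1.6)(ca - ci) with ca, ci in umol mol-1.  Both
    limitation branches are solved analytically (quadratics); the
    binding branch is the one yielding the lower assimilation.  Returns
    (ci, An).  Degenerate cases (no root in (0, ca]) fall back to
    ci = ca, An = -Rd.
    """
    gs = np.asarray(gs, dtype=float)
    if np.any(gs <= 0):
        raise ValueError("gs must be positive")
    if J is None:
        J = electron_transport(p, kin["Jmax"], par_absorbed)
    g = gs / 1.6
    ci_c = _branch_ci(g, ca, kin["Vcmax"], kin["Km"], kin["GammaStar"], kin["Rd"])
    ci_j = _branch_ci(g, ca, J / 4.0, 2.0 * kin["GammaStar"], kin["GammaStar"],
                      kin["Rd"])
    # the operative branch is the one with the larger ci (lower An)
    ci = np.maximum(ci_c, ci_j)
    ci = np.clip(ci, 1e-6, None)
    an = g * (ca - ci)
    bad = ~np.isfinite(ci) | (ci > np.asarray(ca) * (1 + 1e-9))
    if np.any(bad):
        ci = np.where(bad, ca, ci)
        an = np.where(bad, -kin["Rd"] * np.ones_like(ci), an)
    return ci, an


def solve_leaf_energy_balance(env: LeafEnvironment, gs,
                              leaf_dim: float = 0.1,
                              tol: float = 1e-3,
                              max_iter: int = 60,
                              strict: bool = True) -> LeafState:
    """Solve Ra = RL + lambda E + H for leaf temperature (vectorized).

    Sensible heat exchanges on both leaf sides; transpiration through
    one stomatous side in series with its boundary layer.  Newton with
    bisection safeguard over TL in [Tair - 20, Tair + 30]; the residual
    at the returned TL is below ``tol`` W m-2 (default well under the
    0.1 W m-2 budget-closure requirement).  Photosynthesis is not
    evaluated here — compose with :func:`solve_ci` afterwards.
    """
    gs = np.asarray(gs, dtype=float)
    Ra = np.asarray(env.Ra, dtype=float)
    Tair = np.asarray(env.Tair, dtype=float)
    ea = np.asarray(env.ea, dtype=float)
    eps = np.asarray(env.emissivity, dtype=float)
    gbh, gbv = boundary_layer_conductances(env.wind, leaf_dim)
    gv = 1.0 / (1.0 / np.maximum(gs, 1e-9) + 1.0 / gbv)

    shape = np.broadcast_shapes(gs.shape, Ra.shape, Tair.shape, ea.shape,
                                np.shape(eps), np.shape(gbh))
    lo = np.broadcast_to(Tair - 20.0, shape).copy()
    hi = np.broadcast_to(Tair + 30.0, shape).copy()
    TL = np.broadcast_to(Tair, shape).astype(float).copy()

    def residual(T):
        # one-sided vapor exchange: transpiration only, no dew uptake
        rl = 2.0 * eps * STEFAN_BOLTZMANN * T ** 4
        le = LAMBDA_MOL * gv * np.maximum(esat(T) - ea, 0.0) / env.pressure
        h = 2.0 * gbh * CP_MOL * (T - Tair)
        return Ra - rl - le - h, rl, le, h

    f_lo, *_ = residual(lo)
    f_hi, *_ = residual(hi)
    # residual is decreasing in T; a root needs f(lo) >= 0 >= f(hi)
    no_root = (f_lo < 0) | (f_hi > 0)
    pinned = np.zeros(shape, dtype=bool)
    if np.any(no_root):
        if strict:
            raise FloatingPointError(
                "leaf energy balance has no root in [Tair-20, Tair+30]: "
                "unphysical forcing")
        # non-strict (optimizer probes): pin the offending leaves at the
        # bracket edge; their energy residual is reported, and such
        # operating points are never selected as optima
        pinned = no_root
        TL = np.where(f_hi > 0, hi, TL)
        TL = np.where(f_lo < 0, lo, TL)

    for _ in range(max_iter):
        f, rl, le, h = residual(TL)
        if np.all(pinned | (np.abs(f) < tol)):
            break
        drl = 8.0 * eps * STEFAN_BOLTZMANN * TL ** 3
        dle = LAMBDA_MOL * gv * desat_dT(TL) / env.pressure
        dle = np.where(esat(TL) > ea, dle, 0.0)
        dh = 2.0 * gbh * CP_MOL
        lo = np.where(f > 0, TL, lo)
        hi = np.where(f < 0, TL, hi)
        step = f / (drl + dle + dh)
        TL_new = TL + step
        outside = (TL_new <= lo) | (TL_new >= hi)
        TL = np.where(pinned, TL, np.where(outside, 0.5 * (lo + hi), TL_new))

    f, rl, le, h = residual(TL)
    E = gv * np.maximum(esat(TL) - ea, 0.0) / env.pressure
    le_pos = LAMBDA_MOL * E
    return LeafState(TL=TL, An=np.zeros(shape), ci=np.full(shape, np.nan),
                     E=E, LE=le_pos, H=h, RL=rl, gs=np.broadcast_to(gs, shape),
                     residual=f)
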