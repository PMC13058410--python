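"""Plant hydraulic supply and hydraulic-cost stomatal optimization.

The whole-plant hydraulic pathway is summarized by a vulnerability curve
Kp(psi) — conductance per unit leaf area declining with increasingly
negative water potential — and steady-state Darcy flow integrated along
the soil-to-leaf path:

    E = -integral_{psi_s}^{psi_L} Kp(psi) dpsi

The carbon cost of water loss is proportional to the fractional loss of
hydraulic conductivity at the leaf water potential,

    Theta = cw * (1 - Kp(psi_L) / Kmax),

and the stomatal conductance of each leaf maximizes instantaneous net
carbon gain An(gs) - Theta(gs), where both terms are evaluated through
the full chain: energy balance -> leaf temperature -> kinetics ->
intercellular CO2 -> An, and transpiration -> leaf water potential ->
Theta.

Two evaluation paths coexist: a quadrature/brentq path at 1e-8 relative
accuracy for the public scalar operations, and a precomputed cumulative
supply table (`SupplyCurve`) used for the vectorized optimization inside
the canopy driver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .leaf import (LeafEnvironment, PhotosynthesisParams, electron_transport,
                   kinetics_at_temperature, solve_ci,
                   solve_leaf_energy_balance)

__all__ = [
    "HydraulicParams",
    "HydraulicState",
    "conductance_at_psi",
    "leaf_water_potential",
    "water_cost",
    "SupplyCurve",
    "optimize_gs",
    "GS_MIN",
    "GS_MAX",
]

GS_MIN = 0.01  # mol m-2 s-1, minimum (cuticular) conductance
GS_MAX = 1.0  # mol m-2 s-1, search upper bound


@dataclass(frozen=True)
class HydraulicParams:
    """Whole-plant hydraulic traits (per unit leaf area).

    Kmax:  maximum conductance, mol m-2 s-1 MPa-1
    psi50: water potential at 50% conductivity loss, MPa (negative)
    shape: steepness of the vulnerability curve (dimensionless)
    cw:    water-cost scale, umol m-2 s-1 (CO2-equivalent price of full
           conductivity loss); higher cw = more conservative water use
    form:  'sigmoidal' Kp = Kmax / (1 + (psi/psi50)^shape)  (default) or
           'weibull'   Kp = Kmax * exp(-(psi/b)^c) with b = psi50/ln(2)^(1/c)
    """

    Kmax: float = 0.002
    psi50: float = -2.0
    shape: float = 3.0
    cw: float = 2.0
    form: str = "sigmoidal"

    def __post_init__(self) -> None:
        if self.Kmax <= 0:
            raise ValueError("Kmax must be positive")
        if self.psi50 >= 0:
            raise ValueError("psi50 must be negative")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.cw < 0:
            raise ValueError("cw must be non-negative")
        if self.form not in ("sigmoidal", "weibull"):
            raise ValueError("form must be 'sigmoidal' or 'weibull'")


@dataclass
class HydraulicState:
    """Water status of one leaf at its operating point."""

    psiL: float | np.ndarray  # MPa
    psiS: float | np.ndarray  # MPa
    E: float | np.ndarray  # mol m-2 s-1
    Theta: float | np.ndarray  # umol m-2 s-1


def conductance_at_psi(p: HydraulicParams, psi):
    """Vulnerability curve Kp(psi) [mol m-2 s-1 MPa-1] for psi <= 0."""
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 1e-12):
        raise ValueError("water potential must be <= 0")
    if p.form == "sigmoidal":
        return p.Kmax / (1.0 + (psi / p.psi50) ** p.shape)
    b = p.psi50 / math.log(2.0) ** (1.0 / p.shape)
    return p.Kmax * np.exp(-((psi / b) ** p.shape))


def _supply_integral(p: HydraulicParams, psi_from: float, psi_to: float) -> float:
    """integral of Kp over [psi_to, psi_from] (psi_to <= psi_from <= 0)."""
    val, _ = integrate.quad(lambda x: conductance_at_psi(p, x), psi_to,
                            psi_from, limit=200, epsabs=1e-13, epsrel=1e-11)
    return val


def critical_flow(p: HydraulicParams, psiS: float) -> float:
    """Maximum steady-state supply Ecrit = -int_{psiS}^{-inf} Kp dpsi.

    Finite for vulnerability curves with integrable tails (sigmoidal
    shape > 1, any Weibull)."""
    val, _ = integrate.quad(lambda x: conductance_at_psi(p, x), -np.inf, psiS,
                            limit=400, epsabs=1e-13, epsrel=1e-11)
    return val


def leaf_water_potential(p: HydraulicParams, E, psiS: float) -> float | np.ndarray:
    """Leaf water potential psiL [MPa] solving the Darcy supply integral.

    Inverts E = -int_{psiS}^{psiL} Kp(psi) dpsi by bracketing + brentq on
    the quadrature-evaluated supply; relative tolerance ~1e-9.  Raises if
    E exceeds the critical flow (hydraulic failure: the caller must
    restrict gs).
    """
    scalar = np.isscalar(E) or np.ndim(E) == 0
    E_arr = np.atleast_1d(np.asarray(E, dtype=float))
    if np.any(E_arr < 0):
        raise ValueError("E must be non-negative")
    ecrit = critical_flow(p, psiS)
    if np.any(E_arr >= ecrit):
        raise FloatingPointError(
            f"transpiration exceeds hydraulic supply limit Ecrit={ecrit:.3e}")
    out = np.empty_like(E_arr)
    for i, e in enumerate(E_arr):
        if e == 0.0:
            out[i] = psiS
            continue
        # expand bracket downward from psiS
        lo = psiS - e / conductance_at_psi(p, psiS)  # linear first guess
        while _supply_integral(p, psiS, lo) < e:
            lo = psiS + 2.0 * (lo - psiS) - 0.1
        out[i] = optimize.brentq(
            lambda x: _supply_integral(p, psiS, x) - e, lo, psiS,
            xtol=1e-12, rtol=8.9e-16)
    return float(out[0]) if scalar else out


def water_cost(p: HydraulicParams, psiL):
    """Theta = cw (1 - Kp(psiL)/Kmax) [umol m-2 s-1], in [0, cw]."""
    return p.cw * (1.0 - conductance_at_psi(p, psiL) / p.Kmax)


class SupplyCurve:
    """Tabulated cumulative hydraulic supply for fast vectorized use.

    Precomputes P(psi) = int_{psi}^{0} Kp dpsi on a dense grid so that
    psiL(E) = Pinv(P(psiS) + E) reduces to one interpolation per leaf.
    Accuracy ~1e-6 MPa against the quadrature path, ample for the
    optimizer's interior search.
    """

    def __init__(self, p: HydraulicParams, psi_min: float | None = None,
                 n: int = 4000):
        self.params = p
        if psi_min is None:
            psi_min = 50.0 * p.psi50  # conductance down by ~shape decades
        # grid denser near 0 where Kp varies fastest
        s = np.linspace(0.0, 1.0, n) ** 1.5
        self.psi = -s * abs(psi_min)
        kp = conductance_at_psi(p, self.psi)
        # cumulative integral from 0 down to psi (positive, increasing)
        self.P = np.concatenate(
            ([0.0], integrate.cumulative_trapezoid(kp, -self.psi)))
        self.P_total = float(self.P[-1])

    def supply_at(self, psi):
        """P(psi) = integral of Kp from psi up to 0 (positive)."""
        return np.interp(-np.asarray(psi, dtype=float), -self.psi, self.P)

    def psi_at_supply(self, P_val):
        """Inverse of supply_at (monotone)."""
        return -np.interp(np.asarray(P_val, dtype=float), self.P, -self.psi)

    def psi_leaf(self, E, psiS):
        """Vectorized psiL(E, psiS); E beyond the table saturates at the
        deepest tabulated potential (callers cap E below Ecrit)."""
        target = self.supply_at(psiS) + np.asarray(E, dtype=float)
        return self.psi_at_supply(np.minimum(target, self.P_total))

    def max_flow(self, psiS, margin: float = 0.95):
        """Usable supply margin below hydraulic failure."""
        return margin * (self.P_total - self.supply_at(psiS))


def _objective_chain(gs, env: LeafEnvironment, p_photo: PhotosynthesisParams,
                     p_hyd: HydraulicParams, psiS: float,
                     supply: SupplyCurve, capacity_scale=1.0):
    """Net gain An - Theta [umol m-2 s-1] for trial gs (vectorized).

    capacity_scale multiplies Vcmax/Jmax/Rd uniformly (used for the
    within-canopy decline of photosynthetic capacity)."""
    state = solve_leaf_energy_balance(env, gs, strict=False)
    # biochemistry evaluated at the clamped temperature during the line
    # search; out-of-range probes are never selected as optima
    kin = kinetics_at_temperature(p_photo, np.clip(state.TL, 264.0, 332.0))
    if np.any(np.asarray(capacity_scale) != 1.0):
        kin = dict(kin)
        for key in ("Vcmax", "Jmax", "Rd"):
            kin[key] = kin[key] * capacity_scale
    J = electron_transport(p_photo, kin["Jmax"], env.par_absorbed)
    ci, an = solve_ci(kin, gs, env.ca, J=J)
    psiL = supply.psi_leaf(state.E, psiS)
    theta = water_cost(p_hyd, psiL)
    gain = an - theta
    # steep continuous barrier toward the hydraulic supply limit: keeps
    # the optimum strictly below critical flow while leaving the
    # objective smooth (a hard cutoff would make canopy fluxes
    # discontinuous in the forcing and break the coupling solver)
    emax = supply.max_flow(psiS, margin=1.0)
    excess = np.maximum(state.E / emax - 0.9, 0.0) / 0.1
    gain = gain - 50.0 * excess * excess
    return gain, state, kin, ci, an, psiL, theta


def optimize_gs(env: LeafEnvironment, p_photo: PhotosynthesisParams,
                p_hyd: HydraulicParams, psiS: float,
                supply: SupplyCurve | None = None,
                gs_bounds: tuple[float, float] = (GS_MIN, GS_MAX),
                n_scan: int = 24, n_golden: int = 40, tol: float = 1e-5,
                capacity_scale=1.0):
    """Carbon-gain-maximizing stomatal conductance for one leaf.

    Grid pre-scan over [gmin, gmax] followed by a golden-section
    refinement of the best bracket (robust to the kink of the hard
    Farquhar minimum).  Works element-wise on broadcast leaf arrays.
    Returns (gs*, LeafState, HydraulicState).
    """
    if supply is None:
        supply = SupplyCurve(p_hyd)
    glo, ghi = gs_bounds
    grid = np.linspace(glo, ghi, n_scan)

    shape = np.broadcast_shapes(np.shape(env.Ra), np.shape(env.Tair),
                                np.shape(env.ea), np.shape(env.par_absorbed))
    # one stacked evaluation over the whole scan grid and all leaves
    gs_scan = grid.reshape((n_scan,) + (1,) * len(shape))
    vals = _objective_chain(gs_scan, env, p_photo, p_hyd, psiS, supply,
                            capacity_scale)[0]
    vals = np.broadcast_to(vals, (n_scan,) + shape)
    best = np.argmax(vals, axis=0)
    a = grid[np.maximum(best - 1, 0)].astype(float)
    b = grid[np.minimum(best + 1, n_scan - 1)].astype(float)

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    for _ in range(n_golden):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        f = _objective_chain(np.stack([c, d]), env, p_photo, p_hyd, psiS,
                             supply, capacity_scale)[0]
        take_left = f[0] >= f[1]
        a = np.where(take_left, a, c)
        b = np.where(take_left, d, b)
        if np.max(b - a) < tol:
            break
    gs_star = 0.5 * (a + b)
    gain, state, kin, ci, an, psiL, theta = _objective_chain(
        gs_star, env, p_photo, p_hyd, psiS, supply, capacity_scale)
    state.An = an
    state.ci = ci
    hyd = HydraulicState(psiL=psiL, psiS=psiS, E=state.E, Theta=theta)
    return gs_star, state, hyd
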