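# Methods

This note documents the model equations as implemented, the defaults and
their rationale, the numerical choices, and what the synthetic setting
does and does not represent.

## Canopy radiative transfer

Shortwave radiation is split 50/50 into VIS and NIR broadbands sharing
the forcing diffuse fraction; the thermal band closes the longwave
budget. Each canopy layer (default 30 equal-LAI layers, LAI 6) carries a
two-parameter beta leaf-angle distribution interpolated from erectophile
(p, q = 2.770, 1.172) at the top to planophile (1.172, 2.770) at the
bottom. Beam extinction uses the Ross G-function computed by quadrature
over leaf inclination and azimuth (64-node azimuth grid, 90-node
inclination grid); diffuse extinction is defined from the
hemispherically integrated beam transmittance at reference LAI 1.

The diffuse streams use a two-stream layer solution with coefficients
`gamma1 = 1 - omega (1 - beta_d)`, `gamma2 = omega beta_d` — the
diffusivity factor is folded into the leaf-angle-derived diffuse
extinction, so black leaves reproduce Beer's law exactly. The diffuse
backscatter fraction is `beta_d = (0.5 omega + 0.5 (rho - tau)
<cos^2 theta_L>) / omega`; the beam upscatter fraction is taken equal to
it (an adequate simplification for the broadband budget at this level of
abstraction). Interface fluxes solve a pentadiagonal linear system
(LAPACK banded solver), which makes every band exactly energy-conserving
up to linear-algebra precision. Layers are internally subdivided to a
diffuse optical depth of at most 0.08 so that beam-scattered sources,
injected at sublayer boundaries, converge to the continuum
distributed-source solution; a two-layer canopy then agrees with a
successive-orders-of-scattering reference to better than 1%.

In the thermal band, sublayer emission per stream equals sublayer
absorptivity times the blackbody flux (Kirchhoff at the layer level), so
an isothermal enclosure has exactly zero net exchange. The per-leaf
effective emissivity used by the leaf energy budget is the layer
absorptivity per unit leaf area (below the broadband leaf emissivity of
0.98 because of within-layer shading); leaf-level bookkeeping with this
effective emissivity is what closes the canopy energy budget exactly.
The layer temperature entering the emission sources is the fourth-moment
(radiative) mean over exposure classes. Soil: albedo 0.05 (VIS) / 0.20
(NIR), emissivity 0.95, surface at canopy-air temperature — under LAI 6
the ground contributes little to the canopy budget.

Sunlit leaves are grouped into 5 orientation classes by the cosine of
the leaf-sun angle, with class weights and mean projections computed
from the leaf-angle quadrature; per-class beam absorption is normalized
so the class total exactly matches the layer interception. Below 3
degrees of solar elevation the beam is treated as diffuse (its
extinction is numerically ill-conditioned and physically negligible).

## Leaf gas exchange and energy budget

Net assimilation is the hard minimum of Rubisco- and RuBP-limited rates
minus dark respiration. Kinetics at 25 C: Kc = 404.9 umol mol-1,
Ko = 278.4 mmol mol-1, GammaStar = 42.75 umol mol-1 with Arrhenius
activation energies (79430, 36380, 37830 J mol-1); Rd Arrhenius with
46390 J mol-1. Vcmax and Jmax follow peaked Arrhenius responses
(Ha = 65330 / 43540 J mol-1, Hd = 200000 J mol-1, dS = 640 / 644
J mol-1 K-1), putting the Vcmax optimum near 36 C and the Jmax optimum
near 32 C — standard broadleaf values that place midday tropical leaf
temperatures on or beyond the declining limb, which is what gives
stomata a thermoregulatory incentive. Defaults Vcmax25 = 45
umol m-2 s-1 at the canopy top with Jmax25 = 1.67 Vcmax25 and
Rd25 = 0.015 Vcmax25 (empirical proportionalities); photosynthetic
capacity declines with cumulative LAI as exp(-0.2 L). Electron
transport uses a non-rectangular hyperbola (curvature 0.7, quantum
yield 0.3 mol e- per mol absorbed photons; VIS energy converted at 4.6
umol photons per J). The `temperature_dependent=False` switch clamps
every kinetic parameter at its 25 C value regardless of leaf
temperature.

Intercellular CO2 solves supply = demand analytically: each limitation
branch combined with `An = (gs/1.6)(ca - ci)` is a quadratic in ci; the
operative branch is the one with lower assimilation. In darkness (or
vanishing gs) the supply cannot export respired CO2 and the case is
flagged degenerate with ci = ca, An = -Rd.

The leaf energy budget `Ra = RL + lambda E + H` uses Campbell-Norman
flat-plate forced-convection boundary-layer conductances
(characteristic dimension 0.1 m), two-sided sensible exchange,
single-sided (hypostomatous) vapor exchange in series with stomata, a
fixed latent heat of 44.1 kJ mol-1 (2.45 MJ kg-1), surface pressure
101.3 kPa, and no dew uptake (vapor flux floors at zero). A safeguarded
Newton iteration (bisection fallback, bracket Tair - 20 to Tair + 30 K)
solves TL to a residual below 1e-3 W m-2 — two orders tighter than the
0.1 W m-2 budget-closure requirement. During optimizer line searches
the solver runs in a non-strict mode that pins bracket-violating probes
at the bracket edge (such operating points are never optimal); the
kinetics are then evaluated at temperatures clipped to their validity
range.

## Hydraulics and stomatal optimization

The vulnerability curve defaults to the sigmoidal form
`Kp = Kmax / (1 + (psi/psi50)^a)` with Kmax = 2 mmol m-2 s-1 MPa-1,
psi50 = -2 MPa, a = 3 (a Weibull alternative is available). Root-zone
water potential defaults to -0.5 MPa, a mid-dry-season value held
quasi-static over the simulated day. The supply integral and its
inverse psiL(E) are evaluated two ways: adaptive quadrature plus brentq
(relative accuracy ~1e-9) for the public scalar operations, and a
4000-node tabulated cumulative supply curve (~1e-4 MPa accuracy) inside
the vectorized optimizer.

Each leaf independently maximizes `An - Theta` with
`Theta = cw (1 - Kp(psiL)/Kmax)`; cw defaults to 2 umol m-2 s-1
(mid-range of the 1-4 sweep). The optimization is a 24-point grid
pre-scan plus golden-section refinement of the best bracket, all
vectorized across layers, exposure classes and probe points; the bracket
tolerance is 1e-5 mol m-2 s-1 for the public operation and 2e-4 inside
the canopy driver. Transpiration approaching the hydraulic supply limit
is discouraged by a steep continuous barrier (quadratic above 90% of
the remaining supply margin): a hard feasibility cutoff would make
canopy fluxes discontinuous in the forcing and defeat the coupling
solver, while the smooth barrier keeps the optimum strictly below
critical flow. Search bounds: gmin = 0.01 mol m-2 s-1 (cuticular floor)
to gmax = 1.0 mol m-2 s-1.

## Canopy assembly

A single well-mixed canopy airspace carries (Tair, qair); wind decays
exponentially into the canopy with attenuation 2.5. The leaf solves and
the thermal radiation field are iterated to a fixed point (radiative
layer temperature change < 0.005 K; stomata are re-optimized when the
field shifts by more than 0.2 K, otherwise held while the radiation
relaxes). Canopy fluxes are leaf-area-weighted sums; Tcan is the
LAI-weighted mean leaf temperature over the layers down to cumulative
LAI 1 (sunlit classes and shaded leaves weighted by their area
fractions) — the radiometric analog of a nadir-viewing sensor. GPP is
exported both gross (An + Rd) and net of leaf respiration. Soil
evaporation and canopy heat storage are neglected; canopy energy
closure (net absorbed radiation vs turbulent fluxes) stays below 1e-3
relative at every timestep.

## Mixed-layer model

Zeroth-order jump closure: entrainment buoyancy flux = -beta times the
surface buoyancy flux (beta = 0.2), entrainment velocity
`we = beta B_s / dTheta_v` with the virtual jump floored at 0.1 K, and
explicit encroachment growth `dh/dt = w'theta's / (gammaT h)` when the
inversion vanishes — reproducing the classic
`h(t) = sqrt(h0^2 + 2 F t / gammaT)` limit at beta = 0. Subsidence
`ws = -divergence * h` defaults to zero. Virtual temperature includes
the 0.61 moisture terms. The free troposphere is a fixed linear profile
anchored at the dawn sounding (theta0 = 297.5 K, q0 = 0.016 kg kg-1,
gammaT = 5 K km-1, gammaq = -2 g kg-1 km-1, h0 = 200 m — typical
dry-season tropical morning values).

Surface-layer transfer uses Businger-Dyer stability functions with the
Obukhov length lagged one timestep; geometry from canopy height h_c:
z0m = 0.1 h_c, d = 0.7 h_c, z0h = z0m/10, reference height 2 h_c;
raq = raH (scalar similarity).

## Coupling and integration

Each timestep solves the two-unknown algebraic closure on (Tair, qair)
by damped Newton with a finite-difference Jacobian (secant spans 0.25 K
and 1.2e-4 kg kg-1 — wide enough to average over the ~1e-3 K m s-1 of
internal solver noise), warm-started by linear extrapolation of the two
previous closures and with the Jacobian reused across steps. Residual
tolerances: 5e-4 K m s-1 (heat) and 5e-7 kg kg-1 m s-1 (moisture); a
slow phase with fresh Jacobians and half steps handles extreme forcing,
and a point within ten times the tolerance is accepted (and recorded in
the output) rather than aborting. The leaf-temperature field is pinned
per closure so the residual is a deterministic function of the
unknowns. The slab then advances by Heun's method with the converged
fluxes held over the step (the surface is quasi-steady at 60-600 s
steps). The simulation window is sunrise to sunset + 1 h; the nocturnal
stable boundary layer is not modeled. Default timestep 60 s; halving
the step changes the daily maximum Tcan by well under 0.05 K, and
results shown at 300-600 s steps are converged to ~0.05 K.

## Surrogate

The FORCE map (Tair, qair, Rsw, Rlw, fD, zenith, U, psi_s) ->
(w'theta's, w'q's, Tcan) is smooth and deterministic, so a single-hidden-
layer tanh network (64 units, standardized inputs/outputs, lbfgs
training) trained on 5000 Latin-hypercube FORCE evaluations reaches
held-out R^2 above 0.99 per output. An `EmulatedCanopy` adapter lets the
surrogate drive the coupled integration directly; substituted for the
direct solve it reproduces the daily maximum canopy temperature to about
0.1 K while evaluating a full day several hundred times faster. The
surrogate is reproducible from its seed and serialized as plain arrays
plus JSON metadata (no pickling); it interpolates only within the
sampled envelope.

## Metrics

* `max_tcan`: daily maximum canopy-top temperature, degC.
* `slope`: OLS slope of Tcan on Tair over 07:00-17:00 local, both
  hysteresis limbs (a rising-limb-only variant is exposed).
* `lag`: time of the Tcan maximum minus time of the Tair maximum,
  minutes, each peak refined by a quadratic fit over +/-45 min around
  the discrete argmax (robust to solver noise on flat maxima). Because
  the slab integrates the surface heating, Tair peaks after the
  radiation-driven Tcan and the signed lag is negative; trend analyses
  use its magnitude.
* Elasticities: `sigma = log(y1/y2)/log(x1/x2)` from +/-5% parameter
  pairs, with metrics taken on positive scales (max_tcan in degC,
  |slope|, |lag|); non-positive metric pairs are flagged undefined.
  The +/-5% perturbation applies to theta0 in kelvin, following the
  sensitivity protocol; the forcing (longwave, shortwave) is kept at
  its default so the perturbation isolates the ABL initial condition.

## Synthetic forcing: scope and limits

The generator emulates a composite clear dry-season day: Spencer solar
geometry at 9.15 N (local solar time equals clock time; no equation of
time), irradiance `S0 cos z tau^(1/cos z)` with tau = 0.75, diffuse
fraction `0.7 (1 - tau^m)` (daily diffuse share ~0.2, satisfying the
clear-day < 0.5 criterion), constant Brutsaert clear-sky longwave
evaluated at the dawn state, and constant wind (2 m s-1) and friction
velocity (0.3 m s-1). It is deterministic and bit-identical across
calls. It does not represent: cloud passages and their radiative
transients, morning fog or dew, wind diurnality, day-to-day synoptic
variability, or rainy-season conditions. Passing tests therefore
demonstrate the mechanisms of canopy-ABL coupling under idealized
clear-sky forcing, not a site calibration; measured forcing can be
substituted through the CSV interface.

## Design choices on genuinely open points

* Stomata optimize per leaf (layer x exposure class) independently;
  no canopy-wide joint optimization.
* The beam upscatter fraction equals the diffuse backscatter fraction.
* A minimum (cuticular) conductance of 0.01 mol m-2 s-1 is always
  present; whether the supply integral includes cuticular loss is
  unresolved in general, and here all vapor loss passes through the
  same hydraulic pathway.
* The two water-cost cases of the sensitivity analysis are the sweep
  endpoints cw = 1 and cw = 4 umol m-2 s-1.
* Scaled-down runs used in the test suite (8-12 layers, 2-3 orientation
  classes, 300-900 s steps) preserve every qualitative coupling
  signature; the acceptance script runs at full resolution (30 layers,
  5 classes, 60 s).

## Known limitations

* No nocturnal boundary layer, cloud formation, or CO2 slab budget.
* No canopy heat storage or within-canopy air-profile resolution.
* The surrogate network is an interpolator over the sampled input
  envelope; it should not be evaluated outside those ranges.
* The lag metric is noise-limited to roughly +/-2 min at the reduced
  test resolution.
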