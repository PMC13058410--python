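# canopyabl

Coupled forest-canopy / convective boundary-layer simulator for studying
how plant water-use traits shape the relationship between canopy
temperature (Tcan) and air temperature (Tair) over clear-sky tropical
days.

## The problem

Canopy temperature is widely used — from thermal remote sensing to flux
towers — as a diagnostic of forest stress and thermoregulation, usually
by regressing Tcan against Tair as if air temperature were an external
driver. Over a transpiring forest it is not: sensible and latent heat
released by the canopy drive the daytime growth of the atmospheric
boundary layer (ABL), which in turn sets the near-surface air
temperature and humidity the canopy experiences. `canopyabl` closes this
loop explicitly, so that the diurnal Tcan~Tair trajectory — its slope,
the daily maximum Tcan, and the hysteresis lag between the two maxima —
emerges from the two-way coupling rather than being imposed.

## The model

**Canopy (FORCE step).** A multilayer canopy (default LAI 6 in 30
equal-LAI layers, canopy height 30 m, parameters for a seasonally dry
tropical forest) with, per layer:

* two-stream radiative transfer in VIS, NIR and thermal bands, with
  depth-dependent leaf-angle distributions (erectophile top, planophile
  bottom) and sunlit leaves split into orientation classes;
* a leaf energy budget `Ra = RL + lambda*E + H` solved for leaf
  temperature TL per layer and exposure class;
* Farquhar photosynthesis, `An = min(Ac, Aj) - Rd`, with Arrhenius /
  peaked-Arrhenius temperature kinetics and intercellular CO2 from
  Fick's law `An = (gs/1.6)(ca - ci)` at 400 ppm ambient CO2;
* stomatal conductance from instantaneous optimization
  `max_gs [ An(gs) - Theta(gs) ]`, with the water cost
  `Theta = cw (1 - Kp(psiL)/Kmax)` tied to the loss of whole-plant
  hydraulic conductance at the leaf water potential psiL obtained by
  integrating Darcy's law, `E = -int_{psi_s}^{psi_L} Kp(psi) dpsi`.

Aggregation gives the surface fluxes and the canopy-top temperature
(LAI-weighted mean leaf temperature down to cumulative LAI 1):

```
w'theta's, w'q's, Tcan = FORCE(Tair, qair, Rsw, Rlw, fD, ze, U, psi_s)
```

**Boundary layer.** A mixed-layer slab (height h, potential temperature
theta, humidity q) with a zeroth-order entrainment closure
(entrainment-to-surface buoyancy flux ratio beta = 0.2):

```
dh/dt = we + ws,   dtheta/dt = (w'theta's - w'theta'e)/h,   dq/dt = (w'q's - w'q'e)/h
```

**Coupling.** Each timestep solves the algebraic closure between the
canopy fluxes and Monin-Obukhov bulk transfer,
`w'theta's = (Tair - theta)/raH`, `w'q's = (qair - q)/raq`, then
advances the slab. A prescribed-air mode drives FORCE with an external
(Tair, qair) series instead — the usual "uncoupled" assumption — to
quantify what the feedback changes. An optional neural-network surrogate
of the FORCE map (held-out R^2 > 0.99 per output) can replace the direct
canopy solve.

Synthetic clear-sky forcing (solar geometry at 9.15 N, transmissivity-
based irradiance with daily diffuse fraction < 0.5, Brutsaert clear-sky
longwave, constant dry-season wind) replaces site data; measured series
can be supplied as CSV.

## Worked example

```python
from canopyabl import (build_forcing_day, integrate_day, coupling_metrics,
                       CanopyConfig)

forcing = build_forcing_day(step=1800.0)  # clear-sky dry-season day
run = integrate_day(forcing, step=600.0,
                    canopy_config=CanopyConfig(n_layers=12, n_classes=3))
m = coupling_metrics(run)
df = run.frame
print(f"daily max Tcan : {m.max_tcan:.2f} degC")
print(f"Tcan~Tair slope: {m.slope:.3f}")
print(f"peak lag       : {m.lag:+.0f} min (Tcan peak minus Tair peak)")
print(f"ABL growth     : {df['h'].iloc[0]:.0f} -> {df['h'].max():.0f} m")
print(f"midday Bowen   : {df['H'].max():.0f} / {df['LE'].max():.0f} W m-2")
```

prints

```
daily max Tcan : 34.90 degC
Tcan~Tair slope: 1.203
peak lag       : -28 min (Tcan peak minus Tair peak)
ABL growth     : 200 -> 1740 m
midday Bowen   : 268 / 411 W m-2
```

The canopy runs ~2 degC warmer than the air at midday, the boundary
layer deepens from 200 m to ~1.7 km, and the air temperature maximum
trails the canopy maximum by about half an hour — the hysteresis that
makes a single Tcan~Tair regression slope an ambiguous measure of
thermoregulation. Experiment drivers in `canopyabl.experiments` sweep
constant stomatal conductance (0.085-0.380 mol m-2 s-1, 30 runs), the
water-cost parameter cw (1-4 umol m-2 s-1, coupled vs prescribed air),
compare temperature-dependent against fixed-25C photosynthetic
kinetics, and compute +/-5% elasticities of the coupling metrics to the
ABL parameters (theta0, gammaT, gammaq, h0, beta).

A command-line interface mirrors the library:

```
canopyabl simulate --mode coupled --out results/run1
canopyabl experiments run gs_sweep --reduced --out results/sweep
```

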