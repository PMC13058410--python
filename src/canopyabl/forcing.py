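"""Synthetic clear-sky diurnal forcing for a tropical forest site.

Generates the external drivers of the canopy exchange model for one
dry-season day: incoming shortwave and longwave radiation, diffuse
fraction, wind speed, friction velocity, solar zenith angle and ambient
CO2, together with the dawn atmospheric profile (surface potential
temperature and humidity, free-troposphere lapse rates, initial
boundary-layer height) that initializes the mixed-layer model.

The generator is analytic and fully deterministic: a transmissivity-based
clear-sky irradiance model on top of a standard solar-position
computation, constant daytime wind, and a Brutsaert-type clear-sky
longwave emissivity evaluated at the dawn temperature.  Measured series
can be substituted through the CSV round-trip (`DiurnalForcing.to_csv` /
`from_csv`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SiteConfig",
    "AtmosphericProfile",
    "DiurnalForcing",
    "solar_declination",
    "solar_zenith",
    "clear_sky_irradiance",
    "clear_sky_longwave",
    "build_forcing_day",
]

SOLAR_CONSTANT = 1361.0  # W m-2
STEFAN_BOLTZMANN = 5.670374419e-8  # W m-2 K-4
CO2_AMBIENT = 4.0e-4  # mol mol-1 (400 ppm)
P_SURFACE = 101300.0  # Pa


@dataclass
class SiteConfig:
    """Static site descriptors of the simulated forest stand.

    Defaults describe a semi-deciduous tropical forest in central Panama
    in the middle of the dry season: dense canopy (LAI 6, height 30 m)
    and moderately dry soil (`soil_water_potential` is the root-weighted
    mean soil water potential seen by the hydraulic pathway).
    """

    latitude: float = 9.15  # degrees N
    day_of_year: int = 75  # mid dry season
    canopy_height: float = 30.0  # m
    leaf_area_index: float = 6.0
    soil_water_potential: float = -0.5  # MPa

    def __post_init__(self) -> None:
        if self.leaf_area_index <= 0:
            raise ValueError("leaf_area_index must be positive")
        if self.canopy_height <= 0:
            raise ValueError("canopy_height must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SiteConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class AtmosphericProfile:
    """Morning atmospheric state summarizing a dawn sounding.

    theta0, q0:   surface potential temperature [K] and specific
                  humidity [kg kg-1] before boundary-layer development.
    gammaT:       free-troposphere potential-temperature lapse rate
                  [K m-1]; must be positive (statically stable).
    gammaq:       free-troposphere specific-humidity lapse rate
                  [kg kg-1 m-1]; typically negative (drier aloft).
    h0:           initial boundary-layer height [m].
    """

    theta0: float = 297.5
    q0: float = 0.016
    gammaT: float = 0.005
    gammaq: float = -2.0e-6
    h0: float = 200.0

    def __post_init__(self) -> None:
        if self.gammaT <= 0:
            raise ValueError("gammaT must be positive (stable free troposphere)")
        if self.h0 <= 0:
            raise ValueError("h0 must be positive")
        if self.q0 < 0:
            raise ValueError("q0 must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "AtmosphericProfile":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class DiurnalForcing:
    """Time-gridded external drivers for one simulated day.

    All arrays share the regular time grid `time` (seconds since local
    midnight).  `ca` is carried per record so a file-based forcing can
    override it, but defaults to the fixed 400 ppm ambient CO2.
    """

    time: np.ndarray  # s since local midnight
    Rsw: np.ndarray  # W m-2 incoming shortwave
    Rlw: np.ndarray  # W m-2 incoming longwave
    fD: np.ndarray  # diffuse fraction of shortwave [0, 1]
    U: np.ndarray  # m s-1 wind at canopy top
    ustar: np.ndarray  # m s-1 friction velocity
    zenith: np.ndarray  # rad solar zenith
    ca: np.ndarray  # mol mol-1 ambient CO2

    COLUMNS = ("time", "Rsw", "Rlw", "fD", "U", "ustar", "zenith", "ca")

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in self.COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"field {name} must have shape ({n},)")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def step(self) -> float:
        return float(self.time[1] - self.time[0])

    def daily_diffuse_fraction(self) -> float:
        """Ratio of daily diffuse to daily total shortwave (clear-day
        screening criterion: < 0.5)."""
        total = np.trapezoid(self.Rsw, self.time)
        diffuse = np.trapezoid(self.fD * self.Rsw, self.time)
        return float(diffuse / total) if total > 0 else 0.0

    def interp(self, t: float) -> dict:
        """Linear interpolation of every driver to time ``t`` [s]."""
        out = {}
        for name in self.COLUMNS[1:]:
            out[name] = float(np.interp(t, self.time, getattr(self, name)))
        out["Rsw"] = max(out["Rsw"], 0.0)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in self.COLUMNS})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DiurnalForcing":
        return cls(**{c: df[c].to_numpy(dtype=float) for c in cls.COLUMNS})

    @classmethod
    def from_csv(cls, path) -> "DiurnalForcing":
        return cls.from_dataframe(pd.read_csv(path))


def solar_declination(day_of_year: int) -> float:
    """Solar declination [rad] from the Spencer Fourier series."""
    g = 2.0 * math.pi * (day_of_year - 1) / 365.0
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def solar_zenith(site: SiteConfig, t) -> np.ndarray | float:
    """Solar zenith angle [rad] at local solar time ``t`` [s since midnight].

    Local clock time is taken as local solar time (the equation of time
    and longitude offset are irrelevant for a generic synthetic day);
    zenith is symmetric about solar noon at 12:00.
    """
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t >= 86400)):
        raise ValueError("t must satisfy 0 <= t < 86400")
    lat = math.radians(site.latitude)
    dec = solar_declination(site.day_of_year)
    hour_angle = math.pi * (t - 43200.0) / 43200.0
    cosz = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * np.cos(
        hour_angle
    )
    z = np.arccos(np.clip(cosz, -1.0, 1.0))
    return float(z) if z.ndim == 0 else z


def clear_sky_irradiance(zenith, transmissivity: float = 0.75):
    """Clear-sky shortwave irradiance and diffuse fraction.

    Total irradiance follows the classic air-mass attenuation
    ``Rsw = S0 * cos(z) * tau**(1/cos(z))``; the diffuse fraction of that
    total is modelled as ``fD = 0.7 * (1 - tau**m)`` — a fixed share of
    the beam depletion reappears as circumsolar/sky diffuse, growing with
    air mass so fD rises toward low sun.

    Returns (Rsw [W m-2], fD [-]); both zero-beam at or below the horizon.
    """
    if not 0.0 < transmissivity <= 1.0:
        raise ValueError("transmissivity must be in (0, 1]")
    zenith = np.asarray(zenith, dtype=float)
    cosz = np.cos(zenith)
    up = cosz > 1e-6
    m = np.where(up, 1.0 / np.where(up, cosz, 1.0), np.inf)
    tau_m = np.where(up, transmissivity ** np.minimum(m, 100.0), 0.0)
    rsw = np.where(up, SOLAR_CONSTANT * cosz * tau_m, 0.0)
    # all-diffuse at and below the horizon (no beam to partition)
    fd = np.where(up, 0.7 * (1.0 - tau_m), 1.0)
    if zenith.ndim == 0:
        return float(rsw), float(fd)
    return rsw, fd


def clear_sky_longwave(theta0: float, q0: float) -> float:
    """Incoming longwave [W m-2] from the Brutsaert clear-sky emissivity
    ``eps = 1.24 (ea/T)^(1/7)`` (ea in hPa) evaluated at the dawn state.

    A constant value over the day is a fair clear-sky tropical
    approximation (the diurnal range of emitted sky radiance is small
    compared to the shortwave cycle)."""
    ea_hpa = q0 * P_SURFACE / 0.622 / 100.0
    eps = 1.24 * (max(ea_hpa, 1e-3) / theta0) ** (1.0 / 7.0)
    eps = min(eps, 1.0)
    return eps * STEFAN_BOLTZMANN * theta0 ** 4


def build_forcing_day(
    site: SiteConfig | None = None,
    step: float = 1800.0,
    profile: AtmosphericProfile | None = None,
    transmissivity: float = 0.75,
    wind_speed: float = 2.0,
    ustar: float = 0.3,
    ca: float = CO2_AMBIENT,
) -> DiurnalForcing:
    """Assemble a full clear-sky forcing day on a regular grid.

    step must divide 86400 s.  Wind speed and friction velocity default
    to constant dry-season daytime values (2 m s-1 and 0.3 m s-1); the
    output is deterministic — two calls with the same configuration are
    bit-identical.
    """
    site = site or SiteConfig()
    profile = profile or AtmosphericProfile()
    if step <= 0 or 86400 % int(step) != 0:
        raise ValueError("step must be a positive divisor of 86400")
    t = np.arange(0, 86400, step, dtype=float)
    zenith = solar_zenith(site, t)
    rsw, fd = clear_sky_irradiance(zenith, transmissivity)
    rlw = np.full_like(t, clear_sky_longwave(profile.theta0, profile.q0))
    u = np.full_like(t, float(wind_speed))
    us = np.full_like(t, float(ustar))
    return DiurnalForcing(
        time=t,
        Rsw=rsw,
        Rlw=rlw,
        fD=fd,
        U=u,
        ustar=us,
        zenith=zenith,
        ca=np.full_like(t, ca),
    )
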