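"""Shared fixtures: scaled-down model configurations and cached runs.

The heavier fixtures (coupled days, experiment sweeps) are session-scoped
so that several tests can interrogate one simulation.  All of them use
reduced spatial/temporal resolution; the qualitative coupling structure
is resolution-independent (see docs/methods.md).
"""

import numpy as np
import pytest

from canopyabl.canopy import CanopyConfig, CanopyModel, TraitParams
from canopyabl.coupler import integrate_day
from canopyabl.experiments import ExperimentConfig
from canopyabl.forcing import AtmosphericProfile, SiteConfig, \
    build_forcing_day


@pytest.fixture(scope="session")
def site():
    return SiteConfig()


@pytest.fixture(scope="session")
def profile():
    return AtmosphericProfile()


@pytest.fixture(scope="session")
def forcing_day(site, profile):
    return build_forcing_day(site, step=1800.0, profile=profile)


@pytest.fixture(scope="session")
def reduced_config():
    return ExperimentConfig.reduced()


@pytest.fixture(scope="session")
def reduced_canopy_config():
    return CanopyConfig(n_layers=12, n_classes=3)


@pytest.fixture(scope="session")
def coupled_day(forcing_day, reduced_canopy_config):
    """One reduced-resolution coupled diurnal run with default traits."""
    return integrate_day(forcing_day, step=600.0,
                         canopy_config=reduced_canopy_config)


@pytest.fixture(scope="session")
def coupled_day_fine(forcing_day, reduced_canopy_config):
    """Same run at half the timestep (discretization-convergence checks)."""
    return integrate_day(forcing_day, step=300.0,
                         canopy_config=reduced_canopy_config)


@pytest.fixture(scope="session")
def small_canopy():
    """Small canopy model for per-step tests."""
    return CanopyModel(CanopyConfig(n_layers=10, n_classes=2))


@pytest.fixture
def noon_forcing(forcing_day):
    return forcing_day.interp(12 * 3600.0)
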