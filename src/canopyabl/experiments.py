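"""End-to-end simulation experiments on canopy-air temperature coupling.

Four experiment sets probe how plant water-use traits shape the
Tcan~Tair relationship:

* ``gs_sweep``    — 30 coupled runs with constant (non-responsive)
                    stomatal conductance, canopy-top values spanning
                    0.085-0.380 mol m-2 s-1: no biological control of
                    ABL dynamics.
* ``kinetics``    — paired coupled runs with stomatal optimization,
                    temperature-dependent vs fixed-25C photosynthetic
                    kinetics: isolates biochemical thermoregulation.
* ``water_cost``  — sweep of the stomatal water-cost parameter cw from
                    1 to 4 umol m-2 s-1 in coupled mode and in
                    prescribed-air (uncoupled) mode, where the air
                    series comes from the least conservative (cw = 1)
                    coupled run.
* ``sensitivity`` — +/-5% elasticities (log-log) of the three coupling
                    metrics to the ABL parameters theta0, gammaT,
                    gammaq, h0 and beta, for two water-cost cases.

Every run is deterministic and reproducible from the recorded
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .abl import EntrainmentParams
from .canopy import CanopyConfig, TraitParams
from .coupler import DiurnalOutput, integrate_day
from .forcing import AtmosphericProfile, DiurnalForcing, SiteConfig, \
    build_forcing_day
from .metrics import CouplingMetrics, coupling_metrics, elasticity

__all__ = ["ExperimentConfig", "run_gs_sweep", "run_kinetics_comparison",
           "run_water_cost_sweep", "run_sensitivity", "run_experiment_set"]

GS_SWEEP_RANGE = (0.085, 0.380)  # mol m-2 s-1, canopy-top values
GS_SWEEP_N = 30
CW_RANGE = (1.0, 4.0)  # umol m-2 s-1
SENSITIVITY_PARAMS = ("theta0", "gammaT", "gammaq", "h0", "beta")


@dataclass
class ExperimentConfig:
    """Shared setup for an experiment set.

    The discretization fields allow scaled-down runs (fewer layers and
    orientation classes, longer timestep) that preserve every qualitative
    coupling feature of the full-resolution model.
    """

    site: SiteConfig = field(default_factory=SiteConfig)
    profile: AtmosphericProfile = field(default_factory=AtmosphericProfile)
    entrainment: EntrainmentParams = field(default_factory=EntrainmentParams)
    traits: TraitParams = field(default_factory=TraitParams)
    n_layers: int = 30
    n_classes: int = 5
    step: float = 60.0
    forcing_step: float = 1800.0

    def forcing(self) -> DiurnalForcing:
        return build_forcing_day(self.site, step=self.forcing_step,
                                 profile=self.profile)

    def canopy_config(self, **overrides) -> CanopyConfig:
        base = dict(n_layers=self.n_layers, n_classes=self.n_classes,
                    total_lai=self.site.leaf_area_index,
                    canopy_height=self.site.canopy_height)
        base.update(overrides)
        return CanopyConfig(**base)

    @classmethod
    def reduced(cls, **kwargs) -> "ExperimentConfig":
        """Scaled-down resolution preset (test/desk scale)."""
        kwargs.setdefault("n_layers", 12)
        kwargs.setdefault("n_classes", 3)
        kwargs.setdefault("step", 600.0)
        return cls(**kwargs)

    def describe(self) -> dict:
        return {
            "site": asdict(self.site),
            "profile": asdict(self.profile),
            "entrainment": asdict(self.entrainment),
            "n_layers": self.n_layers, "n_classes": self.n_classes,
            "step": self.step, "forcing_step": self.forcing_step,
        }


def _run_day(cfg: ExperimentConfig, canopy_cfg: CanopyConfig,
             traits: TraitParams, profile=None, entrainment=None,
             mode: str = "coupled", prescribed=None) -> DiurnalOutput:
    return integrate_day(
        cfg.forcing(), profile=profile or cfg.profile, site=cfg.site,
        canopy_config=canopy_cfg, traits=traits, mode=mode,
        prescribed=prescribed, step=cfg.step,
        entrainment_params=entrainment or cfg.entrainment)


def _metrics_row(out: DiurnalOutput, m: CouplingMetrics) -> dict:
    df = out.frame
    return {
        "max_tcan": m.max_tcan, "slope": m.slope, "lag": m.lag,
        "lag_magnitude": abs(m.lag),
        "h_max": float(df["h"].max()),
        "le_midday": float(df["LE"].max()),
        "h_flux_midday": float(df["H"].max()),
        "vpd_max": float(df["VPD"].max()),
        "gpp_total_mol": float(np.trapezoid(df["GPP"], df["time"]) * 1e-6),
    }


def run_gs_sweep(cfg: ExperimentConfig | None = None, n: int = GS_SWEEP_N,
                 gs_range: tuple[float, float] = GS_SWEEP_RANGE,
                 keep_outputs: bool = False):
    """Constant-gs experiment: n coupled runs spanning gs_range."""
    cfg = cfg or ExperimentConfig()
    rows, outputs = [], []
    for gs_top in np.linspace(gs_range[0], gs_range[1], n):
        canopy_cfg = cfg.canopy_config(gs_mode="constant",
                                       gs_top=float(gs_top))
        out = _run_day(cfg, canopy_cfg, cfg.traits)
        m = coupling_metrics(out)
        rows.append({"gs_top": float(gs_top), **_metrics_row(out, m)})
        if keep_outputs:
            outputs.append(out)
    table = pd.DataFrame(rows)
    return (table, outputs) if keep_outputs else table


def run_kinetics_comparison(cfg: ExperimentConfig | None = None):
    """Thermoregulation experiment: temperature-dependent vs fixed-25C
    kinetics, both with stomatal optimization.

    Returns (table, {"variable": out, "fixed": out}); the headline
    number is max_tcan(fixed) - max_tcan(variable), the canopy cooling
    attributable to kinetics-aware stomatal regulation.
    """
    cfg = cfg or ExperimentConfig()
    outs = {}
    rows = []
    for label, tdep in (("variable", True), ("fixed", False)):
        traits = TraitParams(
            photosynthesis=replace(cfg.traits.photosynthesis,
                                   temperature_dependent=tdep),
            hydraulics=cfg.traits.hydraulics)
        out = _run_day(cfg, cfg.canopy_config(gs_mode="optimized"), traits)
        m = coupling_metrics(out)
        outs[label] = out
        rows.append({"kinetics": label, **_metrics_row(out, m)})
    table = pd.DataFrame(rows)
    table.attrs["thermoregulation_dTmax"] = float(
        table.loc[table.kinetics == "fixed", "max_tcan"].iloc[0]
        - table.loc[table.kinetics == "variable", "max_tcan"].iloc[0])
    return table, outs


def run_water_cost_sweep(cfg: ExperimentConfig | None = None,
                         cw_values=None, keep_outputs: bool = False):
    """Water-cost sweep in coupled and prescribed-air modes.

    The uncoupled runs are driven by the (Tair, qair) series of the
    least conservative coupled run (lowest cw).
    """
    cfg = cfg or ExperimentConfig()
    if cw_values is None:
        cw_values = np.linspace(CW_RANGE[0], CW_RANGE[1], 7)
    cw_values = np.sort(np.asarray(cw_values, dtype=float))
    canopy_cfg = cfg.canopy_config(gs_mode="optimized")
    rows, outputs = [], {}

    coupled_outs = {}
    for cw in cw_values:
        traits = TraitParams(
            photosynthesis=cfg.traits.photosynthesis,
            hydraulics=replace(cfg.traits.hydraulics, cw=float(cw)))
        out = _run_day(cfg, canopy_cfg, traits)
        coupled_outs[float(cw)] = out
        m = coupling_metrics(out)
        rows.append({"cw": float(cw), "mode": "coupled",
                     **_metrics_row(out, m)})

    air = coupled_outs[float(cw_values[0])].frame[["time", "Tair", "qair"]]
    for cw in cw_values:
        traits = TraitParams(
            photosynthesis=cfg.traits.photosynthesis,
            hydraulics=replace(cfg.traits.hydraulics, cw=float(cw)))
        out = _run_day(cfg, canopy_cfg, traits, mode="prescribed_air",
                       prescribed=air)
        m = coupling_metrics(out)
        rows.append({"cw": float(cw), "mode": "prescribed_air",
                     **_metrics_row(out, m)})
        if keep_outputs:
            outputs[(float(cw), "prescribed_air")] = out
    if keep_outputs:
        outputs.update({(cw, "coupled"): o for cw, o in coupled_outs.items()})
        return pd.DataFrame(rows), outputs
    return pd.DataFrame(rows)


def run_sensitivity(cfg: ExperimentConfig | None = None,
                    cw_cases: tuple[float, float] = (1.0, 4.0),
                    perturbation: float = 0.05) -> pd.DataFrame:
    """Elasticity table of the coupling metrics to the ABL parameters.

    For each parameter in (theta0, gammaT, gammaq, h0, beta), runs the
    coupled day at (1 +/- perturbation) times its default and forms
    sigma = log(y1/y2)/log(x1/x2) per metric, for each water-cost case.
    """
    cfg = cfg or ExperimentConfig()
    canopy_cfg = cfg.canopy_config(gs_mode="optimized")
    rows = []
    for cw in cw_cases:
        traits = TraitParams(
            photosynthesis=cfg.traits.photosynthesis,
            hydraulics=replace(cfg.traits.hydraulics, cw=float(cw)))

        def make_run_fn(param):
            def run_fn(value):
                prof, entr = cfg.profile, cfg.entrainment
                if param == "beta":
                    entr = replace(entr, beta=value)
                else:
                    prof = replace(prof, **{param: value})
                out = _run_day(cfg, canopy_cfg, traits, profile=prof,
                               entrainment=entr)
                return coupling_metrics(out)
            return run_fn

        for param in SENSITIVITY_PARAMS:
            default = (cfg.entrainment.beta if param == "beta"
                       else getattr(cfg.profile, param))
            for res in elasticity(make_run_fn(param), param, default,
                                  perturbation):
                rows.append({"cw": float(cw), "parameter": param,
                             "metric": res.metric, "sigma": res.sigma,
                             "y1": res.y1, "y2": res.y2,
                             "defined": res.defined})
    return pd.DataFrame(rows)


def run_experiment_set(name: str, cfg: ExperimentConfig | None = None,
                       **kwargs):
    """Dispatch one of the four named experiment sets."""
    runners = {
        "gs_sweep": run_gs_sweep,
        "kinetics": run_kinetics_comparison,
        "water_cost": run_water_cost_sweep,
        "sensitivity": run_sensitivity,
    }
    if name not in runners:
        raise KeyError(f"unknown experiment set '{name}'; "
                       f"choose from {sorted(runners)}")
    return runners[name](cfg, **kwargs)
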