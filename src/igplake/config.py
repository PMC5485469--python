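"""Run configuration: schema, defaults, validation, YAML parsing.

A single :class:`RunConfig` document drives every run.  Unknown keys are
rejected, the Z1 diet preferences must sum to 1, and the handful of
literature-sourced defaults (g_max = 3.03, preferences 0.5/0.35/0.15,
vulnerabilities 0.4/0.5/0.02, exploitation 28/0 % yr-1, 12 cm commercial
length) are pre-filled; everything else is an uncalibrated desk-scale
stand-in flagged as such in the methods note.
"""

from __future__ import annotations

import datetime as _dt
import hashlib

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .fish import FishParams
from .forcing import ForcingConfig, WetWinterEvent, generate_forcing
from .grid import ColumnGrid
from .plankton import GrazingParams, PhytoParams, PlanktonParams

__all__ = ["RunConfig", "ConfigError", "parse_config"]

_FC = ForcingConfig()
_PP = PlanktonParams()
_GP = GrazingParams()
_PH = PhytoParams()
_FP = FishParams()


class ConfigError(ValueError):
    """Invalid or unparsable run configuration."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WetWinterBlock(_Block):
    winter_year: int
    rise_m: float = Field(gt=0.0)


class ForcingBlock(_Block):
    t_min: float = _FC.t_min
    t_max: float = _FC.t_max
    t_phase_day: int = _FC.t_phase_day
    t_noise_sd: float = _FC.t_noise_sd
    ar1_rho: float = _FC.ar1_rho
    par_mean: float = _FC.par_mean
    par_amp: float = _FC.par_amp
    par_phase_day: int = _FC.par_phase_day
    par_noise_sd: float = _FC.par_noise_sd
    level_base: float = _FC.level_base
    level_amp: float = _FC.level_amp
    level_phase_day: int = _FC.level_phase_day
    event_ramp_days: int = _FC.event_ramp_days
    nutrient_load_base: float = _FC.nutrient_load_base
    nutrient_load_winter_factor: float = _FC.nutrient_load_winter_factor
    mld_summer: float = _FC.mld_summer
    mld_winter: float = _FC.mld_winter
    strat_start_doy: int = _FC.strat_start_doy
    strat_end_doy: int = _FC.strat_end_doy
    wet_winters: list[WetWinterBlock] = Field(default_factory=list)


class GridBlock(_Block):
    depth: float = 40.0
    n_layers: int = Field(default=10, ge=2)
    surface_area: float = 1.66e8
    total_volume: float = 4.0e9


class PhysicsBlock(_Block):
    hypo_temp: float = 15.0
    mixed_exchange: float = 5.0
    thermocline_exchange: float = 0.02


class PhytoBlock(_Block):
    mu_max: float = _PH.mu_max
    k_n: float = _PH.k_n
    i_k: float = _PH.i_k
    resp: float = _PH.resp
    mort: float = _PH.mort


class Z1Block(_Block):
    g_max: float = _GP.g_max
    pref_z3: float = _GP.pref_z3
    pref_z2: float = _GP.pref_z2
    pref_self: float = _GP.pref_self
    k_graz: float = _GP.k_graz
    assim: float = _GP.assim
    theta: float = _GP.theta
    t_ref: float = _GP.t_ref

    @model_validator(mode="after")
    def _prefs_sum(self):
        s = self.pref_z3 + self.pref_z2 + self.pref_self
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"z1 preferences must sum to 1 (got {s})")
        return self


class PlanktonBlock(_Block):
    phyto: PhytoBlock = Field(default_factory=PhytoBlock)
    z1: Z1Block = Field(default_factory=Z1Block)
    z2_gmax: float = _PP.z2_gmax
    z2_k: float = _PP.z2_k
    z2_assim: float = _PP.z2_assim
    z3_gmax: float = _PP.z3_gmax
    z3_k: float = _PP.z3_k
    z3_assim: float = _PP.z3_assim
    z3_pref_a: float = _PP.z3_pref_a
    z3_pref_d: float = _PP.z3_pref_d
    zoo_resp: float = _PP.zoo_resp
    zoo_mort: float = _PP.zoo_mort
    remin_rate: float = _PP.remin_rate
    burial_frac: float = _PP.burial_frac
    p_to_c: float = _PP.p_to_c
    k_ext: float = _PP.k_ext
    theta: float = _PP.theta
    t_ref: float = _PP.t_ref


class FishBlock(_Block):
    vuln_z1: float = _FP.vuln_z1
    vuln_z2: float = _FP.vuln_z2
    vuln_z3: float = _FP.vuln_z3
    k_fish: float = _FP.k_fish
    cmax_a: float = _FP.cmax_a
    cmax_b: float = _FP.cmax_b
    theta: float = _FP.theta
    t_ref: float = _FP.t_ref
    egestion_frac: float = _FP.egestion_frac
    excretion_frac: float = _FP.excretion_frac
    sda_frac: float = _FP.sda_frac
    resp_frac: float = _FP.resp_frac
    resp_basal: float = _FP.resp_basal
    repro_frac: float = _FP.repro_frac
    repro_doy: int = _FP.repro_doy
    maturity_length_cm: float = _FP.maturity_length_cm
    natural_mortality: float = _FP.natural_mortality
    commercial_length_cm: float = _FP.commercial_length_cm
    exploit_commercial: float = Field(default=_FP.exploit_commercial, ge=0, le=100)
    exploit_noncommercial: float = Field(default=_FP.exploit_noncommercial,
                                         ge=0, le=100)
    carbon_to_ww: float = _FP.carbon_to_ww
    lw_alpha: float = _FP.lw_alpha
    lw_beta: float = _FP.lw_beta
    starvation_frac: float = _FP.starvation_frac
    t_opt: float = _FP.t_opt
    t_sigma: float = _FP.t_sigma
    habitat_t_tol: float = _FP.habitat_t_tol
    recruit_rise_threshold: float = _FP.recruit_rise_threshold
    recruit_mult_slope: float = _FP.recruit_mult_slope
    recruit_per_adult: float = _FP.recruit_per_adult
    recruit_weight: float = _FP.recruit_weight
    recruit_n_super: int = _FP.recruit_n_super


class ScenarioBlock(_Block):
    n_super: int = Field(default=1000, ge=0)
    fish_per_super: float = Field(default=100_000.0, ge=0)
    spinup_years: int = 1
    init_mean_weight: float = 12.0
    init_weight_cv: float = 0.5


class InitBlock(_Block):
    a: float = 0.15
    n: float = 0.01
    d: float = 0.05
    z1: float = 0.01
    z2: float = 0.05
    z3: float = 0.02


class RunConfig(_Block):
    """Top-level, schema-validated run configuration."""

    seed: int = 1
    start_date: _dt.date = _dt.date(1997, 1, 1)
    end_date: _dt.date = _dt.date(2003, 9, 30)
    forcing: ForcingBlock = Field(default_factory=ForcingBlock)
    grid: GridBlock = Field(default_factory=GridBlock)
    physics: PhysicsBlock = Field(default_factory=PhysicsBlock)
    plankton: PlanktonBlock = Field(default_factory=PlanktonBlock)
    fish: FishBlock = Field(default_factory=FishBlock)
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    init: InitBlock = Field(default_factory=InitBlock)

    # -- builders for the runtime parameter objects ------------------------
    def to_forcing_config(self) -> ForcingConfig:
        d = self.forcing.model_dump()
        events = tuple(WetWinterEvent(**e) for e in d.pop("wet_winters"))
        return ForcingConfig(wet_winters=events, **d)

    def generate_forcing(self, seed: int):
        return generate_forcing(self.to_forcing_config(), self.start_date,
                                self.end_date, seed)

    def to_grid(self) -> ColumnGrid:
        return ColumnGrid.frustum(**self.grid.model_dump())

    def to_plankton_params(self) -> PlanktonParams:
        d = self.plankton.model_dump()
        return PlanktonParams(phyto=PhytoParams(**d.pop("phyto")),
                              z1=GrazingParams(**d.pop("z1")), **d)

    def to_fish_params(self) -> FishParams:
        return FishParams(**self.fish.model_dump())

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty file yields the full default configuration.  Schema
    violations raise :class:`ConfigError` naming the offending key.
    """
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return RunConfig(**data)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(f"invalid configuration: {exc}") from exc
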