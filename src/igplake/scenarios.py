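"""Scenario engine: fish multipliers, one-at-a-time sensitivity,
biomanipulation.

Three experiment families over the coupled model:

* fish-abundance multipliers — the count represented by each
  super-individual scales x1 / x2 / ... / x8 while everything else,
  including the seed, stays fixed, so differences are attributable to
  fish abundance alone;
* one-at-a-time sensitivity — the four key IGP parameters (Z1 maximum
  predation rate g_max, Z1 self-predation preference P_zk1, and the
  vulnerabilities of predatory and herbivorous zooplankton to fish, V_11
  and V_12) perturbed by +-50%, with the micro-zooplankton preference
  absorbing the complement so the Z1 diet preferences keep summing to 1;
  the response metric is the mean herbivore concentration over the run
  after a spin-up year;
* biomanipulation — the x8 ("atypical year") scenario rerun with heavy
  size-selective harvest (non-commercial exploitation 0 -> 50,
  commercial 28 -> 50 % yr-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import ConfigError, RunConfig
from .ledger import PredationLedger, annual_channel_totals, build_scenario_table
from .simulate import SimulationResult, run_simulation

__all__ = [
    "ScenarioSpec",
    "SensitivityResult",
    "make_multiplier_scenario",
    "perturb_parameter",
    "run_scenario",
    "run_multiplier_suite",
    "run_sensitivity_suite",
    "run_biomanipulation",
]

log = logging.getLogger(__name__)

SENSITIVITY_PARAMETERS = ("g_max", "P_zk1", "V_11", "V_12")


@dataclass
class ScenarioSpec:
    """One named experiment: a config transform plus a label."""

    label: str
    fish_per_super: float = 100_000.0
    n_super: int = 1000
    overrides: dict = field(default_factory=dict)  # dotted path -> value
    seed: int | None = None

    @property
    def total_fish(self) -> float:
        return self.n_super * self.fish_per_super


@dataclass
class SensitivityResult:
    parameter: str
    factor: float
    mean_z2: float
    percent_change: float
    failed: bool = False


def make_multiplier_scenario(base: ScenarioSpec, m: int) -> ScenarioSpec:
    """Scale the fish count per super-individual by an integer m >= 1."""
    if m < 1:
        raise ValueError("multiplier must be >= 1")
    return ScenarioSpec(label=f"x{m}", fish_per_super=base.fish_per_super * m,
                        n_super=base.n_super, overrides=dict(base.overrides),
                        seed=base.seed)


def _set_path(cfg: RunConfig, path: str, value) -> None:
    obj = cfg
    parts = path.split(".")
    for p in parts[:-1]:
        if not hasattr(obj, p):
            raise ConfigError(f"unknown config path {path!r}")
        obj = getattr(obj, p)
    if not hasattr(obj, parts[-1]):
        raise ConfigError(f"unknown config path {path!r}")
    setattr(obj, parts[-1], value)


def perturb_parameter(config: RunConfig, name: str, factor: float) -> RunConfig:
    """Return a config with one IGP parameter scaled by ``factor``.

    Scaling the Z1 self-predation preference (P_zk1) adjusts the
    micro-zooplankton preference so the three preferences still sum to 1,
    leaving the herbivore preference untouched.
    """
    cfg = config.model_copy(deep=True)
    z1 = cfg.plankton.z1
    if name == "g_max":
        z1.g_max = z1.g_max * factor
    elif name == "P_zk1":
        new_self = z1.pref_self * factor
        new_z3 = 1.0 - new_self - z1.pref_z2
        if not (0.0 <= new_self <= 1.0 and 0.0 <= new_z3 <= 1.0):
            raise ConfigError(
                f"perturbed preferences outside [0,1]: self={new_self}, z3={new_z3}")
        z1.pref_self = new_self
        z1.pref_z3 = new_z3
    elif name == "V_11":
        cfg.fish.vuln_z1 = cfg.fish.vuln_z1 * factor
    elif name == "V_12":
        cfg.fish.vuln_z2 = cfg.fish.vuln_z2 * factor
    else:
        raise ConfigError(f"unknown sensitivity parameter {name!r}")
    return cfg


def apply_spec(config: RunConfig, spec: ScenarioSpec) -> RunConfig:
    cfg = config.model_copy(deep=True)
    cfg.scenario.fish_per_super = spec.fish_per_super
    cfg.scenario.n_super = spec.n_super
    for path, value in spec.overrides.items():
        _set_path(cfg, path, value)
    if spec.seed is not None:
        cfg.seed = spec.seed
    return cfg


def run_scenario(config: RunConfig, spec: ScenarioSpec) -> SimulationResult:
    return run_simulation(apply_spec(config, spec))


def mean_z2(result: SimulationResult, spinup_years: int) -> float:
    return result.annual_mean("conc_z2", spinup_years)


def ledger_of(result: SimulationResult, config: RunConfig) -> PredationLedger:
    return PredationLedger.from_daily_carbon(
        result.ledger, result.grid.total_volume, config.fish.carbon_to_ww)


def run_multiplier_suite(config: RunConfig, multipliers=(1, 2, 8),
                         results: dict | None = None):
    """Run the fish-abundance multiplier scenarios and build the annual
    scenario table (base = x1).  Pre-computed results may be passed in
    (label -> SimulationResult) to avoid re-running."""
    base = ScenarioSpec(label="x1", fish_per_super=config.scenario.fish_per_super,
                        n_super=config.scenario.n_super)
    results = dict(results or {})
    for m in multipliers:
        spec = make_multiplier_scenario(base, m)
        if spec.label not in results:
            log.info("running scenario %s (%g fish)", spec.label, spec.total_fish)
            results[spec.label] = run_scenario(config, spec)
    spin = config.scenario.spinup_years
    totals = {f"x{m}": annual_channel_totals(ledger_of(results[f"x{m}"], config),
                                             spinup_years=spin)
              for m in multipliers}
    table = build_scenario_table(totals, base_label="x1")
    return table, results


def run_sensitivity_suite(config: RunConfig, seed: int | None = None,
                          base_result: SimulationResult | None = None,
                          parameters=SENSITIVITY_PARAMETERS,
                          factors=(0.5, 1.5)) -> list[SensitivityResult]:
    """One-at-a-time +-50% sensitivity of the mean herbivore concentration.

    All runs share one seed so differences are attributable to the
    perturbed parameter.  Aborting runs are reported with a failure flag
    rather than failing the suite.
    """
    if seed is not None:
        config = config.model_copy(deep=True)
        config.seed = seed
    spin = config.scenario.spinup_years
    if base_result is None:
        base_result = run_simulation(config)
    base_mean = mean_z2(base_result, spin)
    out = [SensitivityResult("base", 1.0, base_mean, 0.0)]
    for name in parameters:
        for factor in factors:
            try:
                res = run_simulation(perturb_parameter(config, name, factor))
                mz = mean_z2(res, spin)
                pct = 100.0 * (mz - base_mean) / base_mean
                out.append(SensitivityResult(name, factor, mz, pct))
            except (ArithmeticError, ConfigError) as exc:
                log.error("sensitivity run %s x%g failed: %s", name, factor, exc)
                out.append(SensitivityResult(name, factor, float("nan"),
                                             float("nan"), failed=True))
    return out


def run_biomanipulation(config: RunConfig, multiplier: int = 8,
                        before_result: SimulationResult | None = None):
    """Biomanipulation experiment on the high-fish (x8) scenario.

    The 'before' run keeps the standard exploitation (commercial 28,
    non-commercial 0 % yr-1); the 'after' run raises both to 50 % yr-1.
    Returns ``(before, after)`` simulation results.
    """
    base = ScenarioSpec(label="x1", fish_per_super=config.scenario.fish_per_super,
                        n_super=config.scenario.n_super)
    spec = make_multiplier_scenario(base, multiplier)
    if before_result is None:
        before_result = run_scenario(config, spec)
    after_cfg = apply_spec(config, spec)
    after_cfg.fish.exploit_commercial = 50.0
    after_cfg.fish.exploit_noncommercial = 50.0
    after_result = run_simulation(after_cfg)
    return before_result, after_result
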