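"""Coupled advancement of the plankton column and the fish population.

Operator-split two-timescale scheme: 24 hourly plankton substeps per day,
then one daily fish step (redistribute, consume from the end-of-day
plankton state, grow, die).  Fish egestion and mortality return carbon to
the detritus pool of the fish's layer, excretion and respiration release
nutrient and respired carbon, so the whole system closes: organic carbon
plus cumulative respired, buried and harvested carbon minus cumulative
fixed (GPP) and recruited carbon is conserved.

The six intraguild-predation fluxes are recorded every day: Z1_z1, Z1_z2,
Z1_z3 (predatory-zooplankton predation on the three zooplankton groups,
from the plankton stage) and F_z1, F_z2, F_z3 (fish predation, from the
fish stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import plankton as pk
from .fish import (FishParams, FishPopulation, bioenergetics_update,
                   fish_consumption, apply_mortality, recruitment_event,
                   redistribute_vertical)
from .forcing import ForcingSeries, water_level_rise
from .grid import ColumnGrid, PhysicsState, temperature_profile
from .plankton import PlanktonParams, PlanktonState, step_plankton, day_environment

__all__ = ["SimulationSetup", "SimulationResult", "advance_day", "run_simulation"]

log = logging.getLogger(__name__)

PLANKTON_SUBSTEPS = 24          # 1 h plankton step inside the daily fish step
_FLOOR = 1.0 - 1e-12            # demand-limiter headroom


@dataclass
class SimulationSetup:
    """Everything :func:`advance_day` needs besides the evolving state."""

    grid: ColumnGrid
    plankton: PlanktonParams
    fish: FishParams
    hypo_temp: float = 15.0
    mixed_exchange: float = 5.0
    thermocline_exchange: float = 0.02


@dataclass
class SimulationResult:
    """Run bundle: daily ledger, final states, bookkeeping counters."""

    ledger: pd.DataFrame
    state: PlanktonState
    population: FishPopulation | None
    forcing: ForcingSeries
    grid: ColumnGrid
    seed: int
    limiter_events: int = 0
    counters: dict = field(default_factory=dict)
    last_fluxes: "pk.FluxRecord | None" = None

    def annual_mean(self, column: str, spinup_years: int = 0) -> float:
        """Mean of a daily ledger column after discarding spin-up years."""
        idx = self.ledger.index
        cutoff = idx[0] + pd.DateOffset(years=spinup_years)
        return float(self.ledger.loc[idx >= cutoff, column].mean())


def _fish_step(state: PlanktonState, pop: FishPopulation,
               physics: PhysicsState, setup: SimulationSetup,
               repro_pulse: bool) -> dict:
    """One daily fish step; mutates ``state.y`` and ``pop`` in place.

    Returns lake-wide carbon fluxes (gC day-1) and limiter diagnostics.
    """
    grid = state.grid
    fp = setup.fish
    pc = setup.plankton.p_to_c
    c2w = fp.carbon_to_ww
    vols = grid.layer_volumes
    out = {"f_z1": 0.0, "f_z2": 0.0, "f_z3": 0.0, "fish_respired": 0.0,
           "harvest_c": 0.0, "limited": 0}

    pop.compact()
    if pop.n_super == 0 or pop.total_count() <= 0.0:
        return out

    prey = np.stack([state.z1, state.z2, state.z3])     # (3, L) mgC L-1
    redistribute_vertical(pop, prey, physics.layer_temp, fp)

    m = pop.alive
    lay = pop.layer[m]
    w = pop.weight[m]
    cnt = pop.count[m]
    T = physics.layer_temp[lay]
    intake = fish_consumption(
        w, {"z1": prey[0, lay], "z2": prey[1, lay], "z3": prey[2, lay]}, T, fp)
    per_prey = np.stack([intake["z1"], intake["z2"], intake["z3"]])  # gC d-1 fish-1

    # aggregate demand per (prey, layer) and scale to what the layer holds
    demand = np.zeros((3, grid.n_layers))
    for i in range(3):
        np.add.at(demand[i], lay, per_prey[i] * cnt)    # gC day-1
    removal = demand / vols                              # mgC L-1 day-1
    avail = prey * _FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(removal > avail,
                         avail / np.where(removal > 0, removal, 1.0), 1.0)
    if (scale < 1.0).any():
        out["limited"] = int((scale < 1.0).sum())
        log.warning("fish demand exceeded standing prey in %d (prey, layer) "
                    "cells; demand scaled to availability", out["limited"])
    per_prey = per_prey * scale[:, lay]
    realised = per_prey.sum(axis=0)

    # remove eaten prey from the water column
    eaten = np.zeros((3, grid.n_layers))
    for i in range(3):
        np.add.at(eaten[i], lay, per_prey[i] * cnt)
    state.y[pk.POOL_Z1] -= eaten[0] / vols
    state.y[pk.POOL_Z2] -= eaten[1] / vols
    state.y[pk.POOL_Z3] -= eaten[2] / vols
    out["f_z1"], out["f_z2"], out["f_z3"] = (float(e.sum()) for e in eaten)

    # bioenergetics; spawning restricted to adults
    pulse = (pop.length[m] >= fp.maturity_length_cm) if repro_pulse else False
    new_w, fx = bioenergetics_update(w, realised, T, fp, repro_pulse=pulse)

    def to_layers(amount_per_fish):
        lake = np.zeros(grid.n_layers)
        np.add.at(lake, lay, amount_per_fish * cnt)
        return lake

    egest = to_layers(fx["egestion"] + fx["reproduction"])   # gC day-1
    metab = to_layers(fx["excretion"] + fx["respiration"])
    state.y[pk.POOL_D] += egest / vols
    state.y[pk.POOL_N] += pc * metab / vols
    out["fish_respired"] = float(metab.sum())

    pop.weight[m] = new_w
    pop.length[m] = np.maximum(pop.length[m], fp.length_from_weight(new_w))
    for i, key in enumerate(("z1", "z2", "z3")):
        pop.consumed[key] += float(eaten[i].sum())

    # starvation: below a fraction of the length-expected weight
    expect = fp.weight_from_length(pop.length[m])
    starving = (new_w <= 0.0) | (new_w < fp.starvation_frac * expect)
    if starving.any():
        idx = np.flatnonzero(m)[starving]
        dead_c = np.zeros(grid.n_layers)
        np.add.at(dead_c, pop.layer[idx],
                  pop.count[idx] * pop.weight[idx] * c2w)
        state.y[pk.POOL_D] += dead_c / vols
        pop.alive[idx] = False
        pop.count[idx] = 0.0

    # natural + fishing mortality on the counts
    mort = apply_mortality(pop, 1.0, fp)
    nat_c = np.zeros(grid.n_layers)
    np.add.at(nat_c, mort["layers"],
              mort["natural_by_si"] * pop.weight[pop.alive] * c2w)
    state.y[pk.POOL_D] += nat_c / vols
    out["harvest_c"] = mort["harvested_ww"] * c2w

    if (state.y < 0.0).any():
        raise ArithmeticError("fish feedback produced a negative pool")
    return out


def advance_day(state: PlanktonState, pop: FishPopulation | None,
                physics: PhysicsState, forcing_day, setup: SimulationSetup,
                repro_pulse: bool = False):
    """Advance the coupled system by one day.

    Runs ``PLANKTON_SUBSTEPS`` hourly plankton substeps, then the daily
    fish step against the end-of-day plankton state (operator splitting;
    order fixed so runs are bit-reproducible per seed).  Returns the new
    plankton state, the population, and a flat record of the day's fluxes
    and summaries (lake-wide carbon fluxes in gC day-1).
    """
    env = day_environment(physics, forcing_day, setup.plankton, state.grid)
    dt = 1.0 / PLANKTON_SUBSTEPS
    fluxes = None
    for _ in range(PLANKTON_SUBSTEPS):
        state, rec = step_plankton(state, physics, forcing_day, dt,
                                   setup.plankton, env=env)
        fluxes = rec if fluxes is None else fluxes + rec

    state = state.copy()        # decouple before in-place fish feedback
    fish_out = _fish_step(state, pop, physics, setup, repro_pulse) if pop is not None \
        else {"f_z1": 0.0, "f_z2": 0.0, "f_z3": 0.0, "fish_respired": 0.0,
              "harvest_c": 0.0, "limited": 0}

    vols = state.grid.layer_volumes
    lake = lambda name: float(fluxes.channel(name) @ vols)  # mgC L-1 -> gC
    record = {
        "z1_z1": lake("gz1_z1"), "z1_z2": lake("gz1_z2"), "z1_z3": lake("gz1_z3"),
        "f_z1": fish_out["f_z1"], "f_z2": fish_out["f_z2"], "f_z3": fish_out["f_z3"],
        "z2_nonpred": lake("z2_resp") + lake("z2_mort"),
        "gpp": float(fluxes.fixed_carbon() @ vols),
        "respired": float(fluxes.respired_carbon() @ vols) + fish_out["fish_respired"],
        "buried": float(fluxes.buried_carbon() @ vols),
        "harvest_c": fish_out["harvest_c"],
        "limited": fish_out["limited"],
        "conc_a": state.volume_weighted(pk.POOL_A),
        "conc_n": state.volume_weighted(pk.POOL_N),
        "conc_d": state.volume_weighted(pk.POOL_D),
        "conc_z1": state.volume_weighted(pk.POOL_Z1),
        "conc_z2": state.volume_weighted(pk.POOL_Z2),
        "conc_z3": state.volume_weighted(pk.POOL_Z3),
        "fish_count": pop.total_count() if pop is not None else 0.0,
        "fish_biomass_ww": pop.total_biomass_ww() if pop is not None else 0.0,
    }
    return state, pop, record, fluxes


def run_simulation(config, seed: int | None = None) -> SimulationResult:
    """Run the coupled model over the configured span.

    ``config`` is a :class:`igplake.config.RunConfig`.  ``seed`` overrides
    the configured seed.  The forcing generator and the fish population
    draw from independent streams derived from the one seed, so the whole
    trajectory is reproducible from ``(config, seed)``.
    """
    from .config import RunConfig  # local import to avoid a cycle

    if not isinstance(config, RunConfig):
        raise TypeError("config must be a RunConfig")
    seed = int(config.seed if seed is None else seed)

    grid = config.to_grid()
    setup = SimulationSetup(
        grid=grid,
        plankton=config.to_plankton_params(),
        fish=config.to_fish_params(),
        hypo_temp=config.physics.hypo_temp,
        mixed_exchange=config.physics.mixed_exchange,
        thermocline_exchange=config.physics.thermocline_exchange,
    )
    forcing = config.generate_forcing(seed)
    state = PlanktonState.uniform(grid, **config.init.model_dump())
    pop = None
    if config.scenario.n_super > 0:
        pop = FishPopulation.initialise(
            setup.fish, n_super=config.scenario.n_super,
            fish_per_super=config.scenario.fish_per_super,
            seed=(2 * seed + 1) % (2**31), n_layers=grid.n_layers,
            mean_weight=config.scenario.init_mean_weight,
            weight_cv=config.scenario.init_weight_cv)

    records = []
    recruit_c = 0.0
    limiter_events = 0
    c2w = setup.fish.carbon_to_ww
    initial_carbon = state.total_carbon() + (
        pop.total_biomass_ww() * c2w if pop is not None else 0.0)
    for date in forcing.dates:
        day = forcing.day(date)
        physics = temperature_profile(day, grid, setup.hypo_temp,
                                      setup.mixed_exchange,
                                      setup.thermocline_exchange)
        if pop is not None and (date.month, date.day) == (4, 30):
            rise = water_level_rise(forcing, date.year)
            before = pop.total_count()
            added = recruitment_event(pop, rise, setup.fish, grid.n_layers)
            recruit_c += added * setup.fish.recruit_weight * c2w
            log.info("recruitment on %s: rise %.2f m, %.3g recruits "
                     "(stock %.3g)", date.date(), rise, added, before)
        repro = pop is not None and day.name.dayofyear == setup.fish.repro_doy
        state, pop, rec, fluxes = advance_day(state, pop, physics, day, setup,
                                              repro_pulse=repro)
        limiter_events += rec["limited"]
        rec["recruit_c"] = recruit_c
        records.append(rec)

    ledger = pd.DataFrame(records, index=forcing.dates).astype(float)
    ledger.index.name = "date"
    counters = {
        "initial_carbon": initial_carbon,
        "recruit_carbon": recruit_c,
        "harvested_ww": pop.harvested_ww if pop is not None else 0.0,
        "fish_carbon": (pop.total_biomass_ww() * c2w) if pop is not None else 0.0,
    }
    return SimulationResult(ledger=ledger, state=state, population=pop,
                            forcing=forcing, grid=grid, seed=seed,
                            limiter_events=limiter_events, counters=counters,
                            last_fluxes=fluxes)
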