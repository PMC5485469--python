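"""Individual-based zooplanktivorous fish population (Lavnun-type).

The population is a set of "super-individuals": each carries a wet weight
``W`` (g), a length (cm, from an allometric length--weight relation), a
``count`` of identical real fish it represents, and a current layer.  The
state lives in flat numpy arrays so a thousand super-individuals cost a
handful of vector operations per day.

Daily processes: stochastic vertical redistribution towards layers with
high vulnerability-weighted prey density and suitable temperature;
multi-prey consumption capped by an allometric, temperature-scaled
maximum daily ration; a bioenergetics mass balance (growth = consumption
minus respiration, egestion, excretion, specific dynamic action and
reproduction); deterministic-rate natural and size-selective fishing
mortality applied to the counts; and an annual water-level-driven
recruitment pulse emulating flood-year spawning success.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .plankton import temp_scale

__all__ = [
    "FishParams",
    "FishPopulation",
    "fish_consumption",
    "bioenergetics_update",
    "redistribute_vertical",
    "recruitment_event",
    "apply_mortality",
    "recruitment_multiplier",
]

log = logging.getLogger(__name__)


@dataclass
class FishParams:
    """Bioenergetics and population parameters.

    The prey vulnerabilities (0.4 / 0.5 / 0.02 for predatory, herbivorous
    and micro-zooplankton), the 12 cm commercial-size threshold and the
    28 %·yr-1 commercial exploitation rate are literature values; the
    allometric and loss coefficients are uncalibrated desk-scale defaults.
    """

    vuln_z1: float = 0.4
    vuln_z2: float = 0.5
    vuln_z3: float = 0.02
    k_fish: float = 0.10          # mgC L-1 half saturation on effective prey
    cmax_a: float = 0.007        # gC day-1 at W = 1 g
    cmax_b: float = 0.725         # allometric exponent on W
    theta: float = 2.0            # Q10 of the maximum ration
    t_ref: float = 20.0
    egestion_frac: float = 0.15   # of consumption
    excretion_frac: float = 0.08
    sda_frac: float = 0.12        # specific dynamic action, respired
    resp_frac: float = 0.20       # activity respiration, of consumption
    resp_basal: float = 0.012     # g_ww g-1 day-1 at t_ref, temperature scaled
    repro_frac: float = 0.08      # annual weight fraction spawned by adults
    repro_doy: int = 120          # spawning pulse day of year
    maturity_length_cm: float = 7.0
    natural_mortality: float = 0.0023  # day-1
    commercial_length_cm: float = 12.0
    exploit_commercial: float = 28.0       # % year-1
    exploit_noncommercial: float = 0.0     # % year-1
    carbon_to_ww: float = 0.05    # gC per g wet weight
    lw_alpha: float = 0.0085      # W = alpha * L^beta (g, cm)
    lw_beta: float = 3.0
    starvation_frac: float = 0.2  # die below this fraction of length-expected W
    t_opt: float = 24.0           # °C, habitat optimum
    t_sigma: float = 8.0          # °C, habitat suitability width
    habitat_t_tol: float = 15.0   # °C, habitability band around t_opt
    recruit_rise_threshold: float = 1.0   # m, no boost below this winter rise
    recruit_mult_slope: float = 5.0       # multiplier gain per m above threshold
    recruit_per_adult: float = 0.8        # baseline recruits per adult per year
    recruit_weight: float = 0.5           # g_ww of a recruit
    recruit_n_super: int = 50             # super-individuals per annual pulse

    def __post_init__(self) -> None:
        for name in ("vuln_z1", "vuln_z2", "vuln_z3"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        for name in ("exploit_commercial", "exploit_noncommercial"):
            if not (0.0 <= getattr(self, name) <= 100.0):
                raise ValueError(f"{name} outside [0, 100] % per year")
        if self.commercial_length_cm <= 0:
            raise ValueError("commercial length must be positive")

    def length_from_weight(self, w):
        return (np.asarray(w, dtype=float) / self.lw_alpha) ** (1.0 / self.lw_beta)

    def weight_from_length(self, length):
        return self.lw_alpha * np.asarray(length, dtype=float) ** self.lw_beta

    def cmax(self, w, T):
        """Maximum daily ration, gC day-1 per individual fish."""
        return (self.cmax_a * np.asarray(w, dtype=float) ** self.cmax_b
                * temp_scale(T, self.theta, self.t_ref))

    def fishing_rate(self, length):
        """Instantaneous fishing mortality (day-1) by size class."""
        annual = np.where(np.asarray(length, dtype=float) > self.commercial_length_cm,
                          self.exploit_commercial, self.exploit_noncommercial)
        return -np.log1p(-annual / 100.0) / 365.0


@dataclass
class FishPopulation:
    """Array-backed collection of super-individuals plus cumulative ledgers.

    Ledgers (lake-wide gC unless noted): ``consumed`` per prey group,
    ``harvested_ww`` (g wet weight), ``natural_dead_ww``, ``recruits``
    (number of real fish added).
    """

    count: np.ndarray
    weight: np.ndarray
    length: np.ndarray
    layer: np.ndarray
    alive: np.ndarray
    rng: np.random.Generator
    consumed: dict = field(default_factory=lambda: {"z1": 0.0, "z2": 0.0, "z3": 0.0})
    harvested_ww: float = 0.0
    natural_dead_ww: float = 0.0
    recruits: float = 0.0

    @classmethod
    def initialise(cls, params: FishParams, n_super: int = 1000,
                   fish_per_super: float = 100_000.0, seed: int = 0,
                   mean_weight: float = 12.0, weight_cv: float = 0.5,
                   n_layers: int = 10) -> "FishPopulation":
        """Seeded initial population with lognormal weights around
        ``mean_weight`` g; layers start uniform and are reshuffled on the
        first redistribution."""
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(weight_cv**2))
        mu = np.log(mean_weight) - 0.5 * sigma**2
        w = rng.lognormal(mu, sigma, size=n_super)
        w = np.clip(w, 0.2, None)
        return cls(
            count=np.full(n_super, float(fish_per_super)),
            weight=w,
            length=params.length_from_weight(w),
            layer=rng.integers(0, n_layers, size=n_super),
            alive=np.ones(n_super, dtype=bool),
            rng=rng,
        )

    @property
    def n_super(self) -> int:
        return int(self.alive.sum())

    def total_count(self) -> float:
        return float(self.count[self.alive].sum())

    def total_biomass_ww(self) -> float:
        m = self.alive
        return float((self.count[m] * self.weight[m]).sum())

    def compact(self) -> None:
        """Drop dead or empty super-individuals."""
        keep = self.alive & (self.count > 1e-6)
        if keep.all():
            return
        for name in ("count", "weight", "length", "layer", "alive"):
            setattr(self, name, getattr(self, name)[keep])


# ---------------------------------------------------------------------------
# operations


def fish_consumption(weight, prey: dict, T, params: FishParams):
    """Per-prey intake of one fish, gC day-1.

    Effective prey density is the vulnerability-weighted sum
    ``Ew = sum_i V_i C_i``; total intake is ``Cmax(W, T) * Ew / (K + Ew)``
    and each prey receives its weighted share, so the total never exceeds
    the maximum daily ration.
    """
    c1 = np.asarray(prey.get("z1", 0.0), dtype=float)
    c2 = np.asarray(prey.get("z2", 0.0), dtype=float)
    c3 = np.asarray(prey.get("z3", 0.0), dtype=float)
    if (c1 < 0).any() or (c2 < 0).any() or (c3 < 0).any():
        raise ValueError("negative prey concentration")
    e1 = params.vuln_z1 * c1
    e2 = params.vuln_z2 * c2
    e3 = params.vuln_z3 * c3
    ew = e1 + e2 + e3
    safe = np.where(ew > 0.0, ew, 1.0)
    total = params.cmax(weight, T) * ew / (params.k_fish + ew)
    out = {"z1": total * e1 / safe, "z2": total * e2 / safe,
           "z3": total * e3 / safe}
    if np.ndim(total) == 0:
        out = {k: float(v) for k, v in out.items()}
    return out


def bioenergetics_update(weight, intake, T, params: FishParams,
                         repro_pulse: bool = False):
    """One day of the bioenergetics balance for (arrays of) fish.

    ``intake`` is realised consumption in gC day-1 per fish.  Returns
    ``(new_weight, fluxes)`` where ``fluxes`` holds per-fish carbon
    channels (gC day-1): ``egestion``, ``excretion``, ``respiration``
    (activity + SDA + basal), ``reproduction`` and ``growth``; they sum
    exactly to ``intake``.
    """
    w = np.asarray(weight, dtype=float)
    intake = np.asarray(intake, dtype=float)
    if (intake < 0).any():
        raise ValueError("negative intake")
    c2w = params.carbon_to_ww
    c = intake / (c2w * w)                      # g_ww g-1 day-1
    r = params.resp_frac * c + params.sda_frac * c \
        + params.resp_basal * temp_scale(T, params.theta, params.t_ref)
    e = params.egestion_frac * c
    u = params.excretion_frac * c
    # repro_pulse may be a scalar flag or a per-fish boolean mask (adults)
    g_r = np.asarray(repro_pulse, dtype=float) * params.repro_frac
    if np.ndim(w) == 0:
        g_r = float(g_r)
    g = c - (r + e + u + g_r)
    new_w = w * (1.0 + g)
    to_c = c2w * w                               # gC per unit specific rate
    fluxes = {
        "egestion": e * to_c,
        "excretion": u * to_c,
        "respiration": r * to_c,
        "reproduction": g_r * to_c,
        "growth": g * to_c,
    }
    return new_w, fluxes


def habitat_scores(prey_by_layer: np.ndarray, layer_temp: np.ndarray,
                   params: FishParams) -> np.ndarray:
    """Habitat quality per layer: vulnerability-weighted prey density
    times a Gaussian temperature suitability; zero outside the
    habitability band."""
    ew = (params.vuln_z1 * prey_by_layer[0]
          + params.vuln_z2 * prey_by_layer[1]
          + params.vuln_z3 * prey_by_layer[2])
    suit = np.exp(-0.5 * ((layer_temp - params.t_opt) / params.t_sigma) ** 2)
    habitable = np.abs(layer_temp - params.t_opt) <= params.habitat_t_tol
    return np.where(habitable, (ew + 1e-12) * suit, 0.0)


def redistribute_vertical(pop: FishPopulation, prey_by_layer: np.ndarray,
                          layer_temp: np.ndarray, params: FishParams) -> None:
    """Resample the layer of every living super-individual.

    Each fish draws a layer with probability proportional to the habitat
    score, using the population's own generator (deterministic per seed).
    If no layer is habitable the fish stay put and a warning is logged.
    """
    scores = habitat_scores(prey_by_layer, layer_temp, params)
    total = scores.sum()
    if total <= 0.0:
        log.warning("no habitable layer; fish remain in place")
        return
    p = scores / total
    m = pop.alive
    pop.layer[m] = pop.rng.choice(len(p), size=int(m.sum()), p=p)


def recruitment_multiplier(rise_m: float, params: FishParams) -> float:
    """Recruitment boost as a function of the winter water-level rise.

    1 at or below the threshold rise, then a linear ramp: a >4 m flood
    yields a pulse large enough to lift the population roughly 8-10-fold
    relative to its pre-flood size (cf. the default slope)."""
    if rise_m < 0:
        raise ValueError("water-level rise must be non-negative")
    extra = max(rise_m - params.recruit_rise_threshold, 0.0)
    return 1.0 + params.recruit_mult_slope * extra


def recruitment_event(pop: FishPopulation, water_level_rise: float,
                      params: FishParams, n_layers: int) -> float:
    """Annual recruitment pulse; returns the number of recruits added.

    Recruit numbers scale with the adult stock (baseline recruits per
    adult) times the water-level multiplier; recruits enter as small,
    non-commercial super-individuals spread over the column.
    """
    mult = recruitment_multiplier(water_level_rise, params)
    m = pop.alive & (pop.length >= params.maturity_length_cm)
    adults = float(pop.count[m].sum())
    recruits = params.recruit_per_adult * adults * mult
    if recruits <= 0.0:
        return 0.0
    k = params.recruit_n_super
    w0 = params.recruit_weight
    pop.count = np.concatenate([pop.count, np.full(k, recruits / k)])
    pop.weight = np.concatenate([pop.weight, np.full(k, w0)])
    pop.length = np.concatenate([pop.length,
                                 np.full(k, float(params.length_from_weight(w0)))])
    pop.layer = np.concatenate([pop.layer, pop.rng.integers(0, n_layers, size=k)])
    pop.alive = np.concatenate([pop.alive, np.ones(k, dtype=bool)])
    pop.recruits += recruits
    return recruits


def apply_mortality(pop: FishPopulation, dt: float, params: FishParams) -> dict:
    """Deterministic-rate thinning of the counts over ``dt`` days.

    Counts decay as ``exp(-(m_nat + f) dt)`` with the fishing rate ``f``
    chosen by length relative to the commercial threshold; deaths are
    partitioned between natural mortality and harvest in proportion to
    the rates.  Returns the wet-weight removed by each channel.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    m = pop.alive
    f = params.fishing_rate(pop.length[m])
    z = params.natural_mortality + f
    surv = np.exp(-z * dt)
    deaths = pop.count[m] * (1.0 - surv)
    with np.errstate(invalid="ignore", divide="ignore"):
        harvest_share = np.where(z > 0.0, f / np.where(z > 0, z, 1.0), 0.0)
    harvested = deaths * harvest_share
    natural = deaths - harvested
    harvested_ww = float((harvested * pop.weight[m]).sum())
    natural_ww = float((natural * pop.weight[m]).sum())
    pop.count[m] = pop.count[m] * surv
    pop.harvested_ww += harvested_ww
    pop.natural_dead_ww += natural_ww
    return {"harvested_ww": harvested_ww, "natural_ww": natural_ww,
            "harvested_count": float(harvested.sum()),
            "natural_count": float(natural.sum()),
            "natural_by_si": natural, "layers": pop.layer[m]}
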