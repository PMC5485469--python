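"""Synthetic forcing for a seasonally stratified lake column.

Generates the daily drivers the coupled plankton--fish model needs:
surface temperature, photosynthetically active radiation (PAR), mixed-layer
depth, water level, and an external nutrient (phosphorus) load.  Everything
is seeded and deterministic: a seasonal sinusoid plus AR(1) noise for
temperature and PAR, a seasonal fill/drawdown cycle for water level, and
optional "wet winter" events that raise the level by several metres --
the hydrological trigger for mass fish recruitment in Lake Kinneret-type
systems.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ForcingConfig",
    "WetWinterEvent",
    "ForcingSeries",
    "generate_forcing",
    "add_wet_winter_event",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class WetWinterEvent:
    """An exceptionally wet winter raising the lake level by ``rise_m``.

    ``winter_year`` is the calendar year of the January inside the wet
    winter (the 1991/92 flood is ``winter_year=1992``).
    """

    winter_year: int
    rise_m: float


@dataclass
class ForcingConfig:
    """Parameters of the synthetic forcing generator.

    Temperature and PAR are seasonal sinusoids with seeded AR(1) noise;
    amplitudes default to a warm-monomictic, Kinneret-like climate.  All
    values are stand-ins (uncalibrated), chosen to look like the 1997-2003
    window the simulations emulate.
    """

    t_min: float = 15.0          # °C, winter surface temperature
    t_max: float = 29.0          # °C, late-summer surface temperature
    t_phase_day: int = 226       # day of year of the temperature maximum
    t_noise_sd: float = 0.35     # °C, AR(1) innovation s.d.
    ar1_rho: float = 0.8         # AR(1) autocorrelation (daily)
    par_mean: float = 210.0      # W m-2, annual mean daily PAR
    par_amp: float = 110.0       # W m-2, seasonal amplitude
    par_phase_day: int = 172     # summer solstice
    par_noise_sd: float = 12.0   # W m-2
    level_base: float = 0.0      # m above reference datum
    level_amp: float = 0.8       # m, seasonal fill/drawdown amplitude
    level_phase_day: int = 105   # spring maximum
    event_ramp_days: int = 60    # days over which a flood ramps up
    nutrient_load_base: float = 3.0e5    # gP day-1 into the surface layer
    nutrient_load_winter_factor: float = 3.0  # winter-inflow multiplier
    mld_summer: float = 15.0     # m, stratified-season mixed layer depth
    mld_winter: float = 40.0     # m, holomixis (full column)
    strat_start_doy: int = 75    # onset of stratification (mid March)
    strat_end_doy: int = 350     # destratification (mid December)
    wet_winters: tuple[WetWinterEvent, ...] = field(default_factory=tuple)

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


_COLUMNS = ["surface_temp", "par", "mixed_layer_depth", "water_level", "nutrient_load"]


@dataclass
class ForcingSeries:
    """Daily forcing records on a contiguous calendar.

    Thin wrapper around a :class:`pandas.DataFrame` indexed by date with
    columns ``surface_temp`` (°C), ``par`` (W m-2), ``mixed_layer_depth``
    (m), ``water_level`` (m above datum) and ``nutrient_load`` (gP day-1).
    """

    frame: pd.DataFrame
    seed: int
    config_hash: str

    def __post_init__(self) -> None:
        idx = self.frame.index
        if len(idx) == 0:
            raise ValueError("forcing series is empty")
        expected = pd.date_range(idx[0], idx[-1], freq="D")
        if not idx.equals(expected):
            raise ValueError("forcing dates must be contiguous daily records")
        if not np.isfinite(self.frame.to_numpy()).all():
            raise ValueError("forcing contains non-finite values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def day(self, date) -> pd.Series:
        """Return the record for one calendar day."""
        return self.frame.loc[pd.Timestamp(date)]

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# igplake forcing v1\n# seed={self.seed}\n"
                     f"# config_hash={self.config_hash}\n")
            self.frame.to_csv(fh, index_label="date", float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ForcingSeries":
        meta: dict[str, str] = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    body = line.lstrip("# ").strip()
                    if "=" in body:
                        k, v = body.split("=", 1)
                        meta[k.strip()] = v.strip()
                else:
                    lines.append(line)
        frame = pd.read_csv(io.StringIO("".join(lines)), index_col="date",
                            parse_dates=["date"])
        return cls(frame=frame, seed=int(meta.get("seed", -1)),
                   config_hash=meta.get("config_hash", ""))


def _seasonal(doy: np.ndarray, mean: float, amp: float, phase_day: float) -> np.ndarray:
    return mean + amp * np.cos(2.0 * np.pi * (doy - phase_day) / DAYS_PER_YEAR)


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    # stationary start so the noise level does not drift with series length
    out[0] = innov[0] / np.sqrt(1.0 - rho**2) if rho > 0 else innov[0]
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov[i]
    return out


def _mld_of_doy(doy: np.ndarray, cfg: ForcingConfig) -> np.ndarray:
    """Smooth seasonal mixed-layer depth: full mixing outside the
    stratified season, shoaling to ``mld_summer`` at mid-season."""
    inside = (doy >= cfg.strat_start_doy) & (doy <= cfg.strat_end_doy)
    frac = (doy - cfg.strat_start_doy) / max(cfg.strat_end_doy - cfg.strat_start_doy, 1)
    strength = np.where(inside, np.sin(np.pi * np.clip(frac, 0.0, 1.0)), 0.0)
    return cfg.mld_winter - (cfg.mld_winter - cfg.mld_summer) * strength


def _event_profile(dates: pd.DatetimeIndex, event: WetWinterEvent,
                   ramp_days: int) -> np.ndarray:
    """Local additive water-level anomaly for one wet winter.

    The level ramps up by ``rise_m`` starting 1 December of the preceding
    calendar year, holds through spring, and draws back down to the
    baseline trajectory by 30 November -- the event is entirely local to
    that hydrological year.
    """
    start = pd.Timestamp(year=event.winter_year - 1, month=12, day=1)
    end = pd.Timestamp(year=event.winter_year, month=11, day=30)
    hold_end = pd.Timestamp(year=event.winter_year, month=6, day=30)
    days_since = (dates - start).days.to_numpy()
    anomaly = np.zeros(len(dates))
    in_window = (dates >= start) & (dates <= end)
    ramp = np.clip(days_since / max(ramp_days, 1), 0.0, 1.0)
    decay_len = max((end - hold_end).days, 1)
    decay = np.clip((end - dates).days.to_numpy() / decay_len, 0.0, 1.0)
    anomaly[in_window] = (event.rise_m * ramp * np.where(dates >= hold_end, decay, 1.0))[in_window]
    return anomaly


def generate_forcing(config: ForcingConfig, start_date, end_date,
                     seed: int) -> ForcingSeries:
    """Generate a seeded daily forcing series covering ``[start, end]``.

    Deterministic for a given ``(config, seed)`` pair.  Temperature is
    clipped to ``[t_min, t_max]`` after noise so the configured climate
    envelope is a hard invariant; PAR is clipped at zero.
    """
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if end <= start:
        raise ValueError(f"end_date {end.date()} must be after start_date {start.date()}")
    for key, val in asdict(config).items():
        if key == "wet_winters":
            continue
        if not np.isfinite(val):
            raise ValueError(f"forcing config value {key!r} is not finite")

    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    rng = np.random.default_rng(seed)

    t_mid = 0.5 * (config.t_min + config.t_max)
    t_amp = 0.5 * (config.t_max - config.t_min)
    temp = _seasonal(doy, t_mid, t_amp, config.t_phase_day)
    temp = temp + _ar1(len(dates), config.ar1_rho, config.t_noise_sd, rng)
    temp = np.clip(temp, config.t_min, config.t_max)

    par = _seasonal(doy, config.par_mean, config.par_amp, config.par_phase_day)
    par = np.clip(par + _ar1(len(dates), config.ar1_rho, config.par_noise_sd, rng), 0.0, None)

    level = _seasonal(doy, config.level_base, config.level_amp, config.level_phase_day)

    winter_weight = 0.5 * (1.0 + np.cos(2.0 * np.pi * (doy - 15.0) / DAYS_PER_YEAR))
    load = config.nutrient_load_base * (
        1.0 + (config.nutrient_load_winter_factor - 1.0) * winter_weight**2
    )

    frame = pd.DataFrame(
        {
            "surface_temp": temp,
            "par": par,
            "mixed_layer_depth": _mld_of_doy(doy, config),
            "water_level": level,
            "nutrient_load": load,
        },
        index=dates,
    )
    frame.index.name = "date"
    series = ForcingSeries(frame=frame, seed=seed, config_hash=config.config_hash())
    for event in config.wet_winters:
        series = add_wet_winter_event(series, event.winter_year, event.rise_m,
                                      ramp_days=config.event_ramp_days)
    return series


def add_wet_winter_event(series: ForcingSeries, winter_year: int, rise_m: float,
                         ramp_days: int = 60) -> ForcingSeries:
    """Superimpose a wet-winter flood on the water-level trajectory.

    Returns a new series; only ``water_level`` inside the event's
    hydrological year (1 Dec .. 30 Nov) changes.
    """
    if rise_m <= 0.0:
        raise ValueError("rise_m must be positive")
    years = series.dates.year
    if not ((years.min() <= winter_year) and (winter_year <= years.max())):
        raise ValueError(f"winter_year {winter_year} outside series span "
                         f"{years.min()}..{years.max()}")
    frame = series.frame.copy()
    anomaly = _event_profile(series.dates, WetWinterEvent(winter_year, rise_m),
                             ramp_days)
    frame["water_level"] = frame["water_level"].to_numpy() + anomaly
    return ForcingSeries(frame=frame, seed=series.seed,
                         config_hash=series.config_hash)


def water_level_rise(series: ForcingSeries, spring_year: int,
                     window=("12-01", "04-30")) -> float:
    """Winter water-level rise feeding the recruitment model.

    Maximum level inside the 1 Dec (previous year) .. 30 Apr window minus
    the level at the window start; clipped at zero.  Returns 0 for windows
    not fully covered by the series.
    """
    start = pd.Timestamp(f"{spring_year - 1}-{window[0]}")
    end = pd.Timestamp(f"{spring_year}-{window[1]}")
    if start < series.dates[0] or end > series.dates[-1]:
        return 0.0
    level = series.frame.loc[start:end, "water_level"]
    return float(max(level.max() - level.iloc[0], 0.0))
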