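"""Predation-flux accounting and scenario diagnostics.

Converts the six daily intraguild-predation fluxes (Z1_z1, Z1_z2, Z1_z3:
predatory-zooplankton predation; F_z1, F_z2, F_z3: fish predation) into
volume-weighted mean rates (ugC L-1 day-1) and lake-wide wet-weight totals
(ton day-1), and derives the headline diagnostics: monthly climatologies,
the daily Z1_z2 / F_z2 dominance ratio, the partition of herbivore
mortality among fish predation / zooplankton predation / non-predation
losses, and the annual scenario table (channel totals in thousand ton
yr-1, group totals, ratios to 2 decimals, percent-of-base to the nearest
integer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS6",
    "PredationLedger",
    "ScenarioTable",
    "monthly_climatology",
    "dominance_ratio_series",
    "mortality_partition",
    "annual_channel_totals",
    "build_scenario_table",
]

CHANNELS6 = ("z1_z1", "z1_z2", "z1_z3", "f_z1", "f_z2", "f_z3")
DAYS_PER_YEAR = 365.25


@dataclass
class PredationLedger:
    """Daily predation fluxes in both unit systems.

    ``rates``: volume-weighted mean rates, ugC L-1 day-1.
    ``lakewide``: whole-lake wet-weight fluxes, ton day-1.
    ``z2_nonpred``: herbivore non-predation losses, same two frames'
    convention (stored as extra columns).
    """

    rates: pd.DataFrame
    lakewide: pd.DataFrame
    carbon_to_ww: float
    total_volume: float

    @classmethod
    def from_daily_carbon(cls, daily: pd.DataFrame, total_volume: float,
                          carbon_to_ww: float) -> "PredationLedger":
        """Build from a daily ledger holding lake-wide gC day-1 columns
        (the scheduler output).  1 mgC L-1 = 1 gC m-3, so the
        volume-weighted mean rate is just total / volume."""
        cols = list(CHANNELS6) + ["z2_nonpred"]
        gc = daily[cols]
        rates = gc / total_volume * 1000.0          # ugC L-1 day-1
        lakewide = gc / carbon_to_ww / 1e6          # ton ww day-1
        return cls(rates=rates, lakewide=lakewide,
                   carbon_to_ww=carbon_to_ww, total_volume=total_volume)

    def rate_to_lakewide(self, rate_ug):
        """ugC L-1 day-1 -> ton ww day-1 (inverse of lakewide_to_rate)."""
        return rate_ug / 1000.0 * self.total_volume / self.carbon_to_ww / 1e6

    def lakewide_to_rate(self, tons):
        return tons * 1e6 * self.carbon_to_ww / self.total_volume * 1000.0


def monthly_climatology(series: pd.Series, month: int) -> float:
    """Mean of a daily series over all days of one calendar month,
    pooled across years.  NaN for a month absent from the record."""
    sel = series[series.index.month == month]
    if len(sel) == 0:
        return math.nan
    return float(sel.mean())


def dominance_ratio_series(ledger: PredationLedger) -> pd.Series:
    """Daily ratio of zooplankton predation to fish predation on the
    herbivores (Z1_z2 / F_z2).

    Days with F_z2 = 0 and Z1_z2 > 0 map to +inf; 0/0 days are missing.
    Values above 1 flag predatory-zooplankton dominance.
    """
    num = ledger.rates["z1_z2"]
    den = ledger.rates["f_z2"]
    out = pd.Series(np.full(len(num), np.nan), index=num.index, name="z1z2_over_fz2")
    both = (den > 0)
    out[both] = num[both] / den[both]
    out[(den == 0) & (num > 0)] = np.inf
    return out


def mortality_partition(ledger: PredationLedger) -> pd.DataFrame:
    """Daily fractions of herbivore (Z2) mortality by cause.

    Columns ``fish``, ``zoo``, ``nonpred`` are non-negative and sum to 1;
    days with zero total mortality are dropped.
    """
    f = ledger.rates["f_z2"]
    z = ledger.rates["z1_z2"]
    n = ledger.rates["z2_nonpred"]
    total = f + z + n
    keep = total > 0
    out = pd.DataFrame({
        "fish": f[keep] / total[keep],
        "zoo": z[keep] / total[keep],
        "nonpred": n[keep] / total[keep],
    })
    return out


def annual_channel_totals(ledger: PredationLedger,
                          spinup_years: int = 0) -> dict[str, float]:
    """Average annual lake-wide predation per channel, thousand ton yr-1.

    Mean daily wet-weight flux (after discarding spin-up years) times the
    length of a year.
    """
    lw = ledger.lakewide
    cutoff = lw.index[0] + pd.DateOffset(years=spinup_years)
    lw = lw.loc[lw.index >= cutoff]
    return {c: float(lw[c].mean() * DAYS_PER_YEAR / 1e3) for c in CHANNELS6}


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class ScenarioTable:
    """Annual predation table across scenarios with derived diagnostics.

    ``table`` rows: the six channels plus the derived rows (group totals,
    grand total, total predation on Z2, per-group Z1/F ratios); columns:
    one per scenario.  ``percent_of_base`` holds the per-channel percent
    of the base scenario (nearest integer, NaN where the base channel is
    zero); ``ratios`` the Z1_zi / F_zi ratios rounded to 2 decimals.
    """

    table: pd.DataFrame
    percent_of_base: pd.DataFrame
    ratios: pd.DataFrame
    base_label: str

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# scenario table, base={self.base_label}\n")
            self.table.to_csv(fh, float_format="%.4f")
            fh.write("\n# percent of base (%)\n")
            self.percent_of_base.to_csv(fh, float_format="%.0f")
            fh.write("\n# Z1_zi / F_zi ratios\n")
            self.ratios.to_csv(fh, float_format="%.2f")


def build_scenario_table(channel_totals: dict[str, dict[str, float]],
                         base_label: str) -> ScenarioTable:
    """Derive the scenario comparison table from annual channel totals.

    ``channel_totals`` maps scenario label -> {channel -> thousand ton
    yr-1} for the six predation channels.  Derived rows recompute exactly
    from the inputs: group totals (sum of Z1 channels; sum of F channels),
    grand total, total predation on the herbivores (Z1_z2 + F_z2), the
    per-group Z1_zi / F_zi ratios (2 dp) and per-channel percent of the
    base scenario (nearest integer, half away from zero).
    """
    if base_label not in channel_totals:
        raise ValueError(f"base scenario {base_label!r} missing")
    labels = list(channel_totals)
    tbl = pd.DataFrame({lab: {c: channel_totals[lab][c] for c in CHANNELS6}
                        for lab in labels}).loc[list(CHANNELS6)]
    derived = pd.DataFrame(index=["total_z_pred", "total_f_pred",
                                  "total_pred", "total_on_z2"],
                           columns=labels, dtype=float)
    for lab in labels:
        z = tbl.loc[["z1_z1", "z1_z2", "z1_z3"], lab].sum()
        f = tbl.loc[["f_z1", "f_z2", "f_z3"], lab].sum()
        derived.loc["total_z_pred", lab] = z
        derived.loc["total_f_pred", lab] = f
        derived.loc["total_pred", lab] = z + f
        derived.loc["total_on_z2", lab] = (tbl.loc["z1_z2", lab]
                                           + tbl.loc["f_z2", lab])
    ratios = pd.DataFrame(index=["z1_z1/f_z1", "z1_z2/f_z2", "z1_z3/f_z3"],
                          columns=labels, dtype=float)
    for lab in labels:
        for zi, fi, row in (("z1_z1", "f_z1", "z1_z1/f_z1"),
                            ("z1_z2", "f_z2", "z1_z2/f_z2"),
                            ("z1_z3", "f_z3", "z1_z3/f_z3")):
            den = tbl.loc[fi, lab]
            ratios.loc[row, lab] = (round(tbl.loc[zi, lab] / den, 2)
                                    if den != 0 else math.nan)
    pct = pd.DataFrame(index=list(CHANNELS6), columns=labels, dtype=float)
    for lab in labels:
        for c in CHANNELS6:
            base = channel_totals[base_label][c]
            pct.loc[c, lab] = (_round_half_away(100.0 * channel_totals[lab][c] / base)
                               if base != 0 else math.nan)
    full = pd.concat([tbl, derived])
    return ScenarioTable(table=full, percent_of_base=pct, ratios=ratios,
                         base_label=base_label)
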