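"""Structured run outputs: manifest, ledgers, population snapshots."""

from __future__ import annotations

import datetime as _dt
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .simulate import SimulationResult

__all__ = ["export_run", "read_ledger"]


def _manifest(config: RunConfig, result: SimulationResult) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": result.seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        "n_days": int(len(result.ledger)),
        "limiter_events": int(result.limiter_events),
        "counters": {k: float(v) for k, v in result.counters.items()},
    }


def export_run(result: SimulationResult, config: RunConfig, directory) -> Path:
    """Write a run directory: manifest.json, ledger.csv, population.csv,
    state.csv (final layer-resolved state) and forcing.csv.

    Re-reading ``ledger.csv`` with :func:`read_ledger` reproduces the
    in-memory table exactly (full float precision is written).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not directory.is_dir():
        raise IOError(f"not a writable directory: {directory}")

    with open(directory / "manifest.json", "w") as fh:
        json.dump(_manifest(config, result), fh, indent=2)

    result.ledger.to_csv(directory / "ledger.csv", index_label="date",
                         float_format="%.17g")

    pop = result.population
    if pop is not None:
        snap = pd.DataFrame({
            "count": pop.count, "weight_g": pop.weight,
            "length_cm": pop.length, "layer": pop.layer, "alive": pop.alive,
        })
        snap.to_csv(directory / "population.csv", index_label="id")

    state = pd.DataFrame(result.state.y.T,
                         columns=["a", "n", "d", "z1", "z2", "z3"])
    state.insert(0, "layer_mid_m", result.grid.midpoints)
    state.to_csv(directory / "state.csv", index_label="layer")

    if result.last_fluxes is not None:
        flux = result.last_fluxes.to_frame(result.ledger.index[-1])
        flux.to_csv(directory / "fluxes_last_day.csv", index=False,
                    float_format="%.17g")

    result.forcing.to_csv(directory / "forcing.csv")
    return directory


def read_ledger(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="date", parse_dates=["date"]).astype(float)
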