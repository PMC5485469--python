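import datetime

import numpy as np
import pandas as pd
import pytest

import igplake as ig
from igplake.grid import ColumnGrid, PhysicsState


@pytest.fixture
def default_config():
    return ig.RunConfig()


@pytest.fixture
def one_layer_grid():
    return ColumnGrid(layer_edges=np.array([0.0, 10.0]),
                      layer_volumes=np.array([1.0e9]))


@pytest.fixture
def constant_day():
    """A single synthetic forcing record with no nutrient load."""
    return pd.Series(
        {"surface_temp": 20.0, "par": 150.0, "mixed_layer_depth": 10.0,
         "water_level": 0.0, "nutrient_load": 0.0},
        name=pd.Timestamp("2000-06-01"))


@pytest.fixture
def warm_physics():
    return PhysicsState(layer_temp=np.array([20.0]), mixing_coeff=np.array([]))


def _short_config(days: int, **kwargs) -> ig.RunConfig:
    cfg = ig.RunConfig()
    cfg.end_date = cfg.start_date + datetime.timedelta(days=days)
    for key, value in kwargs.items():
        obj = cfg
        *head, last = key.split("__")
        for part in head:
            obj = getattr(obj, part)
        setattr(obj, last, value)
    return cfg


@pytest.fixture
def short_config_factory():
    return _short_config


# ---------------------------------------------------------------------------
# full-length scenario runs shared by the acceptance tests (session scope:
# each seven-year coupled run takes tens of seconds)

def _scenario_result(multiplier: int, seed: int = 1) -> ig.SimulationResult:
    cfg = ig.RunConfig()
    cfg.scenario.fish_per_super = 100_000.0 * multiplier
    return ig.run_simulation(cfg, seed=seed)


@pytest.fixture(scope="session")
def run_x1():
    return _scenario_result(1)


@pytest.fixture(scope="session")
def run_x2():
    return _scenario_result(2)


@pytest.fixture(scope="session")
def run_x8():
    return _scenario_result(8)


@pytest.fixture(scope="session")
def multiplier_results(run_x1, run_x2, run_x8):
    return {"x1": run_x1, "x2": run_x2, "x8": run_x8}
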