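"""Fixed vertical layer grid and the reduced physics state.

A fixed Eulerian grid (default ten 4 m layers over a 40 m column) with a
frustum hypsography stands in for a full Lagrangian-layer hydrodynamic
model.  Stratification enters the ecology only through (i) a two-value
temperature profile (epilimnion / hypolimnion split at the mixed-layer
depth) and (ii) a vertical exchange coefficient that is large inside the
mixed layer and small across the thermocline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ColumnGrid", "PhysicsState", "temperature_profile"]


@dataclass(frozen=True)
class ColumnGrid:
    """Surface-down layer grid with hypsographic volumes.

    ``layer_edges`` has ``n_layers + 1`` strictly increasing entries in m
    below the surface; ``layer_volumes`` in m3 sum to the configured total
    lake volume.
    """

    layer_edges: np.ndarray
    layer_volumes: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.layer_edges, dtype=float)
        vols = np.asarray(self.layer_volumes, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("layer edges must be strictly increasing")
        if len(vols) != len(edges) - 1:
            raise ValueError("need one volume per layer")
        if np.any(vols <= 0):
            raise ValueError("layer volumes must be positive")
        object.__setattr__(self, "layer_edges", edges)
        object.__setattr__(self, "layer_volumes", vols)

    @property
    def n_layers(self) -> int:
        return len(self.layer_volumes)

    @property
    def depth(self) -> float:
        return float(self.layer_edges[-1])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.layer_edges[:-1] + self.layer_edges[1:])

    @property
    def total_volume(self) -> float:
        return float(self.layer_volumes.sum())

    @classmethod
    def frustum(cls, depth: float = 40.0, n_layers: int = 10,
                surface_area: float = 1.66e8,
                total_volume: float = 4.0e9) -> "ColumnGrid":
        """Grid whose plan area shrinks linearly with depth.

        ``A(z) = A0 * (1 - c z / depth)`` with ``c`` chosen so the column
        integrates to ``total_volume``.  Defaults are Kinneret-like
        (166 km2 surface, 4 km3 volume) but entirely configurable.
        """
        c = 2.0 * (1.0 - total_volume / (surface_area * depth))
        if not (0.0 <= c < 1.0):
            raise ValueError(
                "total_volume incompatible with a frustum of this area/depth")
        edges = np.linspace(0.0, depth, n_layers + 1)
        z0, z1 = edges[:-1], edges[1:]
        # integral of A(z) over each layer
        vols = surface_area * ((z1 - z0) - c * (z1**2 - z0**2) / (2.0 * depth))
        return cls(layer_edges=edges, layer_volumes=vols)


@dataclass
class PhysicsState:
    """Per-layer temperature and interfacial exchange for one day.

    ``mixing_coeff`` has ``n_layers - 1`` entries (day-1); the exchange
    flow across interface i is ``mixing_coeff[i] * min(V_i, V_{i+1})``.
    """

    layer_temp: np.ndarray
    mixing_coeff: np.ndarray

    def __post_init__(self) -> None:
        self.layer_temp = np.asarray(self.layer_temp, dtype=float)
        self.mixing_coeff = np.asarray(self.mixing_coeff, dtype=float)
        if np.any(self.mixing_coeff < 0):
            raise ValueError("mixing coefficients must be non-negative")


def temperature_profile(series_day, grid: ColumnGrid, hypo_temp: float,
                        mixed_exchange: float = 5.0,
                        thermocline_exchange: float = 0.02) -> PhysicsState:
    """Two-layer temperature and mixing profile for one forcing day.

    Layers whose midpoint lies above the mixed-layer depth take the
    surface temperature, deeper layers the configured hypolimnion
    temperature.  Exchange is ``mixed_exchange`` between two layers that
    are both inside the mixed layer and ``thermocline_exchange``
    otherwise.  The mixed-layer depth is clamped to the column.
    """
    surface_temp = float(series_day["surface_temp"])
    if hypo_temp > surface_temp:
        hypo_temp = surface_temp
    mld = float(np.clip(series_day["mixed_layer_depth"], grid.layer_edges[1],
                        grid.depth))
    mids = grid.midpoints
    in_mixed = mids <= mld
    temp = np.where(in_mixed, surface_temp, hypo_temp)
    both_mixed = in_mixed[:-1] & in_mixed[1:]
    mixing = np.where(both_mixed, mixed_exchange, thermocline_exchange)
    return PhysicsState(layer_temp=temp, mixing_coeff=mixing)
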