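"""Per-layer carbon dynamics of the planktonic food web.

State per layer (mgC L-1, numerically equal to gC m-3): nanoplankton ``A``
(the basal resource), detritus ``D``, predatory zooplankton ``Z1``
(cyclopoid copepods, the intraguild prey), herbivorous zooplankton ``Z2``
(cladocerans and copepodites, the shared resource), micro-zooplankton
``Z3``, plus one dissolved nutrient ``N`` (phosphorus, mgP L-1).

The trophic closure is the minimal intraguild-predation triangle: Z2 feeds
on A; Z3 feeds on A and D; Z1 feeds on Z3, Z2 and on its own early stages
(self-limitation) with fixed diet preferences, through a single
preference-weighted Michaelis--Menten functional response scaled by a Q10
temperature factor.  All transfers are recorded as named flux channels so
that every change in every pool is exactly the signed sum of recorded
fluxes, and positivity is enforced only by proportionally scaling the
outgoing fluxes of an over-drawn pool (never by post-hoc clamping).

Integration is fixed-step (default 1 h) with a classic Runge--Kutta
update; a fine-step adaptive integration of the same right-hand side is
the correctness reference in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ColumnGrid, PhysicsState

__all__ = [
    "GrazingParams",
    "PhytoParams",
    "PlanktonParams",
    "PlanktonState",
    "FluxRecord",
    "temp_scale",
    "grazing_fluxes",
    "phyto_growth",
    "step_plankton",
    "CHANNELS",
]

# ---------------------------------------------------------------------------
# flux channel layout (per layer, mgC L-1 day-1 as rates / mgC L-1 as amounts;
# N_LOAD and MIX_N are in phosphorus units, mgP L-1)
CHANNELS = (
    "gpp", "a_resp", "a_mort",
    "gz2_a", "gz3_a", "gz3_d",
    "gz1_z1", "gz1_z2", "gz1_z3",
    "z1_resp", "z2_resp", "z3_resp",
    "z1_mort", "z2_mort", "z3_mort",
    "d_remin", "n_load",
    "mix_a", "mix_n", "mix_d", "mix_z1", "mix_z2", "mix_z3",
)
_CI = {name: i for i, name in enumerate(CHANNELS)}
NCH = len(CHANNELS)
(GPP, A_RESP, A_MORT, GZ2_A, GZ3_A, GZ3_D, GZ1_Z1, GZ1_Z2, GZ1_Z3,
 Z1_RESP, Z2_RESP, Z3_RESP, Z1_MORT, Z2_MORT, Z3_MORT, D_REMIN, N_LOAD,
 MIX_A, MIX_N, MIX_D, MIX_Z1, MIX_Z2, MIX_Z3) = range(NCH)

# pool layout
POOL_A, POOL_N, POOL_D, POOL_Z1, POOL_Z2, POOL_Z3 = range(6)
POOL_NAMES = ("a", "n", "d", "z1", "z2", "z3")
CARBON_POOLS = (POOL_A, POOL_D, POOL_Z1, POOL_Z2, POOL_Z3)


def temp_scale(T, theta: float, t_ref: float):
    """Q10-style temperature factor ``theta ** ((T - t_ref) / 10)``.

    Equals 1 at the reference temperature and is strictly increasing in T
    for ``theta > 1``.
    """
    if theta <= 1.0:
        raise ValueError("theta must exceed 1")
    return np.power(theta, (np.asarray(T, dtype=float) - t_ref) / 10.0)


@dataclass
class GrazingParams:
    """Predatory-zooplankton (Z1) multi-prey grazing parameters.

    ``g_max`` is the maximum predation rate coefficient in
    gC m-3 (gZ m-3)-1 day-1; preferences weight the three prey channels
    (micro-zooplankton, herbivores, own early stages) and must sum to 1.
    """

    g_max: float = 3.03
    pref_z3: float = 0.5
    pref_z2: float = 0.35
    pref_self: float = 0.15
    k_graz: float = 2.0       # mgC L-1, half saturation on weighted prey
    assim: float = 0.7        # assimilation efficiency (0, 1]
    theta: float = 2.0
    t_ref: float = 20.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        s = self.pref_z3 + self.pref_z2 + self.pref_self
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"Z1 prey preferences must sum to 1, got {s!r}")
        for name in ("pref_z3", "pref_z2", "pref_self"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.g_max <= 0 or self.k_graz <= 0:
            raise ValueError("g_max and k_graz must be positive")
        if not (0.0 < self.assim <= 1.0):
            raise ValueError("assimilation efficiency must be in (0, 1]")


@dataclass
class PhytoParams:
    """Nanoplankton growth/loss parameters (uncalibrated defaults)."""

    mu_max: float = 1.5       # day-1 at reference temperature
    k_n: float = 0.005        # mgP L-1
    i_k: float = 40.0         # W m-2, light half saturation
    resp: float = 0.05        # day-1
    mort: float = 0.02        # day-1, non-grazing mortality to detritus

    def __post_init__(self) -> None:
        for name in ("mu_max", "k_n", "i_k", "resp", "mort"):
            if getattr(self, name) <= 0:
                raise ValueError(f"phytoplankton rate {name} must be positive")


@dataclass
class PlanktonParams:
    """Full parameter set of the plankton stage.

    Only ``z1.g_max`` and the Z1 preferences carry literature values; the
    remaining rates are uncalibrated desk-scale defaults documented in the
    methods note.
    """

    phyto: PhytoParams = field(default_factory=PhytoParams)
    z1: GrazingParams = field(default_factory=GrazingParams)
    z2_gmax: float = 0.35      # herbivore grazing on A, same units as g_max
    z2_k: float = 0.1
    z2_assim: float = 0.7
    z3_gmax: float = 0.25      # micro-zooplankton on A and D
    z3_k: float = 0.25
    z3_assim: float = 0.7
    z3_pref_a: float = 0.8
    z3_pref_d: float = 0.2
    zoo_resp: float = 0.014    # day-1, temperature scaled
    zoo_mort: float = 0.008    # day-1, non-predation mortality to detritus
    remin_rate: float = 0.05  # day-1, detrital breakdown
    burial_frac: float = 0.5  # fraction of remineralised D leaving the system
    p_to_c: float = 0.0244    # gP per gC in all organic pools (Redfield mass)
    k_ext: float = 0.3        # m-1, light extinction
    theta: float = 2.0        # shared Q10 for phyto / Z2 / Z3 / detritus
    t_ref: float = 20.0


@dataclass
class PlanktonState:
    """Layered concentrations on a :class:`ColumnGrid`.

    ``y`` has shape (6, n_layers): rows A, N, D, Z1, Z2, Z3.
    """

    grid: ColumnGrid
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (6, self.grid.n_layers):
            raise ValueError(f"state shape {self.y.shape} does not match grid")
        if not np.isfinite(self.y).all():
            raise ValueError("non-finite plankton state")
        if (self.y < 0).any():
            raise ValueError("negative plankton concentration")

    @classmethod
    def uniform(cls, grid: ColumnGrid, a: float = 0.15, n: float = 0.01,
                d: float = 0.05, z1: float = 0.01, z2: float = 0.05,
                z3: float = 0.02) -> "PlanktonState":
        y = np.empty((6, grid.n_layers))
        for i, v in enumerate((a, n, d, z1, z2, z3)):
            y[i] = v
        return cls(grid=grid, y=y)

    def copy(self) -> "PlanktonState":
        return PlanktonState(grid=self.grid, y=self.y.copy())

    @property
    def a(self): return self.y[POOL_A]
    @property
    def n(self): return self.y[POOL_N]
    @property
    def d(self): return self.y[POOL_D]
    @property
    def z1(self): return self.y[POOL_Z1]
    @property
    def z2(self): return self.y[POOL_Z2]
    @property
    def z3(self): return self.y[POOL_Z3]

    def total_carbon(self) -> float:
        """Lake-wide organic carbon over all carbon pools, gC."""
        conc = self.y[list(CARBON_POOLS)].sum(axis=0)  # gC m-3
        return float(conc @ self.grid.layer_volumes)

    def total_phosphorus(self, p_to_c: float) -> float:
        """Lake-wide phosphorus (dissolved + bound in organic pools), gP."""
        bound = p_to_c * self.y[list(CARBON_POOLS)].sum(axis=0)
        return float((bound + self.y[POOL_N]) @ self.grid.layer_volumes)

    def volume_weighted(self, pool: int) -> float:
        """Volume-weighted lake mean concentration of one pool."""
        return float(self.y[pool] @ self.grid.layer_volumes / self.grid.total_volume)


@dataclass
class FluxRecord:
    """Applied per-layer flux amounts for one step (or one day).

    ``amounts`` has shape (NCH, n_layers) in mgC L-1 (N channels in
    mgP L-1).  Pool changes recompute exactly from these amounts via
    :func:`pool_deltas`.
    """

    amounts: np.ndarray
    params: PlanktonParams

    def __add__(self, other: "FluxRecord") -> "FluxRecord":
        return FluxRecord(self.amounts + other.amounts, self.params)

    def channel(self, name: str) -> np.ndarray:
        return self.amounts[_CI[name]]

    def respired_carbon(self) -> np.ndarray:
        """Carbon respired per layer (mgC L-1), incl. remineralisation."""
        ch = self.amounts
        return (ch[A_RESP] + ch[Z1_RESP] + ch[Z2_RESP] + ch[Z3_RESP]
                + (1.0 - self.params.burial_frac) * ch[D_REMIN])

    def buried_carbon(self) -> np.ndarray:
        return self.params.burial_frac * self.amounts[D_REMIN]

    def fixed_carbon(self) -> np.ndarray:
        """Gross primary production per layer (mgC L-1)."""
        return self.amounts[GPP].copy()

    def to_frame(self, date=None):
        """Long-format view: one row per (date, layer, channel, value)."""
        import pandas as pd

        n_layers = self.amounts.shape[1]
        frame = pd.DataFrame({
            "layer": np.repeat(np.arange(n_layers), NCH),
            "channel": np.tile(CHANNELS, n_layers),
            "value": self.amounts.T.ravel(),
        })
        if date is not None:
            frame.insert(0, "date", pd.Timestamp(date))
        return frame


# ---------------------------------------------------------------------------
# process rates


def phyto_growth(a, n, par, T, params: PhytoParams, theta: float = 2.0,
                 t_ref: float = 20.0):
    """Gross nanoplankton growth, mgC L-1 day-1.

    Liebig minimum of nutrient and light Monod terms times a Q10 factor.
    """
    a = np.asarray(a, dtype=float)
    n = np.asarray(n, dtype=float)
    if (a < 0).any() or (n < 0).any():
        raise ValueError("negative concentration in phyto_growth")
    lim = np.minimum(n / (params.k_n + n), par / (params.i_k + par))
    return params.mu_max * temp_scale(T, theta, t_ref) * lim * a


def _z1_grazing(z1, z2, z3, tfac, p: GrazingParams):
    """Gross Z1 consumption of (own early stages, Z2, Z3); vectorised."""
    pw = p.pref_self * z1 + p.pref_z2 * z2 + p.pref_z3 * z3
    safe = np.where(pw > 0.0, pw, 1.0)
    total = p.g_max * tfac * z1 * pw / (p.k_graz + pw)
    f_self = total * p.pref_self * z1 / safe
    f_z2 = total * p.pref_z2 * z2 / safe
    f_z3 = total * p.pref_z3 * z3 / safe
    return f_self, f_z2, f_z3


def grazing_fluxes(z1, prey: dict, T, params: GrazingParams) -> dict:
    """Per-prey consumption by predatory zooplankton, mgC L-1 day-1.

    ``prey`` maps ``{"z1", "z2", "z3"}`` to concentrations.  The total is
    ``g_max * theta^((T-t_ref)/10) * Z1 * Pw / (k_graz + Pw)`` with
    preference-weighted prey ``Pw``; each prey receives its weighted share
    of the total, so the partition sums exactly to it.
    """
    z1 = np.asarray(z1, dtype=float)
    c1 = np.asarray(prey.get("z1", 0.0), dtype=float)
    c2 = np.asarray(prey.get("z2", 0.0), dtype=float)
    c3 = np.asarray(prey.get("z3", 0.0), dtype=float)
    if (z1 < 0).any() or (c1 < 0).any() or (c2 < 0).any() or (c3 < 0).any():
        raise ValueError("negative concentration in grazing_fluxes")
    tfac = temp_scale(T, params.theta, params.t_ref)
    pw = params.pref_self * c1 + params.pref_z2 * c2 + params.pref_z3 * c3
    safe = np.where(pw > 0.0, pw, 1.0)
    total = params.g_max * tfac * z1 * pw / (params.k_graz + pw)
    scalar = np.ndim(total) == 0
    out = {
        "z1": total * params.pref_self * c1 / safe,
        "z2": total * params.pref_z2 * c2 / safe,
        "z3": total * params.pref_z3 * c3 / safe,
    }
    if scalar:
        out = {k: float(v) for k, v in out.items()}
    return out


def day_environment(physics: PhysicsState, forcing_day, params: PlanktonParams,
                    grid: ColumnGrid) -> dict:
    """Precompute per-layer environment factors shared by all substeps of
    one day: temperature factors, light at depth, surface nutrient load."""
    T = physics.layer_temp
    tsc = temp_scale(T, params.theta, params.t_ref)
    tsc1 = temp_scale(T, params.z1.theta, params.z1.t_ref)
    par = float(forcing_day["par"]) * np.exp(-params.k_ext * grid.midpoints)
    load = np.zeros(grid.n_layers)
    load[0] = float(forcing_day["nutrient_load"]) / grid.layer_volumes[0]  # gP m-3 d-1
    q_mix = physics.mixing_coeff * np.minimum(grid.layer_volumes[:-1],
                                              grid.layer_volumes[1:])
    return {"tsc": tsc, "tsc1": tsc1, "par": par, "load": load, "q_mix": q_mix}


def _rates(y: np.ndarray, env: dict, p: PlanktonParams) -> np.ndarray:
    """Channel rates (NCH, L) per day at state ``y`` (negatives guarded)."""
    ye = np.maximum(y, 0.0)
    A, N, D, Z1, Z2, Z3 = ye
    tsc, tsc1, par = env["tsc"], env["tsc1"], env["par"]
    ch = np.zeros((NCH, y.shape[1]))

    lim = np.minimum(N / (p.phyto.k_n + N), par / (p.phyto.i_k + par))
    ch[GPP] = p.phyto.mu_max * tsc * lim * A
    ch[A_RESP] = p.phyto.resp * tsc * A
    ch[A_MORT] = p.phyto.mort * A

    ch[GZ2_A] = p.z2_gmax * tsc * Z2 * A / (p.z2_k + A)

    pw3 = p.z3_pref_a * A + p.z3_pref_d * D
    safe3 = np.where(pw3 > 0.0, pw3, 1.0)
    g3 = p.z3_gmax * tsc * Z3 * pw3 / (p.z3_k + pw3)
    ch[GZ3_A] = g3 * p.z3_pref_a * A / safe3
    ch[GZ3_D] = g3 * p.z3_pref_d * D / safe3

    ch[GZ1_Z1], ch[GZ1_Z2], ch[GZ1_Z3] = _z1_grazing(Z1, Z2, Z3, tsc1, p.z1)

    ch[Z1_RESP] = p.zoo_resp * tsc * Z1
    ch[Z2_RESP] = p.zoo_resp * tsc * Z2
    ch[Z3_RESP] = p.zoo_resp * tsc * Z3
    ch[Z1_MORT] = p.zoo_mort * Z1
    ch[Z2_MORT] = p.zoo_mort * Z2
    ch[Z3_MORT] = p.zoo_mort * Z3
    ch[D_REMIN] = p.remin_rate * tsc * D
    ch[N_LOAD] = env["load"]
    return ch


def pool_deltas(ch: np.ndarray, p: PlanktonParams) -> np.ndarray:
    """Signed pool changes (6, L) implied by channel amounts/rates ``ch``.

    This is the single place where channels map to pools, so recorded
    fluxes and applied changes agree identically.
    """
    ae1, ae2, ae3 = p.z1.assim, p.z2_assim, p.z3_assim
    gz1 = ch[GZ1_Z1] + ch[GZ1_Z2] + ch[GZ1_Z3]
    gz3 = ch[GZ3_A] + ch[GZ3_D]
    zresp = ch[Z1_RESP] + ch[Z2_RESP] + ch[Z3_RESP]
    dy = np.empty((6, ch.shape[1]))
    dy[POOL_A] = ch[GPP] - ch[A_RESP] - ch[A_MORT] - ch[GZ2_A] - ch[GZ3_A]
    dy[POOL_N] = (p.p_to_c * (ch[A_RESP] + zresp
                              + (1.0 - p.burial_frac) * ch[D_REMIN] - ch[GPP])
                  + ch[N_LOAD])
    dy[POOL_D] = (ch[A_MORT] + (1.0 - ae2) * ch[GZ2_A] + (1.0 - ae3) * gz3
                  + (1.0 - ae1) * gz1
                  + ch[Z1_MORT] + ch[Z2_MORT] + ch[Z3_MORT]
                  - ch[GZ3_D] - ch[D_REMIN])
    dy[POOL_Z1] = ae1 * gz1 - ch[GZ1_Z1] - ch[Z1_RESP] - ch[Z1_MORT]
    dy[POOL_Z2] = ae2 * ch[GZ2_A] - ch[GZ1_Z2] - ch[Z2_RESP] - ch[Z2_MORT]
    dy[POOL_Z3] = ae3 * gz3 - ch[GZ1_Z3] - ch[Z3_RESP] - ch[Z3_MORT]
    # mixing channels are pure per-pool additions
    dy[POOL_A] += ch[MIX_A]
    dy[POOL_N] += ch[MIX_N]
    dy[POOL_D] += ch[MIX_D]
    dy[POOL_Z1] += ch[MIX_Z1]
    dy[POOL_Z2] += ch[MIX_Z2]
    dy[POOL_Z3] += ch[MIX_Z3]
    return dy


_OUTGOING = {
    POOL_A: (A_RESP, A_MORT, GZ2_A, GZ3_A),
    POOL_D: (GZ3_D, D_REMIN),
    POOL_Z1: (GZ1_Z1, Z1_RESP, Z1_MORT),
    POOL_Z2: (GZ1_Z2, Z2_RESP, Z2_MORT),
    POOL_Z3: (GZ1_Z3, Z3_RESP, Z3_MORT),
}
# headroom keeps a limited pool strictly non-negative under rounding
_LIMITER_MARGIN = 1.0 - 1e-12


def _limit(ch: np.ndarray, y: np.ndarray, p: PlanktonParams) -> None:
    """Proportionally scale outgoing channel amounts so no pool overdraws.

    Nutrient drawdown (the stoichiometric cost of GPP) is limited against
    the N pool; all organic pools limit their own gross outgoing fluxes.
    Scaling a channel affects source and destination alike, so mass is
    never created.
    """
    for pool, chans in _OUTGOING.items():
        out = ch[list(chans)].sum(axis=0)
        need = out > np.maximum(y[pool], 0.0)
        if need.any():
            s = np.where(need, np.maximum(y[pool], 0.0) / np.where(out > 0, out, 1.0)
                         * _LIMITER_MARGIN, 1.0)
            for c in chans:
                ch[c] *= s
    out_n = p.p_to_c * ch[GPP]
    need = out_n > np.maximum(y[POOL_N], 0.0) + ch[N_LOAD]
    if need.any():
        s = np.where(need,
                     (np.maximum(y[POOL_N], 0.0) + ch[N_LOAD])
                     / np.where(out_n > 0, out_n, 1.0) * _LIMITER_MARGIN, 1.0)
        ch[GPP] *= s


def _mixing(y: np.ndarray, env: dict, grid: ColumnGrid, dt: float) -> np.ndarray:
    """Explicit conservative exchange between adjacent layers.

    Returns per-pool mixing amounts (6, L) such that the lake-wide
    volume-weighted total of each pool is unchanged.
    """
    min_vol = np.minimum(grid.layer_volumes[:-1], grid.layer_volumes[1:])
    # cap the exchanged volume so simultaneous pairwise exchange can never
    # overdraw a layer, whatever dt (fraction per interface <= 1/2)
    q = np.minimum(env["q_mix"] * dt, 0.5 * min_vol)
    diff = y[:, 1:] - y[:, :-1]               # conc difference across interface
    transfer = q * diff                       # g moved upward (per pool)
    mix = np.zeros_like(y)
    mix[:, :-1] += transfer / grid.layer_volumes[:-1]
    mix[:, 1:] -= transfer / grid.layer_volumes[1:]
    return mix


def step_plankton(state: PlanktonState, physics: PhysicsState, forcing_day,
                  dt: float, params: PlanktonParams,
                  env: dict | None = None) -> tuple[PlanktonState, FluxRecord]:
    """Advance the plankton stage by one substep of length ``dt`` (day).

    Classic fixed-step RK4 on the reaction terms, followed by the flux
    limiter on the combined amounts, followed by explicit conservative
    vertical mixing.  Returns the new state and the applied flux record;
    the state change equals :func:`pool_deltas` of the record exactly.
    """
    if not (0.0 < dt <= 1.0):
        raise ValueError("dt must be in (0, 1] day")
    if not np.isfinite(state.y).all():
        raise ValueError("non-finite plankton state entering step")
    grid = state.grid
    if env is None:
        env = day_environment(physics, forcing_day, params, grid)
    y = state.y

    k1 = _rates(y, env, params)
    k2 = _rates(y + (0.5 * dt) * pool_deltas(k1, params), env, params)
    k3 = _rates(y + (0.5 * dt) * pool_deltas(k2, params), env, params)
    k4 = _rates(y + dt * pool_deltas(k3, params), env, params)
    ch = (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

    _limit(ch, y, params)
    y_new = y + pool_deltas(ch, params)
    ch[MIX_A:MIX_Z3 + 1] = _mixing(y_new, env, grid, dt)
    y_new = y_new + ch[MIX_A:MIX_Z3 + 1]

    if not np.isfinite(y_new).all():
        raise ArithmeticError(
            f"plankton integration produced non-finite values on "
            f"{forcing_day.name if hasattr(forcing_day, 'name') else 'day'}")
    new_state = PlanktonState(grid=grid, y=y_new)
    return new_state, FluxRecord(amounts=ch, params=params)


def reaction_rhs(y_flat: np.ndarray, env: dict, params: PlanktonParams,
                 n_layers: int) -> np.ndarray:
    """Flat reaction-term derivative for adaptive reference integrators.

    Same right-hand side :func:`step_plankton` integrates (mixing and
    limiter excluded), packaged for ``scipy.integrate.solve_ivp``.
    """
    y = y_flat.reshape(6, n_layers)
    return pool_deltas(_rates(y, env, params), params).ravel()
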