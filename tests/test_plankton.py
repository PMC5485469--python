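import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igplake.grid import ColumnGrid, PhysicsState
from igplake.plankton import (CARBON_POOLS, GrazingParams, PhytoParams,
                              PlanktonParams, PlanktonState, grazing_fluxes,
                              phyto_growth, pool_deltas, step_plankton,
                              temp_scale)

finite_conc = st.floats(min_value=0.0, max_value=5.0, allow_nan=False)


class TestTempScale:
    def test_unity_at_reference(self):
        assert temp_scale(20.0, theta=2.0, t_ref=20.0) == 1.0

    def test_q10_convention_doubles_over_ten_degrees(self):
        assert temp_scale(30.0, theta=2.0, t_ref=20.0) == pytest.approx(2.0)
        assert temp_scale(10.0, theta=2.0, t_ref=20.0) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(t1=st.floats(-5, 35), dt=st.floats(0.01, 20),
           theta=st.floats(1.01, 4.0))
    def test_strictly_increasing_in_temperature(self, t1, dt, theta):
        assert temp_scale(t1 + dt, theta, 20.0) > temp_scale(t1, theta, 20.0)

    def test_theta_must_exceed_one(self):
        with pytest.raises(ValueError):
            temp_scale(20.0, theta=1.0, t_ref=20.0)


class TestGrazingFluxes:
    def test_worked_multi_prey_example(self):
        # independently evaluated from the stated functional response:
        # Pw = 0.5*0.05 + 0.35*0.05 + 0.15*0.01 = 0.0440
        # total = 3.03 * 0.01 * 0.0440/(0.05 + 0.0440) = 0.0141830
        params = GrazingParams(g_max=3.03, k_graz=0.05)
        fluxes = grazing_fluxes(0.01, {"z1": 0.01, "z2": 0.05, "z3": 0.05},
                                T=params.t_ref, params=params)
        assert sum(fluxes.values()) == pytest.approx(0.0141830, abs=5e-7)
        assert fluxes["z2"] == pytest.approx(0.0056410, abs=5e-7)

    def test_no_prey_no_flux(self):
        params = GrazingParams()
        fluxes = grazing_fluxes(0.5, {"z1": 0.0, "z2": 0.0, "z3": 0.0},
                                T=25.0, params=params)
        assert fluxes == {"z1": 0.0, "z2": 0.0, "z3": 0.0}

    def test_saturation_limit_approaches_gmax(self):
        params = GrazingParams(k_graz=1e-12)
        fluxes = grazing_fluxes(0.01, {"z1": 0.0, "z2": 0.3, "z3": 0.1},
                                T=params.t_ref, params=params)
        assert sum(fluxes.values()) == pytest.approx(3.03 * 0.01, rel=1e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            grazing_fluxes(0.1, {"z1": -0.01, "z2": 0.0, "z3": 0.0},
                           T=20.0, params=GrazingParams())

    @settings(derandomize=True, max_examples=100)
    @given(z1=finite_conc, c1=finite_conc, c2=finite_conc, c3=finite_conc,
           T=st.floats(5, 32))
    def test_partition_sums_to_total(self, z1, c1, c2, c3, T):
        params = GrazingParams()
        fluxes = grazing_fluxes(z1, {"z1": c1, "z2": c2, "z3": c3}, T, params)
        pw = 0.15 * c1 + 0.35 * c2 + 0.5 * c3
        total = (params.g_max * temp_scale(T, 2.0, 20.0) * z1
                 * pw / (params.k_graz + pw)) if pw > 0 else 0.0
        assert sum(fluxes.values()) == pytest.approx(total, rel=1e-12, abs=1e-300)


class TestGrazingParams:
    def test_preferences_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GrazingParams(pref_z3=0.5, pref_z2=0.4, pref_self=0.2)

    def test_assimilation_bounds(self):
        with pytest.raises(ValueError):
            GrazingParams(assim=0.0)


class TestPhytoGrowth:
    def test_no_seed_population_no_growth(self):
        assert phyto_growth(0.0, 0.05, 200.0, 20.0, PhytoParams()) == 0.0

    def test_unlimited_limit_is_mu_max_times_biomass(self):
        p = PhytoParams()
        flux = phyto_growth(0.2, 1e9, 1e9, 20.0, p)
        assert flux == pytest.approx(p.mu_max * 0.2, rel=1e-6)

    def test_half_saturation_of_nutrient(self):
        p = PhytoParams()
        flux = phyto_growth(0.2, p.k_n, 1e9, 20.0, p)
        assert flux == pytest.approx(0.5 * p.mu_max * 0.2, rel=1e-6)


@pytest.fixture
def column():
    grid = ColumnGrid.frustum(n_layers=5)
    physics = PhysicsState(layer_temp=np.array([24., 24., 24., 16., 16.]),
                           mixing_coeff=np.array([3., 3., 0.02, 0.02]))
    return grid, physics


class TestStepPlankton:
    def test_state_change_equals_recorded_fluxes(self, column, constant_day):
        grid, physics = column
        params = PlanktonParams()
        state = PlanktonState.uniform(grid)
        new, record = step_plankton(state, physics, constant_day, 1 / 24, params)
        np.testing.assert_allclose(new.y - state.y,
                                   pool_deltas(record.amounts, params),
                                   rtol=1e-12, atol=1e-16)

    def test_closed_column_conserves_carbon_and_phosphorus(self, column,
                                                           constant_day):
        grid, physics = column
        params = PlanktonParams(burial_frac=0.0)
        state = PlanktonState.uniform(grid)
        c0 = state.total_carbon()
        p0 = state.total_phosphorus(params.p_to_c)
        respired = 0.0
        fixed = 0.0
        for _ in range(48):
            state, rec = step_plankton(state, physics, constant_day, 1 / 24,
                                       params)
            respired += float(rec.respired_carbon() @ grid.layer_volumes)
            fixed += float(rec.fixed_carbon() @ grid.layer_volumes)
            drift = abs(state.total_carbon() + respired - fixed - c0) / c0
            assert drift <= 1e-9
        assert state.total_phosphorus(params.p_to_c) == pytest.approx(p0, rel=1e-9)

    def test_zooplankton_free_subspace_is_invariant(self, column, constant_day):
        grid, physics = column
        state = PlanktonState.uniform(grid, z1=0.0, z2=0.0, z3=0.0)
        params = PlanktonParams()
        for _ in range(48):
            state, _ = step_plankton(state, physics, constant_day, 1 / 24, params)
        assert (state.z1 == 0).all() and (state.z2 == 0).all() \
            and (state.z3 == 0).all()
        assert state.a.max() > 0  # the basal resource still grows

    def test_flux_limiter_preserves_positivity_under_extreme_rates(
            self, column, constant_day):
        grid, physics = column
        params = PlanktonParams(z2_gmax=80.0, z3_gmax=50.0,
                                z1=GrazingParams(g_max=300.0, k_graz=0.01))
        state = PlanktonState.uniform(grid, a=0.001, n=1e-5, z1=2.0, z2=2.0,
                                      z3=2.0)
        for _ in range(24):
            state, _ = step_plankton(state, physics, constant_day, 1.0, params)
            assert (state.y >= 0).all()

    def test_mixing_is_conservative_and_homogenising(self, column, constant_day):
        grid, physics = column
        params = PlanktonParams()
        y = np.zeros((6, grid.n_layers))
        y[2] = np.linspace(1.0, 0.0, grid.n_layers)  # detritus gradient
        params_nolosses = PlanktonParams(remin_rate=1e-12, z3_gmax=1e-12)
        state = PlanktonState(grid=grid, y=y)
        total0 = float(state.d @ grid.layer_volumes)
        spread0 = state.d.max() - state.d.min()
        for _ in range(24):
            state, _ = step_plankton(state, physics, constant_day, 1 / 24,
                                     params_nolosses)
        total1 = float(state.d @ grid.layer_volumes)
        assert total1 == pytest.approx(total0, rel=1e-6)
        assert state.d.max() - state.d.min() < spread0

    def test_invalid_dt_rejected(self, column, constant_day):
        grid, physics = column
        state = PlanktonState.uniform(grid)
        with pytest.raises(ValueError):
            step_plankton(state, physics, constant_day, 0.0, PlanktonParams())

    def test_negative_state_rejected_at_construction(self, column):
        grid, _ = column
        y = np.zeros((6, grid.n_layers))
        y[0, 0] = -1e-3
        with pytest.raises(ValueError):
            PlanktonState(grid=grid, y=y)
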