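import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igplake.fish import (FishParams, FishPopulation, apply_mortality,
                          bioenergetics_update, fish_consumption,
                          recruitment_event, recruitment_multiplier,
                          redistribute_vertical)


class TestConsumption:
    def test_worked_multi_prey_example(self):
        # Ew = 0.4*0.02 + 0.5*0.10 + 0.02*0.10 = 0.060
        # total = 0.2 * 0.060/(0.05+0.060) = 0.109091; Z2 share = 0.05/0.06
        params = FishParams(k_fish=0.05, cmax_a=0.2, cmax_b=0.0)
        intake = fish_consumption(1.0, {"z1": 0.02, "z2": 0.10, "z3": 0.10},
                                  T=params.t_ref, params=params)
        assert sum(intake.values()) == pytest.approx(0.109091, abs=1e-6)
        assert intake["z2"] == pytest.approx(0.090909, abs=1e-6)

    def test_starvation_case(self):
        intake = fish_consumption(10.0, {"z1": 0.0, "z2": 0.0, "z3": 0.0},
                                  T=20.0, params=FishParams())
        assert intake == {"z1": 0.0, "z2": 0.0, "z3": 0.0}

    def test_saturation_attains_maximum_ration(self):
        params = FishParams()
        intake = fish_consumption(10.0, {"z1": 1e6, "z2": 1e6, "z3": 1e6},
                                  T=24.0, params=params)
        assert sum(intake.values()) == pytest.approx(
            float(params.cmax(10.0, 24.0)), rel=1e-5)

    def test_negative_prey_rejected(self):
        with pytest.raises(ValueError):
            fish_consumption(10.0, {"z1": -0.1, "z2": 0.0, "z3": 0.0},
                             T=20.0, params=FishParams())

    @settings(derandomize=True, max_examples=60)
    @given(w=st.floats(0.5, 200), c=st.floats(0, 2), T=st.floats(10, 30))
    def test_intake_never_exceeds_maximum_ration(self, w, c, T):
        params = FishParams()
        intake = fish_consumption(w, {"z1": c, "z2": c, "z3": c}, T, params)
        assert sum(intake.values()) <= float(params.cmax(w, T)) * (1 + 1e-12)


class TestBioenergetics:
    def test_specific_growth_balance_arithmetic(self):
        # c = 0.03, total losses 0.02 -> g = 0.01 day-1, W: 5 -> 5.05
        params = FishParams(egestion_frac=0.2, excretion_frac=0.1,
                            sda_frac=0.1, resp_frac=0.2, resp_basal=0.002,
                            carbon_to_ww=0.05)
        intake = 0.03 * 0.05 * 5.0  # c = intake/(c2w*W) = 0.03
        new_w, fluxes = bioenergetics_update(5.0, intake, params.t_ref, params)
        assert new_w == pytest.approx(5.05, rel=1e-12)
        assert fluxes["growth"] == pytest.approx(0.01 * 0.05 * 5.0, rel=1e-9)

    def test_starving_fish_lose_weight(self):
        new_w, fluxes = bioenergetics_update(10.0, 0.0, 20.0, FishParams())
        assert new_w < 10.0
        assert fluxes["growth"] < 0

    @settings(derandomize=True, max_examples=60)
    @given(w=st.floats(0.5, 100), intake=st.floats(0, 0.5), T=st.floats(10, 30),
           pulse=st.booleans())
    def test_carbon_balance_closes_exactly(self, w, intake, T, pulse):
        _, fx = bioenergetics_update(w, intake, T, FishParams(),
                                     repro_pulse=pulse)
        back = (fx["growth"] + fx["egestion"] + fx["excretion"]
                + fx["respiration"] + fx["reproduction"])
        assert back == pytest.approx(intake, rel=1e-9, abs=1e-12)

    def test_negative_intake_rejected(self):
        with pytest.raises(ValueError):
            bioenergetics_update(5.0, -0.1, 20.0, FishParams())


def _population(n_super=100, fish_per_super=1000.0, seed=0, n_layers=5):
    return FishPopulation.initialise(FishParams(), n_super=n_super,
                                     fish_per_super=fish_per_super,
                                     seed=seed, n_layers=n_layers)


class TestRedistribution:
    def test_uniform_conditions_give_uniform_occupancy(self):
        pop = _population(n_super=10_000)
        prey = np.full((3, 5), 0.05)
        temp = np.full(5, 24.0)
        redistribute_vertical(pop, prey, temp, FishParams())
        counts = np.bincount(pop.layer, minlength=5)
        n, p = 10_000, 1 / 5
        sigma = np.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) <= 3 * sigma).all()

    def test_all_prey_in_one_layer_attracts_all_fish(self):
        pop = _population(n_super=500)
        prey = np.zeros((3, 5))
        prey[:, 2] = 1.0
        redistribute_vertical(pop, prey, np.full(5, 24.0), FishParams())
        assert (pop.layer == 2).all()

    def test_fixed_seed_reproduces_assignment(self):
        prey = np.random.default_rng(3).uniform(0, 0.1, size=(3, 5))
        temp = np.linspace(28, 15, 5)
        pops = [_population(seed=7) for _ in range(2)]
        for pop in pops:
            redistribute_vertical(pop, prey, temp, FishParams())
        assert (pops[0].layer == pops[1].layer).all()

    def test_no_habitable_layer_leaves_fish_in_place(self, caplog):
        pop = _population(n_super=50)
        before = pop.layer.copy()
        freezing = np.full(5, -40.0)
        with caplog.at_level("WARNING"):
            redistribute_vertical(pop, np.full((3, 5), 0.05), freezing,
                                  FishParams())
        assert (pop.layer == before).all()


class TestRecruitment:
    def test_no_rise_is_baseline(self):
        assert recruitment_multiplier(0.0, FishParams()) == 1.0
        assert recruitment_multiplier(1.0, FishParams()) == 1.0

    def test_multiplier_non_decreasing_in_rise(self):
        params = FishParams()
        rises = np.linspace(0, 6, 30)
        mults = [recruitment_multiplier(r, params) for r in rises]
        assert (np.diff(mults) >= 0).all()

    def test_negative_rise_rejected(self):
        with pytest.raises(ValueError):
            recruitment_multiplier(-0.1, FishParams())

    def test_flood_pulse_lifts_population_at_least_eightfold(self):
        params = FishParams()
        pop = _population(n_super=1000, fish_per_super=100_000.0)
        pop.length[:] = params.maturity_length_cm + 1.0  # all adults
        before = pop.total_count()
        recruitment_event(pop, 4.5, params, n_layers=5)
        assert pop.total_count() >= 8.0 * before

    def test_recruits_are_small_noncommercial_fish(self):
        params = FishParams()
        pop = _population()
        n0 = len(pop.count)
        recruitment_event(pop, 2.0, params, n_layers=5)
        new = slice(n0, None)
        assert (pop.weight[new] == params.recruit_weight).all()
        assert (pop.length[new] < params.commercial_length_cm).all()


class TestMortality:
    def test_zero_rates_leave_counts_unchanged(self):
        params = FishParams(natural_mortality=0.0, exploit_commercial=0.0,
                            exploit_noncommercial=0.0)
        pop = _population()
        before = pop.count.copy()
        apply_mortality(pop, 1.0, params)
        assert (pop.count == before).all()

    def test_fifty_percent_annual_exploitation_compounds_exactly(self):
        # 1 - 0.5 = exp(-365 f): daily thinning for a year halves the stock
        params = FishParams(natural_mortality=0.0, exploit_commercial=50.0,
                            exploit_noncommercial=50.0)
        pop = _population(n_super=10, fish_per_super=1000.0)
        before = pop.total_count()
        for _ in range(365):
            apply_mortality(pop, 1.0, params)
        assert pop.total_count() / before == pytest.approx(0.5, abs=1e-9)

    def test_commercial_length_threshold_selects_rate(self):
        params = FishParams(exploit_commercial=28.0, exploit_noncommercial=0.0)
        assert params.fishing_rate(11.9) == 0.0
        assert params.fishing_rate(12.1) == pytest.approx(
            -np.log(1 - 0.28) / 365.0)

    def test_death_accounting_closes(self):
        params = FishParams(exploit_commercial=40.0, exploit_noncommercial=10.0,
                            natural_mortality=0.01)
        pop = _population(n_super=20)
        before = pop.total_count()
        out = apply_mortality(pop, 5.0, params)
        total_after = pop.total_count()
        assert (before - total_after) == pytest.approx(
            out["harvested_count"] + out["natural_count"], rel=1e-12)

    def test_overfull_exploitation_rejected(self):
        with pytest.raises(ValueError):
            FishParams(exploit_commercial=120.0)


def test_length_weight_relation_round_trips():
    params = FishParams()
    w = np.array([0.5, 5.0, 17.0, 60.0])
    np.testing.assert_allclose(params.weight_from_length(
        params.length_from_weight(w)), w, rtol=1e-12)
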