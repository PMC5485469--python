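import math

import numpy as np
import pandas as pd
import pytest

from igplake.ledger import (CHANNELS6, PredationLedger, annual_channel_totals,
                            build_scenario_table, dominance_ratio_series,
                            monthly_climatology, mortality_partition)
from igplake.tables import REFERENCE_ANNUAL_PREDATION

VOLUME = 4.0e9
C2W = 0.05


def _ledger_from_rates(rates: pd.DataFrame) -> PredationLedger:
    """Build a ledger from ugC L-1 day-1 rate columns."""
    daily_gc = rates / 1000.0 * VOLUME
    return PredationLedger.from_daily_carbon(daily_gc, VOLUME, C2W)


@pytest.fixture
def toy_ledger():
    idx = pd.date_range("2000-01-01", "2001-12-31", freq="D")
    rng = np.random.default_rng(0)
    data = {c: rng.uniform(0.5, 5.0, len(idx)) for c in CHANNELS6}
    data["z2_nonpred"] = rng.uniform(0.1, 1.0, len(idx))
    return _ledger_from_rates(pd.DataFrame(data, index=idx))


class TestUnits:
    def test_rate_lakewide_round_trip_is_identity(self, toy_ledger):
        rate = toy_ledger.rates["z1_z2"]
        back = toy_ledger.lakewide_to_rate(toy_ledger.rate_to_lakewide(rate))
        np.testing.assert_allclose(back, rate, rtol=1e-12)

    def test_lakewide_consistent_with_carbon_input(self, toy_ledger):
        # 1 ugC/L/day over 4e9 m3 = 4e3 kgC/day = 4e6/0.05 g ww = 80 t ww
        one = toy_ledger.rate_to_lakewide(1.0)
        assert one == pytest.approx(80.0, rel=1e-12)


class TestClimatology:
    def test_mean_of_constant_series(self):
        idx = pd.date_range("2000-01-01", "2000-12-31", freq="D")
        s = pd.Series(3.7, index=idx)
        assert monthly_climatology(s, 6) == pytest.approx(3.7)

    def test_two_point_mean(self):
        s = pd.Series([2.0, 4.0], index=pd.to_datetime(["2000-05-01",
                                                        "2000-05-02"]))
        assert monthly_climatology(s, 5) == 3.0

    def test_missing_month_is_nan(self):
        s = pd.Series([1.0], index=pd.to_datetime(["2000-05-01"]))
        assert math.isnan(monthly_climatology(s, 11))

    def test_multi_year_pooling_matches_two_pass_mean(self, toy_ledger):
        s = toy_ledger.rates["z1_z2"]
        pooled = monthly_climatology(s, 1)
        per_year = [s[(s.index.year == y) & (s.index.month == 1)]
                    for y in (2000, 2001)]
        two_pass = np.concatenate([p.to_numpy() for p in per_year]).mean()
        assert pooled == pytest.approx(float(two_pass), rel=1e-12)


class TestDominanceRatio:
    def _make(self, z1_z2, f_z2):
        idx = pd.date_range("2000-01-01", periods=len(z1_z2), freq="D")
        data = {c: np.zeros(len(idx)) for c in CHANNELS6}
        data["z1_z2"] = np.array(z1_z2, dtype=float)
        data["f_z2"] = np.array(f_z2, dtype=float)
        data["z2_nonpred"] = np.zeros(len(idx))
        return _ledger_from_rates(pd.DataFrame(data, index=idx))

    def test_elementwise_ratio(self):
        out = dominance_ratio_series(self._make([4.0], [2.0]))
        assert out.iloc[0] == 2.0

    def test_zero_over_zero_is_missing(self):
        out = dominance_ratio_series(self._make([0.0], [0.0]))
        assert math.isnan(out.iloc[0])

    def test_positive_over_zero_is_infinite(self):
        out = dominance_ratio_series(self._make([1.0], [0.0]))
        assert math.isinf(out.iloc[0])

    def test_dominance_flag_above_one(self):
        out = dominance_ratio_series(self._make([3.0, 1.0], [1.0, 2.0]))
        assert (out > 1).tolist() == [True, False]


class TestMortalityPartition:
    def _make(self, fish, zoo, nonpred):
        idx = pd.date_range("2000-01-01", periods=len(fish), freq="D")
        data = {c: np.zeros(len(idx)) for c in CHANNELS6}
        data["f_z2"] = np.array(fish, dtype=float)
        data["z1_z2"] = np.array(zoo, dtype=float)
        data["z2_nonpred"] = np.array(nonpred, dtype=float)
        return _ledger_from_rates(pd.DataFrame(data, index=idx))

    def test_normalisation(self):
        out = mortality_partition(self._make([1.0], [8.0], [1.0]))
        assert out.iloc[0].to_dict() == pytest.approx(
            {"fish": 0.1, "zoo": 0.8, "nonpred": 0.1})

    def test_single_channel_degenerate(self):
        out = mortality_partition(self._make([0.0], [5.0], [0.0]))
        assert out.iloc[0]["zoo"] == 1.0

    def test_zero_total_rows_dropped_and_rows_sum_to_one(self):
        out = mortality_partition(self._make([1.0, 0.0], [2.0, 0.0],
                                             [3.0, 0.0]))
        assert len(out) == 1
        np.testing.assert_allclose(out.sum(axis=1), 1.0, rtol=1e-12)


class TestAnnualTotals:
    def test_matches_trapezoid_integral(self, toy_ledger):
        totals = annual_channel_totals(toy_ledger)
        lw = toy_ledger.lakewide["z1_z2"].to_numpy()
        trapz = np.trapezoid(lw) / (len(lw) - 1) * 365.25 / 1e3
        assert totals["z1_z2"] == pytest.approx(trapz, rel=1e-3)


class TestScenarioTable:
    @pytest.fixture
    def table(self):
        return build_scenario_table(REFERENCE_ANNUAL_PREDATION, "x1")

    def test_group_totals_recompute_from_channels(self, table):
        assert table.table.loc["total_z_pred", "x1"] == pytest.approx(45.02)
        assert table.table.loc["total_f_pred", "x1"] == pytest.approx(15.28)
        assert table.table.loc["total_pred", "x1"] == pytest.approx(60.30)
        assert table.table.loc["total_on_z2", "x1"] == pytest.approx(44.64)

    def test_channel_ratios_round_to_reported_precision(self, table):
        assert table.ratios.loc["z1_z1/f_z1", "x1"] == 5.32
        assert table.ratios.loc["z1_z2/f_z2", "x1"] == 2.48
        assert table.ratios.loc["z1_z1/f_z1", "x2"] == 1.98

    def test_percent_of_base(self, table):
        assert table.percent_of_base.loc["f_z1", "x8"] == 211
        assert table.percent_of_base.loc["z1_z1", "x2"] == 55  # 6.89/12.62
        assert (table.percent_of_base["x1"] == 100).all()

    def test_zero_base_channel_marks_percent_undefined(self):
        channels = {lab: dict(v) for lab, v in
                    REFERENCE_ANNUAL_PREDATION.items()}
        for lab in channels:
            channels[lab]["f_z3"] = 0.0
        table = build_scenario_table(channels, "x1")
        assert math.isnan(table.percent_of_base.loc["f_z3", "x8"])
        assert math.isnan(table.ratios.loc["z1_z3/f_z3", "x1"])

    def test_missing_base_rejected(self):
        with pytest.raises(ValueError):
            build_scenario_table(REFERENCE_ANNUAL_PREDATION, "x99")

    def test_csv_export(self, table, tmp_path):
        path = tmp_path / "table.csv"
        table.to_csv(path)
        text = path.read_text()
        assert "total_on_z2" in text and "percent of base" in text


def test_flux_record_long_format_round_trips_amounts():
    from igplake.grid import ColumnGrid, PhysicsState
    from igplake.plankton import (CHANNELS, PlanktonParams, PlanktonState,
                                  step_plankton)
    grid = ColumnGrid.frustum(n_layers=4)
    physics = PhysicsState(layer_temp=np.full(4, 22.0),
                           mixing_coeff=np.full(3, 1.0))
    day = pd.Series({"surface_temp": 22.0, "par": 180.0,
                     "mixed_layer_depth": 40.0, "water_level": 0.0,
                     "nutrient_load": 0.0})
    _, record = step_plankton(PlanktonState.uniform(grid), physics, day,
                              1 / 24, PlanktonParams())
    frame = record.to_frame("2000-03-01")
    assert set(frame.columns) == {"date", "layer", "channel", "value"}
    pivoted = frame.pivot(index="channel", columns="layer", values="value")
    np.testing.assert_array_equal(pivoted.loc[list(CHANNELS)].to_numpy(),
                                  record.amounts)
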