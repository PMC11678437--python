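"""Cost engine: inflation, blending, accrual, shares, poverty ratios."""

import numpy as np
import pytest

from malnutburden import colombia
from malnutburden.costs import (
    CostConfigError,
    CostTable,
    InflationSeries,
    StateCostSchedule,
    CostComponent,
    TherapyAddon,
    UnitCost,
    accrue_direct,
    accrue_indirect,
    back_solve_indirect,
    blended_state_cost,
    inflate,
    poverty_burden_ratio,
    resolve_schedules,
    totals_and_shares,
)

SERIES = InflationSeries(
    {
        (2019, 2023): 956.11 / 698.16,
        (2015, 2023): 86.35 / 52.60,
        (2021, 2023): 460.03 / 560.52,
        (2023, 2019): 698.16 / 956.11,
    }
)


class TestInflation:
    @pytest.mark.parametrize(
        "amount,year,expected",
        [(698.16, 2019, 956.11), (52.60, 2015, 86.35), (560.52, 2021, 460.03)],
    )
    def test_standardizes_published_costs_to_2023(self, amount, year, expected):
        out = inflate(UnitCost(amount, year), SERIES, 2023)
        assert out.amount == pytest.approx(expected, abs=0.005)
        assert out.price_year == 2023

    def test_same_year_is_identity(self):
        assert inflate(UnitCost(10.0, 2023), SERIES, 2023).amount == 10.0

    def test_missing_factor_is_config_error(self):
        with pytest.raises(CostConfigError, match="2010 -> 2023"):
            inflate(UnitCost(1.0, 2010), SERIES, 2023)

    def test_round_trip_with_reciprocal_factors(self):
        once = inflate(UnitCost(698.16, 2019), SERIES, 2023)
        back = inflate(once, SERIES, 2019)
        assert back.amount == pytest.approx(698.16, rel=1e-9)


class TestBlending:
    def test_wasting_composition_as_published(self):
        sched = StateCostSchedule(
            state="wasting",
            components=(
                CostComponent(0.42, UnitCost(956.11, 2023)),
                CostComponent(0.53, UnitCost(86.35, 2023)),
            ),
        )
        assert blended_state_cost(sched) == pytest.approx(447.33, abs=0.005)

    def test_single_component_passthrough(self):
        sched = StateCostSchedule(
            state="s", components=(CostComponent(1.0, UnitCost(460.03, 2023)),)
        )
        assert blended_state_cost(sched) == pytest.approx(460.03)

    def test_mixed_price_years_rejected(self):
        sched = StateCostSchedule(
            state="s",
            components=(
                CostComponent(0.5, UnitCost(1.0, 2019)),
                CostComponent(0.5, UnitCost(1.0, 2023)),
            ),
        )
        with pytest.raises(CostConfigError, match="price years"):
            blended_state_cost(sched)

    def test_combined_state_takes_maximum_item_cost(self):
        cfg = colombia.cost_config()
        resolved = resolve_schedules(cfg["schedules"], cfg["inflation"], cfg["target_year"])
        assert resolved["wasting_stunting"][1] == pytest.approx(956.11, abs=0.005)

    def test_linearity_in_unit_costs(self):
        base = StateCostSchedule(
            state="s",
            components=(
                CostComponent(0.4, UnitCost(100.0, 2023)),
                CostComponent(0.5, UnitCost(10.0, 2023)),
            ),
        )
        doubled = StateCostSchedule(
            state="s",
            components=(
                CostComponent(0.4, UnitCost(200.0, 2023)),
                CostComponent(0.5, UnitCost(20.0, 2023)),
            ),
        )
        assert blended_state_cost(doubled) == pytest.approx(2 * blended_state_cost(base))


class TestDirectAccrual:
    def test_person_cycles_times_blended_cost(self, tiny_trace):
        resolved = {
            "disabled": (
                StateCostSchedule(
                    state="disabled",
                    components=(
                        CostComponent(0.42, UnitCost(956.11, 2023)),
                        CostComponent(0.53, UnitCost(86.35, 2023)),
                    ),
                    active_cycles=frozenset({1, 2}),
                ),
                447.3317,
            )
        }
        direct = accrue_direct(tiny_trace, resolved)
        assert direct[0] == pytest.approx(200 * 447.3317)
        assert direct[1] == pytest.approx(300 * 447.3317)

    def test_zero_occupancy_zero_cost(self, tiny_trace):
        resolved = {
            "disabled": (
                StateCostSchedule(
                    state="disabled",
                    components=(CostComponent(1.0, UnitCost(100.0, 2023)),),
                    active_cycles=frozenset(),
                ),
                100.0,
            )
        }
        assert accrue_direct(tiny_trace, resolved).sum() == 0

    def test_inactive_cycles_accrue_nothing(self, col_trace):
        cfg = colombia.cost_config()
        resolved = resolve_schedules(cfg["schedules"], cfg["inflation"], cfg["target_year"])
        direct = accrue_direct(col_trace, resolved)
        # cycles 1-2 carry only the wasting cost (therapy starts at age two)
        wasting = col_trace.state_occupancy("wasting")[1:]
        amount = resolved["wasting"][1]
        assert direct[0] == pytest.approx(wasting[0] * amount)
        assert direct[1] == pytest.approx(wasting[1] * amount)
        assert direct[2] > wasting[2] * amount  # stunting therapy now active

    def test_unknown_state_rejected(self, tiny_trace):
        resolved = {
            "ghost": (
                StateCostSchedule(
                    state="ghost",
                    components=(CostComponent(1.0, UnitCost(1.0, 2023)),),
                    active_cycles=frozenset({1}),
                ),
                1.0,
            )
        }
        with pytest.raises(CostConfigError, match="unknown states"):
            accrue_direct(tiny_trace, resolved)

    def test_linear_in_occupancy(self, col_model):
        from malnutburden.markov import NewbornAllocation, simulate

        space, matrix, alloc, n = col_model
        cfg = colombia.cost_config()
        resolved = resolve_schedules(cfg["schedules"], cfg["inflation"], cfg["target_year"])
        d1 = accrue_direct(simulate(alloc, matrix, space, n), resolved)
        alloc2 = NewbornAllocation(2 * alloc.cohort_size, alloc.split)
        d2 = accrue_direct(simulate(alloc2, matrix, space, n), resolved)
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)


class TestIndirectAccrual:
    def test_therapy_addon_per_stunted_person_cycle(self, tiny_trace):
        addon = TherapyAddon(amount=920.0, states=("disabled",), active_cycles=frozenset({2}))
        indirect = accrue_indirect(tiny_trace, {}, addon)
        assert indirect[0] == 0.0  # add-on inactive in cycle 1
        assert indirect[1] == pytest.approx(300 * 920.0)

    def test_thousand_person_cycles_at_920(self):
        from malnutburden.markov import CohortTrace, StateSpace

        space = StateSpace(names=("healthy", "stunted", "death"), absorbing=frozenset({"death"}))
        occ = np.array(
            [[2000.0, 0.0, 0.0]] * 3 + [[1000.0, 1000.0, 0.0]]
        )  # 1000 stunted at end of cycle 3
        trace = CohortTrace(space, occ, np.zeros((3, 3, 3)))
        addon = TherapyAddon(amount=920.0, states=("stunted",), active_cycles=frozenset({3, 4}))
        indirect = accrue_indirect(trace, {}, addon)
        assert indirect.tolist() == [0.0, 0.0, 920_000.0]

    def test_deactivating_timing_rule_strictly_increases_total(self, col_trace):
        cfg = colombia.cost_config()
        addon = cfg["addon"]
        always = TherapyAddon(addon.amount, addon.states, frozenset({1, 2, 3, 4}))
        gated = accrue_indirect(col_trace, {}, addon)
        ungated = accrue_indirect(col_trace, {}, always)
        assert ungated.sum() > gated.sum()
        np.testing.assert_allclose(ungated[2:], gated[2:])

    def test_household_costs_linear_in_inputs(self, tiny_trace):
        one = accrue_indirect(tiny_trace, {"disabled": 10.0}, None)
        two = accrue_indirect(tiny_trace, {"disabled": 20.0}, None)
        np.testing.assert_allclose(two, 2 * one)

    def test_negative_household_cost_rejected(self, tiny_trace):
        with pytest.raises(ValueError):
            accrue_indirect(tiny_trace, {"disabled": -1.0}, None)


class TestTotalsAndShares:
    def test_published_cost_table_totals(self, cost_target):
        table = CostTable(cost_target["direct"].to_numpy(), cost_target["indirect"].to_numpy())
        out = totals_and_shares(table)
        assert out["total_direct"] == pytest.approx(128_919_089.41, abs=2.5)
        assert out["total_indirect"] == pytest.approx(243_576_094.12, abs=0.02)
        assert round(out["grand_total"] / 1e6, 2) == pytest.approx(372.50, abs=0.01)
        assert out["share_indirect_pct_rounded"] == 65
        assert out["share_direct_pct_rounded"] == 35

    def test_shares_sum_to_100_before_rounding(self, cost_target):
        table = CostTable(cost_target["direct"].to_numpy(), cost_target["indirect"].to_numpy())
        out = totals_and_shares(table)
        assert out["share_direct_pct"] + out["share_indirect_pct"] == pytest.approx(100.0)

    def test_equal_columns_give_even_split(self):
        out = totals_and_shares(CostTable(np.array([50.0, 50.0]), np.array([60.0, 40.0])))
        assert out["share_direct_pct_rounded"] == 50
        assert out["share_indirect_pct_rounded"] == 50


class TestPovertyRatio:
    def test_line_ratio_matches_percentage_ratio(self):
        # same spending over the two 2022 lines: percentages scale as the lines
        oop = 2_942_000.0  # arbitrary positive numerator, COP/yr
        extreme = poverty_burden_ratio(oop, colombia.EXTREME_POVERTY_LINE_COP)
        monetary = poverty_burden_ratio(oop, colombia.MONETARY_POVERTY_LINE_COP)
        assert extreme / monetary == pytest.approx(396_864 / 198_698, rel=1e-12)
        assert extreme / monetary == pytest.approx(123.4 / 61.8, abs=0.005)

    def test_annualized_line_is_100_percent(self):
        assert poverty_burden_ratio(12 * 198_698.0, 198_698.0) == pytest.approx(100.0)

    def test_zero_spending_zero_percent(self):
        assert poverty_burden_ratio(0.0, 198_698.0) == 0.0

    def test_nonpositive_line_rejected(self):
        with pytest.raises(ValueError):
            poverty_burden_ratio(1.0, 0.0)


class TestBackSolve:
    def test_round_trip_against_forward_accrual(self, col_trace):
        cfg = colombia.cost_config()
        persistent = [s for s in col_trace.space.names if s not in col_trace.space.absorbing]
        target = accrue_indirect(
            col_trace, {s: 25.0 for s in persistent}, cfg["addon"]
        )
        report = back_solve_indirect(col_trace, target, persistent, cfg["addon"])
        np.testing.assert_allclose(report["implied_per_person"], 25.0, rtol=1e-9)

    def test_published_indirect_column_implies_rising_household_burden(
        self, col_trace, cost_target
    ):
        cfg = colombia.cost_config()
        persistent = [s for s in col_trace.space.names if s not in col_trace.space.absorbing]
        report = back_solve_indirect(
            col_trace, cost_target["indirect"].to_numpy(), persistent, cfg["addon"]
        )
        implied = report["implied_per_person"].to_numpy()
        assert np.all(np.diff(implied) > 0)  # sharp rise once therapy starts
        assert np.all(implied > 0)
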