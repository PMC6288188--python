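import math

import pytest

from methanoflux.etc_modes import (
    ModeConfig,
    ReferenceDataset,
    apply_mode,
    default_grid,
    fit_parameter,
    nh4_oxidation_analysis,
    o2_ch4_ratio,
    simulate_scenario,
    sweep_parameter,
)
from methanoflux.etc_modes import SweepTable, ScenarioResult
from methanoflux.lp_engine import fva, pfba
from methanoflux.model_core import FluxState


def _result(ratio, growth=0.1, ok=True):
    state = FluxState(fluxes={"EX_ch4_e": -1.0}, objective_value=growth,
                      status="optimal" if ok else "infeasible")
    return ScenarioResult(growth_rate=growth, o2_ch4_ratio=ratio,
                          flux_state=state, config=ModeConfig())


def _table(rows):
    table = SweepTable(mode="direct_coupling", parameter_name="k")
    table.rows = [(p, _result(r)) for p, r in rows]
    return table


class TestModeConfig:
    def test_parameter_dispatch(self):
        assert ModeConfig("redox_arm", protons_per_atp=3.0).parameter == 3.0
        assert ModeConfig("direct_coupling", pmmo_flux_ratio=5.5).parameter == 5.5
        assert ModeConfig("uphill", uphill_lower_bound=-2.8).parameter == -2.8

    def test_validation(self):
        with pytest.raises(ValueError):
            ModeConfig("sideways")
        with pytest.raises(ValueError):
            ModeConfig("direct_coupling", pmmo_flux_ratio=-1)
        with pytest.raises(ValueError):
            ModeConfig("uphill", uphill_lower_bound=1.0)
        with pytest.raises(ValueError):
            ModeConfig("redox_arm", nh4_no2_ratio=1.5)


class TestApplyMode:
    def test_redox_arm_closes_direct_variant(self, core_model):
        model, couplings = apply_mode(core_model, ModeConfig("redox_arm"))
        assert couplings == []
        rxn = model.reactions["PMMODCipp"]
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)
        assert model.reactions["CYOR_q8ppi"].lower_bound == 0.0

    def test_redox_arm_blocked_by_fva(self, core_model):
        from methanoflux.core_network import set_nitrogen_source

        model, _ = apply_mode(set_nitrogen_source(core_model, "no3"),
                              ModeConfig("redox_arm"), inplace=True)
        assert fva(model, ["PMMODCipp"], 0.0)["PMMODCipp"] == (0.0, 0.0)

    def test_direct_coupling_ratio_holds(self, core_model):
        # the k = 5.5 configuration must satisfy its own ratio constraint
        config = ModeConfig("direct_coupling", pmmo_flux_ratio=5.5)
        result = simulate_scenario(core_model, config, "no3", "pmmo")
        assert result.feasible
        state = result.flux_state
        assert state["PMMOipp"] == pytest.approx(
            5.5 * state["PMMODCipp"], abs=1e-6)
        assert state["PMMODCipp"] > 0

    def test_uphill_zero_bound_equals_redox_arm(self, core_model):
        uphill = simulate_scenario(
            core_model, ModeConfig("uphill", uphill_lower_bound=0.0), "no3")
        redox = simulate_scenario(core_model, ModeConfig("redox_arm"), "no3")
        assert uphill.growth_rate == pytest.approx(redox.growth_rate, abs=1e-8)
        assert uphill.o2_ch4_ratio == pytest.approx(redox.o2_ch4_ratio, abs=1e-8)

    def test_missing_reaction_raises(self, chain_model):
        with pytest.raises(KeyError):
            apply_mode(chain_model, ModeConfig("redox_arm"))


class TestRatio:
    def test_arithmetic(self):
        state = FluxState(fluxes={"EX_o2_e": -27.69, "EX_ch4_e": -18.46},
                          objective_value=0.0, status="optimal")
        assert o2_ch4_ratio(state) == pytest.approx(1.5)

    def test_zero_oxygen(self):
        state = FluxState(fluxes={"EX_o2_e": 0.0, "EX_ch4_e": -1.0},
                          objective_value=0.0, status="optimal")
        assert o2_ch4_ratio(state) == 0.0

    def test_no_methane_uptake_rejected(self):
        state = FluxState(fluxes={"EX_ch4_e": 0.0}, objective_value=0.0,
                          status="optimal")
        with pytest.raises(ValueError):
            o2_ch4_ratio(state)

    def test_core_redox_arm_regression(self, core_model):
        # pinned regression constant fixed by the built stoichiometry
        result = simulate_scenario(core_model, ModeConfig("redox_arm"), "no3")
        assert 1.0 < result.o2_ch4_ratio < 2.0
        assert result.o2_ch4_ratio == pytest.approx(1.5, abs=1e-6)


class TestSimulateScenario:
    def test_basic_run(self, core_model):
        result = simulate_scenario(core_model, ModeConfig("redox_arm"), "no3")
        assert result.feasible
        assert result.growth_rate > 0
        assert result.flux_state["EX_ch4_e"] == pytest.approx(-18.46, abs=1e-6)

    def test_direct_coupling_at_least_as_efficient(self, core_model):
        dc = simulate_scenario(
            core_model, ModeConfig("direct_coupling", pmmo_flux_ratio=0.0), "no3")
        redox = simulate_scenario(core_model, ModeConfig("redox_arm"), "no3")
        assert dc.o2_ch4_ratio <= redox.o2_ch4_ratio + 1e-9

    def test_closed_methane_no_growth(self, core_model):
        # without methane neither growth nor the forced maintenance demand
        # can be sustained: the scenario is infeasible, flagged not raised
        reference = ReferenceDataset(methane_uptake=1e-9)
        result = simulate_scenario(core_model, ModeConfig("redox_arm"), "no3",
                                   reference=reference)
        assert not result.feasible

        # with maintenance lifted the model is feasible at zero growth
        relaxed = core_model.copy()
        relaxed.reactions["ATPM"].lower_bound = 0.0
        result = simulate_scenario(relaxed, ModeConfig("redox_arm"), "no3",
                                   reference=reference)
        assert result.growth_rate == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_flagged_not_raised(self, core_model):
        model = core_model.copy()
        model.reactions["ATPM"].lower_bound = 1e5  # impossible maintenance
        result = simulate_scenario(model, ModeConfig("redox_arm"), "no3")
        assert not result.feasible
        assert math.isnan(result.growth_rate)


class TestSweeps:
    def test_redox_arm_flat_in_protons_per_atp(self, core_model):
        table = sweep_parameter(core_model, ModeConfig("redox_arm"),
                                [1.0, 2.0, 4.0, 6.0], "no3")
        ratios = [r for _, r in table.ratios()]
        assert max(ratios) - min(ratios) < 1e-6

    def test_direct_coupling_monotone_in_k(self, core_model):
        table = sweep_parameter(core_model, ModeConfig("direct_coupling"),
                                [0, 1, 2, 4, 8], "no3")
        ratios = [r for _, r in table.ratios()]
        assert all(b >= a - 1e-9 for a, b in zip(ratios, ratios[1:]))

    def test_uphill_monotone_in_bound_magnitude(self, core_model):
        table = sweep_parameter(core_model, ModeConfig("uphill"),
                                [0, -1, -2, -4, -8], "no3")
        ratios = [r for _, r in table.ratios()]
        assert all(b <= a + 1e-9 for a, b in zip(ratios, ratios[1:]))

    def test_growth_non_increasing_away_from_efficiency(self, core_model):
        table = sweep_parameter(core_model, ModeConfig("direct_coupling"),
                                [0, 1, 2, 4, 8], "no3")
        growth = [r.growth_rate for _, r in table.feasible_rows()]
        assert all(b <= a + 1e-9 for a, b in zip(growth, growth[1:]))

    def test_ratio_at_least_one_with_monooxygenase(self, core_model):
        for mode in (ModeConfig("redox_arm"),
                     ModeConfig("direct_coupling", pmmo_flux_ratio=2.0),
                     ModeConfig("uphill", uphill_lower_bound=-3.0)):
            result = simulate_scenario(core_model, mode, "no3")
            assert result.o2_ch4_ratio >= 1.0 - 1e-9

    def test_empty_grid_rejected(self, core_model):
        with pytest.raises(ValueError):
            sweep_parameter(core_model, ModeConfig("redox_arm"), [], "no3")

    def test_default_grids(self):
        assert default_grid("redox_arm")[0] == 1.0
        assert default_grid("direct_coupling")[-1] == 10.0
        assert default_grid("uphill")[-1] == pytest.approx(-10.0)


class TestModeOrdering:
    def test_efficiency_ordering(self, core_model):
        dc = simulate_scenario(
            core_model, ModeConfig("direct_coupling", pmmo_flux_ratio=0.0), "no3")
        uphill = simulate_scenario(
            core_model, ModeConfig("uphill", uphill_lower_bound=-1e5), "no3")
        redox = simulate_scenario(core_model, ModeConfig("redox_arm"), "no3")
        assert dc.o2_ch4_ratio <= uphill.o2_ch4_ratio + 1e-9
        assert uphill.o2_ch4_ratio <= redox.o2_ch4_ratio + 1e-9


class TestFit:
    def test_nearest_value(self):
        table = _table([(1, 1.2), (2, 1.45), (3, 1.7)])
        assert fit_parameter(table, 1.43) == 2

    def test_tie_breaks_toward_smaller_magnitude(self):
        table = _table([(1, 1.40), (2, 1.46)])
        assert fit_parameter(table, 1.43) == 1

    def test_all_infeasible_rejected(self):
        table = SweepTable(mode="direct_coupling", parameter_name="k")
        table.rows = [(1.0, _result(math.nan, ok=False))]
        with pytest.raises(ValueError):
            fit_parameter(table, 1.43)

    def test_recovery_direct_coupling(self, core_model):
        target = simulate_scenario(
            core_model, ModeConfig("direct_coupling", pmmo_flux_ratio=3.0), "no3")
        grid = [0.5 * i for i in range(13)]  # 0 .. 6
        table = sweep_parameter(core_model, ModeConfig("direct_coupling"),
                                grid, "no3")
        assert fit_parameter(table, target.o2_ch4_ratio) == pytest.approx(3.0)

    def test_recovery_uphill(self, core_model):
        target = simulate_scenario(
            core_model, ModeConfig("uphill", uphill_lower_bound=-2.5), "no3")
        grid = [-0.5 * i for i in range(11)]  # 0 .. -5
        table = sweep_parameter(core_model, ModeConfig("uphill"), grid, "no3")
        assert fit_parameter(table, target.o2_ch4_ratio) == pytest.approx(-2.5)


class TestNh4Oxidation:
    def test_r_zero_reduces_to_plain_scenario(self, core_model):
        config = ModeConfig("uphill", uphill_lower_bound=-2.8)
        plain = simulate_scenario(core_model, config, "nh4_excess")
        best, table = nh4_oxidation_analysis(core_model, config, [0.0], 1.6)
        assert table.rows[0][1].o2_ch4_ratio == pytest.approx(
            plain.o2_ch4_ratio, abs=1e-8)

    def test_monotone_in_r(self, core_model):
        config = ModeConfig("uphill", uphill_lower_bound=-2.8)
        _, table = nh4_oxidation_analysis(
            core_model, config, [0.2, 0.4, 0.6, 0.8], 1.6)
        ratios = [r for _, r in table.ratios()]
        assert all(b >= a - 1e-9 for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] >= ratios[0]

    def test_recovery_of_known_r(self, core_model):
        config = ModeConfig("uphill", uphill_lower_bound=-2.8)
        config_ref = ModeConfig("uphill", uphill_lower_bound=-2.8,
                                nh4_no2_ratio=0.5)
        reference = simulate_scenario(core_model, config_ref, "nh4_excess")
        grid = [0.1 * i for i in range(11)]
        best, _ = nh4_oxidation_analysis(
            core_model, config, grid, reference.o2_ch4_ratio)
        assert best == pytest.approx(0.5)

    def test_invalid_r_rejected(self, core_model):
        config = ModeConfig("uphill", uphill_lower_bound=-2.8)
        with pytest.raises(ValueError):
            nh4_oxidation_analysis(core_model, config, [0.5, 1.5], 1.6)
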