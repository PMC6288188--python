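import math

import numpy as np
import pytest

from methanoflux.lp_engine import (
    LinearCoupling,
    SolveOptions,
    add_coupling_nh4_no2,
    atp_generation_assay,
    fba,
    fva,
    pfba,
)
from methanoflux.model_core import Metabolite, Reaction

from conftest import make_model

INF = math.inf


def segment_oracle(evaluate, lo, hi, n=2001):
    """Brute-force scan of a 1-parameter feasible segment.

    The toy networks used here collapse to a single degree of freedom, so
    enumerating candidate flux levels is an exhaustive, solver-independent
    oracle for optima and ranges.
    """
    best = None
    for t in np.linspace(lo, hi, n):
        value = evaluate(t)
        if value is not None and (best is None or value > best):
            best = value
    return best


class TestFba:
    def test_linear_chain(self, chain_model):
        state = fba(chain_model)
        assert state.ok
        assert state.objective_value == pytest.approx(10.0)
        assert state["EX_A"] == pytest.approx(-10.0)

    def test_branch_condensation(self, branch_model):
        # oracle: all flux levels are tied to t = flux through R_BCD;
        # feasibility requires t <= 4 (R_AC cap) and 2t <= 8 (uptake)
        expected = segment_oracle(
            lambda t: t if (t <= 4 and 2 * t <= 8) else None, 0, 10)
        state = fba(branch_model)
        assert state.objective_value == pytest.approx(expected)  # == 4
        assert state.objective_value == pytest.approx(4.0)

    def test_closed_medium_zero(self, chain_model):
        chain_model.reactions["EX_A"].lower_bound = 0.0
        state = fba(chain_model)
        assert state.ok
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_flagged(self, chain_model):
        chain_model.reactions["R_AB"].lower_bound = 20.0
        chain_model.reactions["R_AB"].upper_bound = 21.0
        state = fba(chain_model)
        assert state.status == "infeasible"
        assert state.fluxes == {}

    def test_unbounded_flagged(self, chain_model):
        chain_model.reactions["EX_A"].lower_bound = -INF
        state = fba(chain_model)
        assert state.status == "unbounded"

    def test_min_sense(self, chain_model):
        state = fba(chain_model, sense="min", objective_id="EX_A")
        assert state.objective_value == pytest.approx(-10.0)

    def test_steady_state_and_bounds(self, branch_model):
        state = fba(branch_model)
        S = branch_model.s_matrix()
        v = np.array([state[r] for r in branch_model.reaction_ids])
        assert np.abs(S @ v).max() < 1e-6
        for rid, rxn in branch_model.reactions.items():
            assert rxn.lower_bound - 1e-9 <= state[rid] <= rxn.upper_bound + 1e-9


class TestPfba:
    def test_prefers_short_route(self, two_route_model):
        state = pfba(two_route_model)
        # oracle: both routes yield 5; direct costs 2 units of |v| per unit
        # yield, the detour 3 -- parsimony must route everything directly
        assert state.objective_value == pytest.approx(5.0)
        assert state["R_direct"] == pytest.approx(5.0)
        assert state["R_leg1"] == 0.0
        assert state["R_leg2"] == 0.0

    def test_unique_optimum_matches_fba(self, chain_model):
        fba_state = fba(chain_model)
        pfba_state = pfba(chain_model)
        for rid in chain_model.reactions:
            assert pfba_state[rid] == pytest.approx(fba_state[rid], abs=1e-8)

    def test_objective_preserved_on_core(self, core_model):
        from methanoflux.core_network import set_nitrogen_source, set_mmo_availability

        model = set_mmo_availability(set_nitrogen_source(core_model, "nh4_excess"),
                                     "pmmo", inplace=True)
        model.reactions["PMMODCipp"].upper_bound = 0.0
        assert pfba(model).objective_value == pytest.approx(
            fba(model).objective_value, abs=1e-6)

    def test_total_flux_not_worse_than_perturbed_alternates(self, branch_model):
        # randomized secondary objectives pick alternative optimal vertices;
        # none may have a smaller 1-norm than the pFBA solution
        base = pfba(branch_model)
        base_norm = sum(abs(v) for v in base.fluxes.values())
        rng = np.random.default_rng(42)
        rxn_ids = branch_model.reaction_ids
        opt = fba(branch_model).objective_value
        fix = LinearCoupling({branch_model.objective_id: 1.0}, "=", opt)
        for _ in range(8):
            secondary = rng.choice(rxn_ids)
            alt = fba(branch_model, [fix], sense="max", objective_id=secondary)
            if not alt.ok:
                continue
            alt_norm = sum(abs(v) for v in alt.fluxes.values())
            assert base_norm <= alt_norm + 1e-6

    def test_infeasible_propagates(self, chain_model):
        chain_model.reactions["R_AB"].lower_bound = 20.0
        chain_model.reactions["R_AB"].upper_bound = 21.0
        assert pfba(chain_model).status == "infeasible"


class TestFva:
    def test_blocked_reaction(self, chain_model):
        # dead-end metabolite: nothing consumes X
        chain_model.add_metabolite(Metabolite(id="X", compartment="c"))
        chain_model.add_reaction(Reaction(
            id="R_AX", stoichiometry={"A": -1, "X": 1}, lower_bound=0,
        ))
        ranges = fva(chain_model, ["R_AX"], fraction_of_optimum=0.0)
        assert ranges["R_AX"] == (0.0, 0.0)

    def test_linear_chain_pinned_at_optimum(self, chain_model):
        ranges = fva(chain_model, ["R_AB"], fraction_of_optimum=1.0)
        assert ranges["R_AB"][0] == pytest.approx(10.0)
        assert ranges["R_AB"][1] == pytest.approx(10.0)

    def test_branch_range_at_fraction_zero(self, branch_model):
        # oracle: steady state ties R_AB to R_BCD which R_AC caps at 4
        # (the network has a single degree of freedom)
        hi = segment_oracle(lambda t: t if t <= 4 and 2 * t <= 8 else None, 0, 10)
        ranges = fva(branch_model, ["R_AB"], fraction_of_optimum=0.0)
        assert ranges["R_AB"] == pytest.approx((0.0, hi))

    def test_contains_pfba_solution(self, branch_model):
        state = pfba(branch_model)
        ranges = fva(branch_model, fraction_of_optimum=1.0)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-8 <= state[rid] <= hi + 1e-8


class TestAtpAssay:
    def test_core_model_clean(self, core_model):
        assert atp_generation_assay(core_model) == 0.0

    def test_injected_cycle_detected(self, core_model):
        broken = core_model.copy()
        # a duplicated synthase with an erroneously low proton requirement
        # closes a loop with the reverse of the original: the pair pumps
        # protons from nothing, which the real synthase turns into ATP
        broken.add_reaction(Reaction(id="ATPS_dup_cheap", stoichiometry={
            "h_p": -2.0, "adp_c": -1.0, "pi_c": -1.0,
            "atp_c": 1.0, "h2o_c": 1.0, "h_c": 1.0,
        }))
        assert atp_generation_assay(broken) > 0

    def test_missing_maintenance_errors(self, chain_model):
        with pytest.raises(KeyError):
            atp_generation_assay(chain_model)

    def test_balanced_closed_networks_make_nothing(self, core_model):
        # fault-injection counterpart: the untouched model must stay at 0
        # even when the maintenance bound is lifted beforehand
        model = core_model.copy()
        model.reactions["ATPM"].lower_bound = 0.0
        assert atp_generation_assay(model) == 0.0


class TestCouplings:
    def test_validation(self):
        with pytest.raises(ValueError):
            LinearCoupling({}, "=", 0.0)
        with pytest.raises(ValueError):
            LinearCoupling({"r": 1.0}, "~", 0.0)
        with pytest.raises(ValueError):
            LinearCoupling({"r": math.nan}, "=", 0.0)

    def test_nh4_no2_bounds_checked(self):
        with pytest.raises(ValueError):
            add_coupling_nh4_no2(-0.1)
        with pytest.raises(ValueError):
            add_coupling_nh4_no2(1.1)

    def test_nh4_no2_on_toy_nitrogen_balance(self):
        # toy: N taken up is either assimilated into X or secreted as M
        model = make_model(
            ["N", "M", "X"],
            [
                ("EX_n", {"N": -1}, -10, INF),
                ("R_ox", {"N": -1, "M": 1}, 0, INF),
                ("EX_m", {"M": -1}, 0, INF),
                ("R_assim", {"N": -1, "X": 1}, 0, INF),
                ("DM_x", {"X": -1}, 0, INF),
            ],
            "DM_x",
        )
        coupling = add_coupling_nh4_no2(0.5, "EX_n", "EX_m")
        state = fba(model, [coupling])
        assert state["EX_n"] == pytest.approx(-10.0)
        assert state["EX_m"] == pytest.approx(5.0, abs=1e-9)

        # r = 0 degenerates to no secretion
        state0 = fba(model, [add_coupling_nh4_no2(0.0, "EX_n", "EX_m")])
        assert state0["EX_m"] == pytest.approx(0.0, abs=1e-9)

        # r = 1: secretion equals the uptake magnitude, nothing assimilated
        state1 = fba(model, [add_coupling_nh4_no2(1.0, "EX_n", "EX_m")])
        assert state1["EX_m"] == pytest.approx(-state1["EX_n"], abs=1e-9)

    def test_coupling_never_raises_optimum(self, branch_model):
        base = fba(branch_model).objective_value
        for rhs in (3.0, 2.0, 1.0):
            coupled = fba(branch_model, [
                LinearCoupling({"R_AC": 1.0}, "<=", rhs)])
            assert coupled.objective_value <= base + 1e-9

    def test_unknown_reaction_in_coupling(self, branch_model):
        with pytest.raises(KeyError):
            fba(branch_model, [LinearCoupling({"ghost": 1.0}, "=", 0.0)])


class TestSolveOptions:
    def test_positive_tolerances_required(self):
        with pytest.raises(ValueError):
            SolveOptions(feasibility_tol=0.0)
        with pytest.raises(ValueError):
            SolveOptions(optimality_tol=-1.0)
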