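import math

import pytest

from methanoflux.core_network import build_core_model
from methanoflux.model_core import Metabolite, Reaction, StoichiometricModel

INF = math.inf


def make_model(metabolites, reactions, objective):
    """Assemble a toy model from (id, compartment) and reaction tuples."""
    model = StoichiometricModel(id="toy")
    for met_id in metabolites:
        model.add_metabolite(Metabolite(id=met_id, compartment="c"))
    for rxn_id, stoich, lb, ub in reactions:
        model.add_reaction(Reaction(
            id=rxn_id, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            is_boundary=len(stoich) == 1 and rxn_id.startswith(("EX_", "DM_")),
        ))
    model.objective_id = objective
    return model


@pytest.fixture(scope="session")
def core_model():
    """The default core network; session-scoped, never mutated in place."""
    return build_core_model()


@pytest.fixture
def chain_model():
    """EX_A -> A -> B -> EX_B, uptake limited to 10."""
    return make_model(
        ["A", "B"],
        [
            ("EX_A", {"A": -1}, -10, INF),
            ("R_AB", {"A": -1, "B": 1}, 0, INF),
            ("EX_B", {"B": -1}, 0, INF),
        ],
        "EX_B",
    )


@pytest.fixture
def branch_model():
    """A splits to B (ub 10) and C (ub 4); B + C condense to D."""
    return make_model(
        ["A", "B", "C", "D"],
        [
            ("EX_A", {"A": -1}, -8, INF),
            ("R_AB", {"A": -1, "B": 1}, 0, 10),
            ("R_AC", {"A": -1, "C": 1}, 0, 4),
            ("R_BCD", {"B": -1, "C": -1, "D": 1}, 0, INF),
            ("EX_D", {"D": -1}, 0, INF),
        ],
        "EX_D",
    )


@pytest.fixture
def two_route_model():
    """Two equal-yield routes A->B: one direct, one via X (longer)."""
    return make_model(
        ["A", "B", "X"],
        [
            ("EX_A", {"A": -1}, -5, INF),
            ("R_direct", {"A": -1, "B": 1}, 0, INF),
            ("R_leg1", {"A": -1, "X": 1}, 0, INF),
            ("R_leg2", {"X": -1, "B": 1}, 0, INF),
            ("EX_B", {"B": -1}, 0, INF),
        ],
        "EX_B",
    )
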