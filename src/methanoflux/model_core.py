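"""In-memory data model for constraint-based metabolic networks.

Provides the stoichiometric building blocks (metabolites, reactions, the
model holding the implied matrix S) together with the curation checks used
throughout the package: elemental/charge balancing, GPR evaluation and
medium (uptake-bound) manipulation.

Sign conventions
----------------
* Stoichiometric coefficients are negative for consumed species and
  positive for produced species.
* Exchange reactions are written ``1 met_e <-> (nothing)``: uptake is a
  negative flux, secretion a positive flux.
* Balance residuals are reported as products minus reactants, i.e. the
  signed sum ``sum(coefficient * element_count)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

__all__ = [
    "FormulaError",
    "GPRError",
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "FluxState",
    "parse_formula",
    "reaction_imbalance",
    "check_model_balance",
    "evaluate_gpr",
    "apply_medium",
    "UNBALANCEABLE",
]

#: Marker returned by :func:`reaction_imbalance` when a participant lacks a
#: formula and the reaction therefore cannot be assessed.
UNBALANCEABLE = "unbalanceable"

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for formula strings that do not match the element grammar."""


class GPRError(ValueError):
    """Raised for malformed gene-protein-reaction rule strings."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula string into an element -> count map.

    The grammar is a sequence of element symbols (capital letter plus an
    optional lowercase letter) each followed by an optional non-negative
    integer count (default 1).  The empty string parses to an empty map.
    Polymer units ("...n") are rejected.

    >>> parse_formula("C6H11O9P")
    {'C': 6, 'H': 11, 'O': 9, 'P': 1}
    """
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        match = _ELEMENT_RE.match(formula, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(
                f"malformed formula {formula!r}: unexpected token at position {pos}"
            )
        element = match.group(1)
        count = int(match.group(2)) if match.group(2) else 1
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    return counts


@dataclass
class Metabolite:
    """A chemical species localised to one compartment."""

    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "c"

    def element_counts(self) -> Dict[str, int]:
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed).  Boundary pseudo-reactions (exchanges, demands,
    sinks) touch exactly one metabolite and are flagged ``is_boundary``.
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = math.inf
    gpr: str = ""
    name: str = ""
    subsystem: str = ""
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class StoichiometricModel:
    """A metabolic network: the matrix S plus bounds and an objective."""

    id: str = "model"
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    objective_id: str = ""
    compartments: Dict[str, str] = field(
        default_factory=lambda: {"c": "cytosol", "p": "periplasm",
                                 "im": "intramembrane", "e": "extracellular"}
    )
    #: Non-boundary pseudo-reactions (biomass, maintenance) exempt from
    #: elemental balancing.
    pseudo_reactions: Set[str] = field(default_factory=set)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise ValueError(
                f"metabolite {met.id!r}: compartment {met.compartment!r} not "
                f"declared (have {sorted(self.compartments)})"
            )
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoichiometry:
            raise ValueError(f"reaction {rxn.id!r} has empty stoichiometry")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        if rxn.is_boundary and len(rxn.stoichiometry) != 1:
            raise ValueError(
                f"boundary reaction {rxn.id!r} must touch exactly one metabolite"
            )
        self.reactions[rxn.id] = rxn
        return rxn

    # -- views ------------------------------------------------------------
    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> List[str]:
        return list(self.metabolites)

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_boundary]

    def s_matrix(self):
        """Dense stoichiometric matrix S (metabolites x reactions)."""
        import numpy as np

        met_index = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions.values()):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_index[met_id], j] = coeff
        return S

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            id=self.id,
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions={k: v.copy() for k, v in self.reactions.items()},
            objective_id=self.objective_id,
            compartments=dict(self.compartments),
            pseudo_reactions=set(self.pseudo_reactions),
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.objective_id and self.objective_id not in self.reactions:
            raise ValueError(f"objective {self.objective_id!r} is not a reaction")
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )


@dataclass
class FluxState:
    """A solved flux vector with objective value and solver status."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def reaction_imbalance(
    rxn: Reaction, metabolites: Mapping[str, Metabolite]
) -> Dict[str, float]:
    """Per-element (and charge) residual of a reaction.

    Residuals follow the products-minus-reactants convention; an all-zero
    (empty) map means the reaction is balanced.  If any participant lacks a
    formula the reaction cannot be assessed and ``{UNBALANCEABLE: nan}``
    is returned instead of a residual.
    """
    if rxn.is_boundary:
        raise ValueError(f"{rxn.id!r} is a boundary pseudo-reaction")
    residuals: Dict[str, float] = {}
    for met_id, coeff in rxn.stoichiometry.items():
        met = metabolites[met_id]
        if not met.formula:
            return {UNBALANCEABLE: math.nan}
        for element, count in met.element_counts().items():
            residuals[element] = residuals.get(element, 0.0) + coeff * count
        residuals["charge"] = residuals.get("charge", 0.0) + coeff * met.charge
    return {k: v for k, v in residuals.items() if abs(v) > 1e-9}


def check_model_balance(model: StoichiometricModel) -> Dict[str, Dict[str, float]]:
    """Report every unbalanced non-pseudo reaction with its residuals.

    Boundary reactions and the model's declared pseudo-reactions (biomass,
    maintenance drains that are balanced by definition of the pool they
    represent) are excluded.  An empty report means the model is clean.
    """
    report: Dict[str, Dict[str, float]] = {}
    for rxn in model.reactions.values():
        if rxn.is_boundary or rxn.id in model.pseudo_reactions:
            continue
        residual = reaction_imbalance(rxn, model.metabolites)
        if residual:
            report[rxn.id] = residual
    return report


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_GPR_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize_gpr(rule: str) -> List[str]:
    return _GPR_TOKEN_RE.findall(rule)


def _parse_or(tokens: List[str], pos: int) -> Tuple[object, int]:
    node, pos = _parse_and(tokens, pos)
    terms = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        nxt, pos = _parse_and(tokens, pos + 1)
        terms.append(nxt)
    return (("or", terms) if len(terms) > 1 else terms[0]), pos


def _parse_and(tokens: List[str], pos: int) -> Tuple[object, int]:
    node, pos = _parse_atom(tokens, pos)
    terms = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        nxt, pos = _parse_atom(tokens, pos + 1)
        terms.append(nxt)
    return (("and", terms) if len(terms) > 1 else terms[0]), pos


def _parse_atom(tokens: List[str], pos: int) -> Tuple[object, int]:
    if pos >= len(tokens):
        raise GPRError("unexpected end of GPR expression")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GPRError("unbalanced parentheses in GPR expression")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GPRError(f"unexpected token {tok!r} in GPR expression")
    return ("gene", tok), pos + 1


def _eval_node(node: object, deleted: Set[str]) -> bool:
    kind = node[0]
    if kind == "gene":
        return node[1] not in deleted
    if kind == "and":
        return all(_eval_node(child, deleted) for child in node[1])
    return any(_eval_node(child, deleted) for child in node[1])


def evaluate_gpr(rule: str, deleted: Iterable[str] = ()) -> bool:
    """Evaluate a boolean gene rule given a set of deleted genes.

    ``and`` encodes an enzyme complex (all subunits required), ``or``
    isozymes (any suffices).  An empty rule is always active.
    """
    if not rule or not rule.strip():
        return True
    tokens = _tokenize_gpr(rule)
    node, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise GPRError(f"trailing tokens in GPR expression {rule!r}")
    return _eval_node(node, set(deleted))


def parse_gpr(rule: str):
    """Parse a rule into a nested tuple tree: ("gene", id) / ("and"|"or", [children]).

    Returns None for an empty rule.
    """
    if not rule or not rule.strip():
        return None
    tokens = _tokenize_gpr(rule)
    node, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise GPRError(f"trailing tokens in GPR expression {rule!r}")
    return node


def gpr_genes(rule: str) -> Set[str]:
    """All gene ids appearing in a rule string."""
    if not rule or not rule.strip():
        return set()
    return {t for t in _tokenize_gpr(rule)
            if t not in ("(", ")") and t.lower() not in ("and", "or")}


# ---------------------------------------------------------------------------
# medium
# ---------------------------------------------------------------------------

def apply_medium(
    model: StoichiometricModel,
    uptake_limits: Mapping[str, float],
    inplace: bool = False,
) -> StoichiometricModel:
    """Constrain uptake to the given exchange -> max-magnitude map.

    Listed exchanges receive ``lower_bound = -magnitude``; every other
    exchange has its lower bound closed (set to 0).  Secretion (upper
    bounds) is never touched.  Unknown or non-boundary ids raise.
    """
    out = model if inplace else model.copy()
    for ex_id in uptake_limits:
        rxn = out.reactions.get(ex_id)
        if rxn is None or not rxn.is_boundary:
            raise KeyError(f"{ex_id!r} is not an exchange reaction of the model")
    for rxn in out.reactions.values():
        if not rxn.is_boundary:
            continue
        if rxn.id in uptake_limits:
            magnitude = uptake_limits[rxn.id]
            if magnitude < 0:
                raise ValueError(f"uptake magnitude for {rxn.id!r} must be >= 0")
            rxn.lower_bound = -magnitude
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out
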