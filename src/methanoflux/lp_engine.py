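"""Linear-programming machinery: FBA, pFBA, FVA, flux couplings, QC assays.

The LP backend is a pluggable contract -- a callable taking dense problem
data ``(c, A_eq, b_eq, A_ub, b_ub, bounds, sense)`` and returning
``(status, x, objective)``.  The default backend is scipy's HiGHS
interface; nothing else in the package assumes a particular solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model_core import FluxState, StoichiometricModel

__all__ = [
    "LinearCoupling",
    "SolveOptions",
    "fba",
    "pfba",
    "fva",
    "atp_generation_assay",
    "add_coupling_nh4_no2",
]

#: Fluxes below this magnitude are reported as exact zeros.
ZERO_TOL = 1e-9


@dataclass(frozen=True)
class LinearCoupling:
    """A linear constraint ``sum(coeff * v_rxn)  <relation>  rhs``.

    Used for flux-ratio constraints, e.g. tying nitrite secretion to a
    fraction of ammonium uptake, or fixing the split between two
    monooxygenase variants.
    """

    terms: Mapping[str, float]
    relation: str = "="  # "=", "<=" or ">="
    rhs: float = 0.0

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("coupling needs at least one term")
        if self.relation not in ("=", "<=", ">="):
            raise ValueError(f"unknown relation {self.relation!r}")
        for rxn_id, coeff in self.terms.items():
            if not math.isfinite(coeff):
                raise ValueError(f"non-finite coefficient for {rxn_id!r}")


@dataclass
class SolveOptions:
    feasibility_tol: float = 1e-9
    optimality_tol: float = 1e-9
    pfba_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.feasibility_tol <= 0 or self.optimality_tol <= 0:
            raise ValueError("tolerances must be positive")


_STATUS_MAP = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _scipy_backend(c, A_eq, b_eq, A_ub, b_ub, bounds, options: SolveOptions):
    res = linprog(
        c,
        A_ub=A_ub if A_ub is not None and len(A_ub) else None,
        b_ub=b_ub if b_ub is not None and len(b_ub) else None,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": options.feasibility_tol,
            "dual_feasibility_tolerance": options.optimality_tol,
        },
    )
    status = _STATUS_MAP.get(res.status, "numerical")
    x = res.x if res.x is not None else None
    return status, x, (res.fun if res.fun is not None else math.nan)


LPBackend = Callable[..., Tuple[str, Optional[np.ndarray], float]]


def _assemble(
    model: StoichiometricModel,
    couplings: Sequence[LinearCoupling],
):
    rxn_ids = model.reaction_ids
    rxn_index = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids)
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    m = len(met_index)

    A_eq_rows: List[np.ndarray] = []
    b_eq: List[float] = []
    S = np.zeros((m, n))
    for j, rid in enumerate(rxn_ids):
        for met_id, coeff in model.reactions[rid].stoichiometry.items():
            S[met_index[met_id], j] = coeff
    A_eq_rows.append(S)
    b_eq.extend([0.0] * m)

    A_ub_rows: List[np.ndarray] = []
    b_ub: List[float] = []
    for coupling in couplings:
        row = np.zeros(n)
        for rxn_id, coeff in coupling.terms.items():
            if rxn_id not in rxn_index:
                raise KeyError(f"coupling references unknown reaction {rxn_id!r}")
            row[rxn_index[rxn_id]] = coeff
        if coupling.relation == "=":
            A_eq_rows.append(row.reshape(1, -1))
            b_eq.append(coupling.rhs)
        elif coupling.relation == "<=":
            A_ub_rows.append(row)
            b_ub.append(coupling.rhs)
        else:  # ">="
            A_ub_rows.append(-row)
            b_ub.append(-coupling.rhs)

    A_eq = np.vstack(A_eq_rows)
    A_ub = np.vstack(A_ub_rows) if A_ub_rows else None
    bounds = [(model.reactions[r].lower_bound, model.reactions[r].upper_bound)
              for r in rxn_ids]
    return rxn_ids, A_eq, np.asarray(b_eq), A_ub, np.asarray(b_ub), bounds


def _clean(value: float) -> float:
    return 0.0 if abs(value) < ZERO_TOL else float(value)


def fba(
    model: StoichiometricModel,
    couplings: Sequence[LinearCoupling] = (),
    sense: str = "max",
    objective_id: Optional[str] = None,
    options: Optional[SolveOptions] = None,
    backend: LPBackend = _scipy_backend,
) -> FluxState:
    """Flux balance analysis: optimise one reaction subject to S v = 0,
    bounds and any extra linear couplings."""
    options = options or SolveOptions()
    objective_id = objective_id or model.objective_id
    if objective_id not in model.reactions:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")

    rxn_ids, A_eq, b_eq, A_ub, b_ub, bounds = _assemble(model, couplings)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0 if sense == "max" else 1.0

    status, x, fun = backend(c, A_eq, b_eq, A_ub, b_ub, bounds, options)
    if status != "optimal" or x is None:
        return FluxState(fluxes={}, objective_value=math.nan, status=status)
    fluxes = {rid: _clean(v) for rid, v in zip(rxn_ids, x)}
    objective = fluxes[objective_id]
    return FluxState(fluxes=fluxes, objective_value=objective, status="optimal")


def pfba(
    model: StoichiometricModel,
    couplings: Sequence[LinearCoupling] = (),
    objective_id: Optional[str] = None,
    options: Optional[SolveOptions] = None,
    backend: LPBackend = _scipy_backend,
) -> FluxState:
    """Parsimonious FBA: fix the FBA optimum, then minimise total |v|.

    The flux vector is split into non-negative forward and reverse parts
    and the sum of both is minimised, which is the standard LP encoding of
    minimising the 1-norm.  The returned state attains the same objective
    value as plain FBA (up to the fixing fraction).
    """
    options = options or SolveOptions()
    objective_id = objective_id or model.objective_id
    first = fba(model, couplings, "max", objective_id, options, backend)
    if not first.ok:
        return first
    target = first.objective_value * options.pfba_fraction

    rxn_ids, A_eq, b_eq, A_ub, b_ub, bounds = _assemble(model, couplings)
    n = len(rxn_ids)
    j_obj = rxn_ids.index(objective_id)

    # variables: [forward | reverse], v = f - r
    split_bounds: List[Tuple[float, float]] = []
    for lb, ub in bounds:
        split_bounds.append((max(lb, 0.0), max(ub, 0.0)))  # forward
    for lb, ub in bounds:
        split_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))  # reverse

    A_eq_split = np.hstack([A_eq, -A_eq])
    obj_row = np.zeros(2 * n)
    obj_row[j_obj] = 1.0
    obj_row[n + j_obj] = -1.0
    A_eq_split = np.vstack([A_eq_split, obj_row])
    b_eq_split = np.concatenate([b_eq, [target]])
    A_ub_split = np.hstack([A_ub, -A_ub]) if A_ub is not None else None

    c = np.ones(2 * n)
    status, x, _ = backend(c, A_eq_split, b_eq_split, A_ub_split, b_ub, split_bounds, options)
    if status != "optimal" or x is None:
        # objective fixing can be marginally infeasible at exotic tolerances;
        # surface the failure rather than silently falling back
        return FluxState(fluxes={}, objective_value=math.nan, status=status)
    v = x[:n] - x[n:]
    fluxes = {rid: _clean(val) for rid, val in zip(rxn_ids, v)}
    return FluxState(fluxes=fluxes, objective_value=fluxes[objective_id], status="optimal")


def fva(
    model: StoichiometricModel,
    reaction_ids: Optional[Iterable[str]] = None,
    fraction_of_optimum: float = 1.0,
    couplings: Sequence[LinearCoupling] = (),
    objective_id: Optional[str] = None,
    options: Optional[SolveOptions] = None,
    backend: LPBackend = _scipy_backend,
) -> Dict[str, Tuple[float, float]]:
    """Flux variability analysis.

    Min/max flux per reaction with the objective constrained to at least
    ``fraction_of_optimum`` times its optimum.  At fraction 0 a (0, 0)
    range identifies blocked reactions.
    """
    options = options or SolveOptions()
    objective_id = objective_id or model.objective_id
    base = fba(model, couplings, "max", objective_id, options, backend)
    if not base.ok:
        raise RuntimeError(f"FVA requires a solvable model (status={base.status})")
    target = base.objective_value * fraction_of_optimum

    all_couplings = list(couplings) + [
        LinearCoupling(terms={objective_id: 1.0}, relation=">=", rhs=target)
    ]
    rxn_ids, A_eq, b_eq, A_ub, b_ub, bounds = _assemble(model, all_couplings)
    targets = list(reaction_ids) if reaction_ids is not None else rxn_ids

    result: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        c = np.zeros(len(rxn_ids))
        extremes = []
        for sign in (1.0, -1.0):
            c[j] = sign
            status, x, _ = backend(c, A_eq, b_eq, A_ub, b_ub, bounds, options)
            if status == "unbounded":
                extremes.append(math.inf * -sign)
            elif status != "optimal" or x is None:
                raise RuntimeError(f"FVA subproblem for {rid!r} failed: {status}")
            else:
                extremes.append(_clean(x[j]))
        result[rid] = (min(extremes), max(extremes))
    return result


def atp_generation_assay(
    model: StoichiometricModel,
    maintenance_id: str = "ATPM",
    options: Optional[SolveOptions] = None,
    backend: LPBackend = _scipy_backend,
) -> float:
    """Maximum maintenance-ATP flux with every exchange closed.

    All boundary lower *and* upper bounds are set to zero, then flux
    through the ATP maintenance reaction is maximised.  Any strictly
    positive value flags an energy-generating cycle (a thermodynamically
    impossible free lunch).  Returns ``inf`` when the cycle is unbounded.
    """
    if maintenance_id not in model.reactions:
        raise KeyError(f"model has no maintenance reaction {maintenance_id!r}")
    closed = model.copy()
    for rxn in closed.reactions.values():
        if rxn.is_boundary:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    # the maintenance lower bound itself must not force flux
    closed.reactions[maintenance_id].lower_bound = 0.0
    state = fba(closed, (), "max", maintenance_id, options, backend)
    if state.status == "unbounded":
        return math.inf
    if not state.ok:
        raise RuntimeError(f"ATP assay failed with status {state.status}")
    return state.objective_value


def add_coupling_nh4_no2(
    r: float,
    nh4_exchange: str = "EX_nh4_e",
    no2_exchange: str = "EX_no2_e",
) -> LinearCoupling:
    """Couple nitrite secretion to a fraction ``r`` of ammonium uptake.

    With uptake negative and secretion positive the constraint reads
    ``r * v_EX_nh4_e + v_EX_no2_e = 0``: when a fraction r of the ammonium
    taken up is co-oxidised, nitrite leaves at r times the uptake
    magnitude.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"oxidised fraction r must lie in [0, 1], got {r}")
    return LinearCoupling(terms={nh4_exchange: r, no2_exchange: 1.0},
                          relation="=", rhs=0.0)
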