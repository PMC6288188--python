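"""Read and write models in SBML Level 3 + FBC and COBRA-style JSON.

SBML is emitted as Level 3 Version 1 with FBC version 2 for maximal
reader compatibility.  GPRs are serialised both as FBC gene-product
associations (SBML) and as flat rule strings (JSON).  Round trips
reproduce ids, stoichiometry, bounds and GPR strings exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import libsbml

from .model_core import (
    GPRError,
    Metabolite,
    Reaction,
    StoichiometricModel,
    gpr_genes,
    parse_gpr,
)

__all__ = [
    "ModelDocument",
    "ModelIOError",
    "read_sbml",
    "write_sbml",
    "read_json_model",
    "write_json_model",
    "read_model",
    "write_model",
    "models_equal",
]


class ModelIOError(ValueError):
    """Raised for unreadable, non-FBC or structurally incomplete files."""


@dataclass
class ModelDocument:
    model: StoichiometricModel
    annotations: Dict[str, Dict[str, str]] = field(default_factory=dict)
    source_format: str = "memory"


_BOUNDARY_PREFIXES = ("EX_", "DM_", "SK_")


def _infer_boundary(rxn_id: str, n_species: int) -> bool:
    return n_species == 1 and rxn_id.startswith(_BOUNDARY_PREFIXES) or n_species == 1


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _sid(identifier: str) -> str:
    """Mangle an id into an SBML SId body.

    Callers prepend a type prefix (``M_``/``R_``/...) which guarantees the
    letter start; only non-word characters are replaced (and therefore ids
    containing them do not round-trip verbatim).
    """
    return "".join(
        ch if ch.isalnum() or ch == "_" else "_x" + format(ord(ch), "02d")
        for ch in identifier
    )


def _gpr_to_association(node, parent, fbc_model, registered: Dict[str, str]) -> None:
    kind = node[0]
    if kind == "gene":
        gene = node[1]
        if gene not in registered:
            gp = fbc_model.createGeneProduct()
            gp.setId("G_" + _sid(gene))
            gp.setLabel(gene)
            registered[gene] = "G_" + _sid(gene)
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(registered[gene])
    elif kind == "and":
        fbc_and = parent.createAnd()
        for child in node[1]:
            _gpr_to_association(child, fbc_and, fbc_model, registered)
    else:
        fbc_or = parent.createOr()
        for child in node[1]:
            _gpr_to_association(child, fbc_or, fbc_model, registered)


def _association_to_gpr(assoc, labels: Dict[str, str]) -> str:
    if assoc is None:
        return ""
    type_code = assoc.getTypeCode()
    if type_code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return labels.get(assoc.getGeneProduct(), assoc.getGeneProduct())
    children = [
        _association_to_gpr(assoc.getAssociation(i), labels)
        for i in range(assoc.getNumAssociations())
    ]
    joiner = " and " if type_code == libsbml.SBML_FBC_AND else " or "
    rendered = joiner.join(
        f"({c})" if (" and " in c or " or " in c) else c for c in children
    )
    return rendered


def write_sbml(document: ModelDocument, path: str) -> None:
    """Serialise a model as SBML L3V1 with the FBC v2 package."""
    model = document.model
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    sbml_doc = libsbml.SBMLDocument(ns)
    sbml_doc.setPackageRequired("fbc", False)
    sbml = sbml_doc.createModel()
    model_sid = _sid(model.id)
    sbml.setId(model_sid if model_sid[:1].isalpha() or model_sid[:1] == "_"
               else "MOD_" + model_sid)
    fbc = sbml.getPlugin("fbc")
    fbc.setStrict(False)

    for comp_id, comp_name in model.compartments.items():
        compartment = sbml.createCompartment()
        compartment.setId(comp_id)
        compartment.setName(comp_name)
        compartment.setConstant(True)

    for met in model.metabolites.values():
        species = sbml.createSpecies()
        species.setId("M_" + _sid(met.id))
        species.setName(met.name)
        species.setCompartment(met.compartment)
        species.setHasOnlySubstanceUnits(False)
        species.setBoundaryCondition(False)
        species.setConstant(False)
        splug = species.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula:
            splug.setChemicalFormula(met.formula)

    def bound_parameter(value: float, name: str) -> str:
        pid = "P_" + _sid(name)
        parameter = sbml.createParameter()
        parameter.setId(pid)
        parameter.setValue(value)
        parameter.setConstant(True)
        return pid

    registered_genes: Dict[str, str] = {}
    for rxn in model.reactions.values():
        reaction = sbml.createReaction()
        reaction.setId("R_" + _sid(rxn.id))
        reaction.setName(rxn.name)
        reaction.setFast(False)
        reaction.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = reaction.createReactant() if coeff < 0 else reaction.createProduct()
            ref.setSpecies("M_" + _sid(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = reaction.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_parameter(rxn.lower_bound, rxn.id + "_lb"))
        rplug.setUpperFluxBound(bound_parameter(rxn.upper_bound, rxn.id + "_ub"))
        if rxn.gpr:
            gpa = rplug.createGeneProductAssociation()
            _gpr_to_association(parse_gpr(rxn.gpr), gpa, fbc, registered_genes)
        notes = []
        if rxn.subsystem:
            notes.append(f"<p>SUBSYSTEM: {rxn.subsystem}</p>")
        if rxn.is_boundary:
            notes.append("<p>BOUNDARY: true</p>")
        if rxn.id in model.pseudo_reactions:
            notes.append("<p>PSEUDO: true</p>")
        if notes:
            reaction.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                + "".join(notes) + "</body>"
            )

    if model.objective_id:
        objective = fbc.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction("R_" + _sid(model.objective_id))
        flux_obj.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(sbml_doc, str(path)) != 1:
        raise ModelIOError(f"could not write SBML to {path!r}")


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def read_sbml(path: str) -> ModelDocument:
    """Parse an SBML L3 + FBC file into a model document."""
    sbml_doc = libsbml.readSBMLFromFile(str(path))
    if sbml_doc.getNumErrors() > 0:
        for i in range(sbml_doc.getNumErrors()):
            err = sbml_doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelIOError(
                    f"SBML parse error in {path!r}: {err.getMessage().strip()}"
                )
    sbml = sbml_doc.getModel()
    if sbml is None:
        raise ModelIOError(f"{path!r} contains no SBML model")
    fbc = sbml.getPlugin("fbc")
    if fbc is None:
        raise ModelIOError(f"{path!r} lacks the FBC package (missing FBC)")

    model = StoichiometricModel(id=sbml.getId() or "model", compartments={})
    for i in range(sbml.getNumCompartments()):
        compartment = sbml.getCompartment(i)
        model.compartments[compartment.getId()] = compartment.getName() or compartment.getId()

    for i in range(sbml.getNumSpecies()):
        species = sbml.getSpecies(i)
        splug = species.getPlugin("fbc")
        model.add_metabolite(Metabolite(
            id=_strip_prefix(species.getId(), "M_"),
            name=species.getName(),
            formula=(splug.getChemicalFormula() if splug and splug.isSetChemicalFormula() else ""),
            charge=(splug.getCharge() if splug and splug.isSetCharge() else 0),
            compartment=species.getCompartment(),
        ))

    labels: Dict[str, str] = {}
    for i in range(fbc.getNumGeneProducts()):
        gp = fbc.getGeneProduct(i)
        labels[gp.getId()] = gp.getLabel() or gp.getId()

    def parameter_value(pid: str) -> float:
        parameter = sbml.getParameter(pid)
        if parameter is None:
            raise ModelIOError(f"missing flux-bound parameter {pid!r}")
        return parameter.getValue()

    pseudo: List[str] = []
    for i in range(sbml.getNumReactions()):
        reaction = sbml.getReaction(i)
        rxn_id = _strip_prefix(reaction.getId(), "R_")
        stoich: Dict[str, float] = {}
        for j in range(reaction.getNumReactants()):
            ref = reaction.getReactant(j)
            met = _strip_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(reaction.getNumProducts()):
            ref = reaction.getProduct(j)
            met = _strip_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = reaction.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound():
            raise ModelIOError(
                f"reaction {rxn_id!r} lacks FBC flux bounds (missing FBC)"
            )
        gpr = ""
        if rplug.isSetGeneProductAssociation():
            gpr = _association_to_gpr(
                rplug.getGeneProductAssociation().getAssociation(), labels
            )
        subsystem = ""
        is_boundary = len(stoich) == 1 and rxn_id.startswith(_BOUNDARY_PREFIXES)
        if reaction.isSetNotes():
            notes = reaction.getNotesString()
            for line in notes.splitlines():
                line = line.strip()
                if "SUBSYSTEM:" in line:
                    subsystem = line.split("SUBSYSTEM:", 1)[1].split("<")[0].strip()
                if "BOUNDARY: true" in line:
                    is_boundary = True
                if "PSEUDO: true" in line:
                    pseudo.append(rxn_id)
        model.add_reaction(Reaction(
            id=rxn_id,
            name=reaction.getName(),
            stoichiometry=stoich,
            lower_bound=parameter_value(rplug.getLowerFluxBound()),
            upper_bound=parameter_value(rplug.getUpperFluxBound()),
            gpr=gpr,
            subsystem=subsystem,
            is_boundary=is_boundary,
        ))

    objective = fbc.getActiveObjective()
    if objective is None or objective.getNumFluxObjectives() == 0:
        raise ModelIOError(f"{path!r} declares no flux objective")
    model.objective_id = _strip_prefix(
        objective.getFluxObjective(0).getReaction(), "R_"
    )
    model.pseudo_reactions = set(pseudo) or {model.objective_id}
    model.validate()
    return ModelDocument(model=model, source_format="sbml")


# ---------------------------------------------------------------------------
# COBRA JSON
# ---------------------------------------------------------------------------

def write_json_model(document: ModelDocument, path: str) -> None:
    """Serialise a model following the community COBRA JSON schema (v1)."""
    model = document.model
    genes = sorted({g for r in model.reactions.values() for g in gpr_genes(r.gpr)})
    payload = {
        "id": model.id,
        "version": "1",
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": met.id,
                "name": met.name,
                "compartment": met.compartment,
                "formula": met.formula,
                "charge": met.charge,
            }
            for met in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": rxn.id,
                "name": rxn.name,
                "metabolites": dict(rxn.stoichiometry),
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "gene_reaction_rule": rxn.gpr,
                "subsystem": rxn.subsystem,
                "objective_coefficient": 1.0 if rxn.id == model.objective_id else 0.0,
                "notes": (
                    {"boundary": True} if rxn.is_boundary else {}
                ) | ({"pseudo": True} if rxn.id in model.pseudo_reactions else {}),
            }
            for rxn in model.reactions.values()
        ],
        "genes": [{"id": g, "name": g} for g in genes],
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1)


def read_json_model(path: str) -> ModelDocument:
    """Parse a COBRA-schema JSON model file."""
    with open(path) as handle:
        try:
            payload = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ModelIOError(f"malformed JSON in {path!r}: {exc}") from exc
    for key in ("metabolites", "reactions"):
        if key not in payload:
            raise ModelIOError(f"{path!r} lacks required key {key!r}")

    model = StoichiometricModel(
        id=payload.get("id", "model"),
        compartments=dict(payload.get("compartments", {})) or {"c": "cytosol"},
    )
    for met in payload["metabolites"]:
        compartment = met.get("compartment", "c")
        if compartment not in model.compartments:
            model.compartments[compartment] = compartment
        model.add_metabolite(Metabolite(
            id=met["id"], name=met.get("name", ""),
            formula=met.get("formula") or "",
            charge=int(met.get("charge", 0) or 0),
            compartment=compartment,
        ))

    objective_id = ""
    pseudo: List[str] = []
    for rxn in payload["reactions"]:
        notes = rxn.get("notes", {}) or {}
        is_boundary = bool(notes.get("boundary")) or _infer_boundary(
            rxn["id"], len(rxn["metabolites"])
        ) and rxn["id"].startswith(_BOUNDARY_PREFIXES)
        model.add_reaction(Reaction(
            id=rxn["id"], name=rxn.get("name", ""),
            stoichiometry={k: float(v) for k, v in rxn["metabolites"].items()},
            lower_bound=float(rxn.get("lower_bound", 0.0)),
            upper_bound=float(rxn.get("upper_bound", math.inf)),
            gpr=rxn.get("gene_reaction_rule", "") or "",
            subsystem=rxn.get("subsystem", "") or "",
            is_boundary=is_boundary,
        ))
        if rxn.get("objective_coefficient"):
            objective_id = rxn["id"]
        if notes.get("pseudo"):
            pseudo.append(rxn["id"])
    if not objective_id:
        raise ModelIOError(f"{path!r} declares no objective reaction")
    model.objective_id = objective_id
    model.pseudo_reactions = set(pseudo) or {objective_id}
    model.validate()
    return ModelDocument(model=model, source_format="json")


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def read_model(path: str) -> ModelDocument:
    """Dispatch on file extension (.xml/.sbml vs .json)."""
    text = str(path)
    if text.endswith((".xml", ".sbml")):
        return read_sbml(path)
    if text.endswith(".json"):
        return read_json_model(path)
    raise ModelIOError(f"cannot infer model format from {path!r}")


def write_model(document: ModelDocument, path: str) -> None:
    text = str(path)
    if text.endswith((".xml", ".sbml")):
        write_sbml(document, path)
    elif text.endswith(".json"):
        write_json_model(document, path)
    else:
        raise ModelIOError(f"cannot infer model format from {path!r}")


def models_equal(a: StoichiometricModel, b: StoichiometricModel,
                 tol: float = 0.0) -> bool:
    """Structural equality: ids, stoichiometry, bounds, GPRs, objective."""
    if set(a.metabolites) != set(b.metabolites):
        return False
    if set(a.reactions) != set(b.reactions):
        return False
    for met_id, met_a in a.metabolites.items():
        met_b = b.metabolites[met_id]
        if (met_a.formula, met_a.charge, met_a.compartment) != (
            met_b.formula, met_b.charge, met_b.compartment
        ):
            return False
    for rxn_id, rxn_a in a.reactions.items():
        rxn_b = b.reactions[rxn_id]
        if set(rxn_a.stoichiometry) != set(rxn_b.stoichiometry):
            return False
        for met_id, coeff in rxn_a.stoichiometry.items():
            if abs(coeff - rxn_b.stoichiometry[met_id]) > tol:
                return False
        for bound in ("lower_bound", "upper_bound"):
            va, vb = getattr(rxn_a, bound), getattr(rxn_b, bound)
            if va != vb and not (math.isinf(va) and math.isinf(vb) and va * vb > 0):
                return False
        if rxn_a.gpr != rxn_b.gpr:
            return False
    return a.objective_id == b.objective_id
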