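"""Programmatic construction of a desk-scale core model of methanotroph
central metabolism.

The network covers every pathway the electron-transfer analysis
manipulates: methane oxidation by the soluble (SMMOi) and two particulate
monooxygenase variants (PMMOipp quinol-driven, PMMODCipp cytochrome
c555-driven), periplasmic methanol dehydrogenase, three formaldehyde
oxidation routes, all four RuMP-cycle variants, the CBB carboxylation
pair, a TCA branch with a blockable 2-oxoglutarate dehydrogenase, a
parameterised respiratory chain, ammonium/nitrate/dinitrogen nitrogen
metabolism including co-oxidation of ammonium to nitrite, and a
composition-derived biomass drain.

Every non-pseudo reaction is elementally and charge balanced; the
respiratory proton stoichiometries are exposed on
:class:`NetworkOptions` because they are free parameters of the
analysis.  The proton-motive force is represented purely
stoichiometrically: periplasmic protons are ordinary metabolites and no
membrane-potential term exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .biomass_builder import (
    BiomassComposition,
    SynthesisCostTable,
    assemble_biomass_reaction,
    lipid_coefficients,
    nucleotide_coefficients,
)
from .model_core import Metabolite, Reaction, StoichiometricModel
from .reference_data import CONSTANTS, default_composition

__all__ = [
    "NetworkOptions",
    "build_core_model",
    "set_nitrogen_source",
    "set_mmo_availability",
    "set_atp_synthase_stoichiometry",
    "baseline_medium",
    "NITROGEN_SOURCES",
]

INF = math.inf

NITROGEN_SOURCES = ("nh4_excess", "nh4_low", "no3", "n2")


@dataclass
class NetworkOptions:
    """Tunable stoichiometric parameters of the core network."""

    protons_per_atp: float = 4.0
    ndh_protons_per_2e: float = 4.0
    bc1_protons_per_2e: float = 4.0
    oxidase_protons_per_2e: float = 4.0
    akgdh_blocked: bool = True
    gam: float = 23.087   # mmol ATP / gDW
    ngam: float = 8.39    # mmol ATP / gDW / h

    def validate(self) -> None:
        if self.protons_per_atp < 1.0:
            raise ValueError(
                "protons_per_atp must be >= 1 (the synthase returns "
                f"{self.protons_per_atp - 1} protons to the cytosol)"
            )
        for name in ("ndh_protons_per_2e", "bc1_protons_per_2e",
                     "oxidase_protons_per_2e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bc1_protons_per_2e < 2.0:
            raise ValueError("bc1_protons_per_2e must be >= 2 (quinol chemistry)")
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("maintenance demands must be non-negative")


# ---------------------------------------------------------------------------
# species table: base id -> (name, formula, charge)
# ---------------------------------------------------------------------------

_SPECIES: Dict[str, Tuple[str, str, int]] = {
    "ch4": ("Methane", "CH4", 0),
    "o2": ("Oxygen", "O2", 0),
    "co2": ("Carbon dioxide", "CO2", 0),
    "h2o": ("Water", "H2O", 0),
    "h": ("Proton", "H", 1),
    "h2": ("Hydrogen", "H2", 0),
    "meoh": ("Methanol", "CH4O", 0),
    "fald": ("Formaldehyde", "CH2O", 0),
    "for": ("Formate", "CHO2", -1),
    "nad": ("NAD+", "C21H26N7O14P2", -1),
    "nadh": ("NADH", "C21H27N7O14P2", -2),
    "nadp": ("NADP+", "C21H25N7O17P3", -3),
    "nadph": ("NADPH", "C21H26N7O17P3", -4),
    "q8": ("Ubiquinone-8", "C49H74O4", 0),
    "q8h2": ("Ubiquinol-8", "C49H76O4", 0),
    "ficytcc555": ("Ferricytochrome c555", "Fe", 3),
    "focytcc555": ("Ferrocytochrome c555", "Fe", 2),
    "ficytcc553": ("Ferricytochrome c553", "Fe", 3),
    "focytcc553": ("Ferrocytochrome c553", "Fe", 2),
    "fdxox": ("Oxidised ferredoxin", "Fe", 3),
    "fdxrd": ("Reduced ferredoxin", "Fe", 2),
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "pi": ("Phosphate", "HO4P", -2),
    "ppi": ("Diphosphate", "HO7P2", -3),
    "nh4": ("Ammonium", "H4N", 1),
    "ham": ("Hydroxylamine", "H3NO", 0),
    "no2": ("Nitrite", "NO2", -1),
    "no3": ("Nitrate", "NO3", -1),
    "n2": ("Dinitrogen", "N2", 0),
    "so4": ("Sulfate", "O4S", -2),
    "g6p": ("D-Glucose 6-phosphate", "C6H11O9P", -2),
    "f6p": ("D-Fructose 6-phosphate", "C6H11O9P", -2),
    "fdp": ("D-Fructose 1,6-bisphosphate", "C6H10O12P2", -4),
    "dhap": ("Dihydroxyacetone phosphate", "C3H5O6P", -2),
    "g3p": ("Glyceraldehyde 3-phosphate", "C3H5O6P", -2),
    "13dpg": ("3-Phospho-D-glyceroyl phosphate", "C3H4O10P2", -4),
    "3pg": ("3-Phospho-D-glycerate", "C3H4O7P", -3),
    "2pg": ("2-Phospho-D-glycerate", "C3H4O7P", -3),
    "pep": ("Phosphoenolpyruvate", "C3H2O6P", -3),
    "pyr": ("Pyruvate", "C3H3O3", -1),
    "6pgl": ("6-Phospho-D-glucono-1,5-lactone", "C6H9O9P", -2),
    "6pgc": ("6-Phospho-D-gluconate", "C6H10O10P", -3),
    "2ddg6p": ("2-Dehydro-3-deoxy-D-gluconate 6-phosphate", "C6H8O9P", -3),
    "ru5p__D": ("D-Ribulose 5-phosphate", "C5H9O8P", -2),
    "r5p": ("alpha-D-Ribose 5-phosphate", "C5H9O8P", -2),
    "xu5p__D": ("D-Xylulose 5-phosphate", "C5H9O8P", -2),
    "h6p": ("D-arabino-Hex-3-ulose 6-phosphate", "C6H11O9P", -2),
    "s7p": ("Sedoheptulose 7-phosphate", "C7H13O10P", -2),
    "s17bp": ("Sedoheptulose 1,7-bisphosphate", "C7H12O13P2", -4),
    "e4p": ("D-Erythrose 4-phosphate", "C4H7O7P", -2),
    "rb15bp": ("D-Ribulose 1,5-bisphosphate", "C5H8O11P2", -4),
    "accoa": ("Acetyl-CoA", "C23H34N7O17P3S", -4),
    "coa": ("Coenzyme A", "C21H32N7O16P3S", -4),
    "cit": ("Citrate", "C6H5O7", -3),
    "icit": ("Isocitrate", "C6H5O7", -3),
    "akg": ("2-Oxoglutarate", "C5H4O5", -2),
    "succoa": ("Succinyl-CoA", "C25H35N7O19P3S", -5),
    "succ": ("Succinate", "C4H4O4", -2),
    "fum": ("Fumarate", "C4H2O4", -2),
    "mal__L": ("L-Malate", "C4H4O5", -2),
    "oaa": ("Oxaloacetate", "C4H2O5", -2),
    "glu__L": ("L-Glutamate", "C5H8NO4", -1),
    "gln__L": ("L-Glutamine", "C5H10N2O3", 0),
    "ala__L": ("L-Alanine", "C3H7NO2", 0),
    "thmpt": ("Tetrahydromethanopterin (lumped)", "C30H45N6O16P", -3),
    "mlthmpt": ("Methylene-tetrahydromethanopterin (lumped)", "C31H47N6O17P", -3),
    "biomass": ("Biomass", "", 0),
}


def _met(model: StoichiometricModel, base: str, compartment: str) -> str:
    met_id = f"{base}_{compartment}"
    if met_id not in model.metabolites:
        name, formula, charge = _SPECIES[base]
        model.add_metabolite(Metabolite(
            id=met_id, name=name, formula=formula, charge=charge,
            compartment=compartment,
        ))
    return met_id


def _add(
    model: StoichiometricModel,
    rxn_id: str,
    stoich: Dict[str, float],
    lb: float = 0.0,
    ub: float = INF,
    subsystem: str = "",
    boundary: bool = False,
    name: str = "",
) -> Reaction:
    full: Dict[str, float] = {}
    for spec, coeff in stoich.items():
        base, comp = spec.rsplit("_", 1)
        full[_met(model, base, comp)] = coeff
    return model.add_reaction(Reaction(
        id=rxn_id, stoichiometry=full, lower_bound=lb, upper_bound=ub,
        subsystem=subsystem, is_boundary=boundary, name=name or rxn_id,
    ))


# ---------------------------------------------------------------------------
# biomass precursor mapping
# ---------------------------------------------------------------------------

#: Mole fraction of the protein drain carried by alanine; the remainder is
#: glutamate.  Chosen so the mean residue mass lands near typical protein.
_ALA_MOLE_FRACTION = 0.55

#: Acetyl-CoA (C2) units, glycerol backbones and reduction/activation costs
#: per lipid species used to translate the monomer coefficients onto core
#: precursors.
_LIPID_PRECURSOR_COST: Dict[str, Tuple[float, float]] = {
    # species -> (acyl chains, glycerol-phosphate backbones)
    "pe": (2.0, 1.0),
    "pc": (2.0, 1.0),
    "pg": (2.0, 1.0),
    "clpn": (4.0, 2.0),
    "fa_c14": (1.0, 0.0),
    "fa_c16": (1.0, 0.0),
    "fa_c16_1": (1.0, 0.0),
    "fa_c18_1": (1.0, 0.0),
}
_ACCOA_PER_CHAIN = 8.0     # C16 equivalent
_NADPH_PER_CHAIN = 14.0
_ATP_PER_CHAIN = 7.0
_BASE_N_PER_NUCLEOTIDE = 3.75   # mean ring nitrogens across the four bases
_GLYCOGEN_RESIDUE_MASS = 162.14
_GENERIC_NADPH = 1.0       # mmol/gDW catch-all for other reductive synthesis

#: Small fixed drains standing in for the biosynthetic families that are
#: not resolved at monomer level in the core network (aromatics, other
#: amino-acid skeletons, cofactors).
_AUXILIARY_PRECURSORS: Dict[str, float] = {
    "pep_c": 0.2, "oaa_c": 0.4, "akg_c": 0.2, "pyr_c": 0.3,
    "3pg_c": 0.3, "e4p_c": 0.1,
}


def biomass_precursor_coefficients(
    composition: BiomassComposition,
    costs: SynthesisCostTable,
) -> Dict[str, Dict[str, float]]:
    """Map a macromolecular composition onto core-model precursor drains.

    Protein is drained as alanine plus glutamate totalling ``x_protein``
    residues; nucleic acids as ribose-5-phosphate backbones plus ammonium
    for ring nitrogen; lipids as acetyl-CoA chains with their NADPH/ATP
    synthesis costs; carbohydrate as fructose-6-phosphate residues.
    Returned maps are positive mmol/gDW drains keyed by metabolite id.
    """
    protein = {
        "ala__L_c": _ALA_MOLE_FRACTION * costs.x_protein,
        "glu__L_c": (1.0 - _ALA_MOLE_FRACTION) * costs.x_protein,
    }

    nucleotides = nucleotide_coefficients(
        composition.gc_content,
        composition.fractions.get("rna", 0.0),
        composition.fractions.get("dna", 0.0),
    )
    residues = sum(nucleotides.values())
    nucleic = {
        "r5p_c": residues,
        "nh4_c": _BASE_N_PER_NUCLEOTIDE * residues,
    }

    lipids = lipid_coefficients(composition)
    chains = sum(_LIPID_PRECURSOR_COST[s][0] * v for s, v in lipids.items())
    backbones = sum(_LIPID_PRECURSOR_COST[s][1] * v for s, v in lipids.items())
    lipid = {
        "accoa_c": chains * _ACCOA_PER_CHAIN,
        "dhap_c": backbones,
    }

    carbohydrate = {
        "f6p_c": composition.fractions.get("glucose", 0.0)
        / (_GLYCOGEN_RESIDUE_MASS / 1000.0),
    }

    energy = {
        "nadph_c": chains * _NADPH_PER_CHAIN + _GENERIC_NADPH,
        "atp_c_extra": 0.0,  # placeholder, merged below
    }
    # lipid activation ATP is charged on top of the polymerisation GAM
    extra_atp = chains * _ATP_PER_CHAIN
    del energy["atp_c_extra"]

    return {
        "protein": protein,
        "nucleic_acids": nucleic,
        "lipids": lipid,
        "carbohydrate": carbohydrate,
        "reductant": energy,
        "activation": {"atp_lipid": extra_atp},
    }


def _core_biomass_reaction(
    composition: BiomassComposition, costs: SynthesisCostTable, gam: float
) -> Reaction:
    maps = biomass_precursor_coefficients(composition, costs)
    extra_atp = maps.pop("activation")["atp_lipid"]
    accoa = maps["lipids"].pop("accoa_c")
    nadph = maps["reductant"].pop("nadph_c")

    rxn = assemble_biomass_reaction(
        maps, gam=gam, reaction_id="BIOMASS", biomass_metabolite="biomass_c",
    )
    st = rxn.stoichiometry
    # acetyl-CoA drain returns free CoA; NADPH drain returns NADP+ and a
    # proton; lipid activation ATP hydrolyses alongside the GAM terms.
    st["accoa_c"] = st.get("accoa_c", 0.0) - accoa
    st["coa_c"] = st.get("coa_c", 0.0) + accoa
    st["nadph_c"] = st.get("nadph_c", 0.0) - nadph
    st["nadp_c"] = st.get("nadp_c", 0.0) + nadph
    st["h_c"] = st.get("h_c", 0.0) + nadph
    st["atp_c"] -= extra_atp
    st["h2o_c"] -= extra_atp
    st["adp_c"] += extra_atp
    st["pi_c"] += extra_atp
    st["h_c"] += extra_atp
    # 9-decimal coefficients survive SBML's significant-digit formatting,
    # keeping write -> read round trips exact
    rxn.stoichiometry = {k: round(v, 9) for k, v in st.items() if round(v, 9)}
    rxn.subsystem = "Biomass"
    return rxn


# ---------------------------------------------------------------------------
# the builder
# ---------------------------------------------------------------------------

def set_atp_synthase_stoichiometry(model: StoichiometricModel, protons_per_atp: float) -> None:
    """Rewrite the ATP synthase with the given H+/ATP coupling ratio."""
    if protons_per_atp < 1.0:
        raise ValueError("protons_per_atp must be >= 1")
    rxn = model.reactions["ATPS4rpp"]
    rxn.stoichiometry = {
        "h_p": -protons_per_atp, "adp_c": -1.0, "pi_c": -1.0,
        "atp_c": 1.0, "h2o_c": 1.0, "h_c": protons_per_atp - 1.0,
    }


def build_core_model(options: Optional[NetworkOptions] = None) -> StoichiometricModel:
    """Build the curated core model.

    The returned model grows on methane with ammonium, nitrate or
    dinitrogen under any of the three electron-transfer modes, passes the
    elemental/charge balance check and produces no ATP with all
    exchanges closed.
    """
    opt = options or NetworkOptions()
    opt.validate()

    model = StoichiometricModel(id="mcap_core")

    ndh = opt.ndh_protons_per_2e
    bc1 = opt.bc1_protons_per_2e
    oxp = opt.oxidase_protons_per_2e
    a = opt.protons_per_atp

    # -- methane and methanol oxidation ----------------------------------
    _add(model, "SMMOi",
         {"ch4_c": -1, "o2_c": -1, "nadh_c": -1, "h_c": -1,
          "meoh_c": 1, "h2o_c": 1, "nad_c": 1},
         subsystem="Methane oxidation", name="Soluble methane monooxygenase")
    _add(model, "PMMOipp",
         {"ch4_p": -1, "o2_p": -1, "q8h2_c": -1,
          "meoh_p": 1, "h2o_p": 1, "q8_c": 1},
         subsystem="Methane oxidation",
         name="Particulate methane monooxygenase (ubiquinol)")
    _add(model, "PMMODCipp",
         {"ch4_p": -1, "o2_p": -1, "focytcc555_p": -2, "h_p": -2,
          "meoh_p": 1, "h2o_p": 1, "ficytcc555_p": 2},
         subsystem="Methane oxidation",
         name="Particulate methane monooxygenase (cytochrome c555)")
    _add(model, "MDH",
         {"meoh_p": -1, "ficytcc555_p": -2,
          "fald_p": 1, "focytcc555_p": 2, "h_p": 2},
         subsystem="Methane oxidation", name="Methanol dehydrogenase (periplasm)")

    # -- formaldehyde oxidation (three routes) ---------------------------
    _add(model, "FALDDHipp",
         {"fald_p": -1, "q8_c": -1, "h2o_p": -1,
          "for_p": 1, "q8h2_c": 1, "h_p": 1},
         subsystem="Formaldehyde oxidation",
         name="Dye-linked formaldehyde dehydrogenase (ubiquinone)")
    _add(model, "ALDD1",
         {"fald_c": -1, "h2o_c": -1, "nad_c": -1,
          "for_c": 1, "nadh_c": 1, "h_c": 2},
         subsystem="Formaldehyde oxidation",
         name="Aldehyde dehydrogenase (NAD, formaldehyde)")
    _add(model, "FAE",
         {"fald_c": -1, "thmpt_c": -1, "mlthmpt_c": 1},
         subsystem="Formaldehyde oxidation",
         name="Formaldehyde activating enzyme (lumped H4MPT route)")
    _add(model, "MTHMPTD",
         {"mlthmpt_c": -1, "h2o_c": -1, "nadp_c": -1,
          "thmpt_c": 1, "for_c": 1, "nadph_c": 1, "h_c": 2},
         subsystem="Formaldehyde oxidation",
         name="Methylene-H4MPT dehydrogenase (lumped to formate)")
    _add(model, "FDH",
         {"for_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1},
         subsystem="Formaldehyde oxidation", name="Formate dehydrogenase")

    # -- RuMP cycle (both cleavage and both rearrangement variants) ------
    _add(model, "HPS", {"fald_c": -1, "ru5p__D_c": -1, "h6p_c": 1},
         subsystem="RuMP cycle", name="Hexulose-6-phosphate synthase")
    _add(model, "PHI", {"h6p_c": -1, "f6p_c": 1},
         lb=-INF, subsystem="RuMP cycle", name="Hexulose-6-phosphate isomerase")
    _add(model, "PGI", {"g6p_c": -1, "f6p_c": 1}, lb=-INF,
         subsystem="Glycolysis")
    _add(model, "PFK", {"f6p_c": -1, "atp_c": -1,
                        "fdp_c": 1, "adp_c": 1, "h_c": 1},
         subsystem="Glycolysis", name="Phosphofructokinase")
    _add(model, "FBA", {"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, lb=-INF,
         subsystem="Glycolysis", name="Fructose-bisphosphate aldolase")
    _add(model, "TPI", {"dhap_c": -1, "g3p_c": 1}, lb=-INF,
         subsystem="Glycolysis")
    _add(model, "GAPD", {"g3p_c": -1, "nad_c": -1, "pi_c": -1,
                         "13dpg_c": 1, "nadh_c": 1, "h_c": 1},
         lb=-INF, subsystem="Glycolysis")
    _add(model, "PGK", {"3pg_c": -1, "atp_c": -1, "13dpg_c": 1, "adp_c": 1},
         lb=-INF, subsystem="Glycolysis")
    _add(model, "PGM", {"2pg_c": -1, "3pg_c": 1}, lb=-INF,
         subsystem="Glycolysis")
    _add(model, "ENO", {"2pg_c": -1, "pep_c": 1, "h2o_c": 1}, lb=-INF,
         subsystem="Glycolysis")
    _add(model, "PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1,
                        "pyr_c": 1, "atp_c": 1},
         subsystem="Glycolysis", name="Pyruvate kinase")
    _add(model, "PDH", {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
                        "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
         subsystem="Glycolysis", name="Pyruvate dehydrogenase")

    _add(model, "G6PDH2r", {"g6p_c": -1, "nadp_c": -1,
                            "6pgl_c": 1, "nadph_c": 1, "h_c": 1},
         lb=-INF, subsystem="Pentose phosphate / ED")
    _add(model, "PGL", {"6pgl_c": -1, "h2o_c": -1, "6pgc_c": 1, "h_c": 1},
         subsystem="Pentose phosphate / ED")
    _add(model, "GND", {"6pgc_c": -1, "nadp_c": -1,
                        "ru5p__D_c": 1, "co2_c": 1, "nadph_c": 1},
         subsystem="Pentose phosphate / ED",
         name="6-phosphogluconate dehydrogenase")
    _add(model, "EDD", {"6pgc_c": -1, "2ddg6p_c": 1, "h2o_c": 1},
         subsystem="Pentose phosphate / ED")
    _add(model, "EDA", {"2ddg6p_c": -1, "g3p_c": 1, "pyr_c": 1},
         subsystem="Pentose phosphate / ED", name="KDPG aldolase")
    _add(model, "RPI", {"ru5p__D_c": -1, "r5p_c": 1}, lb=-INF,
         subsystem="Pentose phosphate / ED")
    _add(model, "RPE", {"ru5p__D_c": -1, "xu5p__D_c": 1}, lb=-INF,
         subsystem="Pentose phosphate / ED")
    _add(model, "TKT1", {"xu5p__D_c": -1, "r5p_c": -1, "s7p_c": 1, "g3p_c": 1},
         lb=-INF, subsystem="Pentose phosphate / ED")
    _add(model, "TALA", {"s7p_c": -1, "g3p_c": -1, "e4p_c": 1, "f6p_c": 1},
         lb=-INF, subsystem="Pentose phosphate / ED", name="Transaldolase")
    _add(model, "TKT2", {"xu5p__D_c": -1, "e4p_c": -1, "f6p_c": 1, "g3p_c": 1},
         lb=-INF, subsystem="Pentose phosphate / ED")
    _add(model, "FBA3", {"s17bp_c": -1, "dhap_c": 1, "e4p_c": 1}, lb=-INF,
         subsystem="Pentose phosphate / ED",
         name="Sedoheptulose-bisphosphate aldolase")
    _add(model, "PFK_3_ppi", {"s7p_c": -1, "ppi_c": -1,
                              "s17bp_c": 1, "pi_c": 1, "h_c": 1},
         lb=-INF, subsystem="Pentose phosphate / ED",
         name="PPi-dependent phosphofructokinase (sedoheptulose)")
    _add(model, "PPA", {"ppi_c": -1, "h2o_c": -1, "pi_c": 2, "h_c": 1},
         subsystem="Pentose phosphate / ED", name="Inorganic pyrophosphatase")

    # -- CBB carboxylation ----------------------------------------------
    _add(model, "PRUK", {"ru5p__D_c": -1, "atp_c": -1,
                         "rb15bp_c": 1, "adp_c": 1, "h_c": 1},
         subsystem="CBB cycle", name="Phosphoribulokinase")
    _add(model, "RBPC", {"rb15bp_c": -1, "co2_c": -1, "h2o_c": -1,
                         "3pg_c": 2, "h_c": 2},
         subsystem="CBB cycle", name="Ribulose-bisphosphate carboxylase")

    # -- TCA branch ------------------------------------------------------
    _add(model, "CS", {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1,
                       "cit_c": 1, "coa_c": 1, "h_c": 1},
         subsystem="TCA cycle", name="Citrate synthase")
    _add(model, "ACONT", {"cit_c": -1, "icit_c": 1}, lb=-INF,
         subsystem="TCA cycle")
    _add(model, "ICDHyr", {"icit_c": -1, "nadp_c": -1,
                           "akg_c": 1, "co2_c": 1, "nadph_c": 1},
         lb=-INF, subsystem="TCA cycle", name="Isocitrate dehydrogenase (NADP)")
    akgdh_ub = 0.0 if opt.akgdh_blocked else INF
    _add(model, "AKGDH", {"akg_c": -1, "coa_c": -1, "nad_c": -1,
                          "succoa_c": 1, "co2_c": 1, "nadh_c": 1},
         lb=0.0, ub=akgdh_ub, subsystem="TCA cycle",
         name="2-oxoglutarate dehydrogenase")
    _add(model, "SUCOAS", {"succ_c": -1, "coa_c": -1, "atp_c": -1,
                           "succoa_c": 1, "adp_c": 1, "pi_c": 1},
         lb=-INF, subsystem="TCA cycle", name="Succinyl-CoA synthetase")
    _add(model, "SUCDi", {"succ_c": -1, "q8_c": -1, "fum_c": 1, "q8h2_c": 1},
         subsystem="TCA cycle", name="Succinate dehydrogenase (irreversible)")
    _add(model, "FUM", {"fum_c": -1, "h2o_c": -1, "mal__L_c": 1}, lb=-INF,
         subsystem="TCA cycle", name="Fumarase")
    _add(model, "MDH2", {"mal__L_c": -1, "q8_c": -1, "oaa_c": 1, "q8h2_c": 1},
         subsystem="TCA cycle", name="Malate dehydrogenase (ubiquinone)")
    _add(model, "PPC", {"pep_c": -1, "co2_c": -1, "h2o_c": -1,
                        "oaa_c": 1, "pi_c": 1, "h_c": 1},
         subsystem="TCA cycle", name="PEP carboxylase")

    # -- respiratory chain ----------------------------------------------
    _add(model, "NDH1", {"nadh_c": -1, "q8_c": -1, "h_c": -(ndh + 1),
                         "nad_c": 1, "q8h2_c": 1, "h_p": ndh},
         subsystem="Respiratory chain",
         name="NADH dehydrogenase I (proton pumping)")
    _add(model, "NDH2", {"nadh_c": -1, "q8_c": -1, "h_c": -1,
                         "nad_c": 1, "q8h2_c": 1},
         subsystem="Respiratory chain",
         name="NADH dehydrogenase II (non-pumping)")
    _add(model, "CYOR_q8ppi",
         {"q8h2_c": -1, "ficytcc553_p": -2, "h_c": -(bc1 - 2),
          "q8_c": 1, "focytcc553_p": 2, "h_p": bc1},
         lb=0.0, subsystem="Respiratory chain",
         name="Ubiquinol-cytochrome-c reductase")
    _add(model, "CYTCC555", {"focytcc555_p": -1, "ficytcc553_p": -1,
                             "ficytcc555_p": 1, "focytcc553_p": 1},
         subsystem="Respiratory chain",
         name="Cytochrome c555 -> c553 electron transfer")
    _add(model, "CYOO3ppi",
         {"focytcc553_p": -4, "o2_p": -1, "h_c": -(4 + 2 * oxp),
          "ficytcc553_p": 4, "h2o_p": 2, "h_p": 2 * oxp},
         subsystem="Respiratory chain",
         name="aa3-type cytochrome-c oxidase")
    _add(model, "CYTBDpp",
         {"q8h2_c": -2, "o2_p": -1, "h_c": -4,
          "q8_c": 2, "h2o_p": 2, "h_p": 4},
         subsystem="Respiratory chain",
         name="bd-type quinol oxidase (non-pumping)")
    _add(model, "ATPS4rpp",
         {"h_p": -a, "adp_c": -1, "pi_c": -1,
          "atp_c": 1, "h2o_c": 1, "h_c": a - 1},
         lb=-INF, subsystem="Respiratory chain", name="ATP synthase")
    _add(model, "ATPM", {"atp_c": -1, "h2o_c": -1,
                         "adp_c": 1, "pi_c": 1, "h_c": 1},
         lb=opt.ngam, subsystem="Maintenance", name="ATP maintenance demand")
    _add(model, "THD2pp", {"nadh_c": -1, "nadp_c": -1, "h_p": -2,
                           "nad_c": 1, "nadph_c": 1, "h_c": 2},
         subsystem="Respiratory chain",
         name="Proton-translocating transhydrogenase")

    # -- nitrogen metabolism ---------------------------------------------
    _add(model, "NO3R", {"no3_c": -1, "nadh_c": -1, "h_c": -1,
                         "no2_c": 1, "nad_c": 1, "h2o_c": 1},
         subsystem="Nitrogen metabolism", name="Assimilatory nitrate reductase")
    _add(model, "NTRIR", {"no2_c": -1, "nadph_c": -3, "h_c": -5,
                          "nh4_c": 1, "nadp_c": 3, "h2o_c": 2},
         subsystem="Nitrogen metabolism", name="Assimilatory nitrite reductase")
    _add(model, "GLNS", {"glu__L_c": -1, "nh4_c": -1, "atp_c": -1,
                         "gln__L_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 1},
         subsystem="Nitrogen metabolism", name="Glutamine synthetase")
    _add(model, "GLUSy", {"gln__L_c": -1, "akg_c": -1, "nadph_c": -1, "h_c": -1,
                          "glu__L_c": 2, "nadp_c": 1},
         subsystem="Nitrogen metabolism", name="Glutamate synthase (NADPH)")
    _add(model, "ALAD_L", {"pyr_c": -1, "nh4_c": -1, "nadh_c": -1, "h_c": -1,
                           "ala__L_c": 1, "h2o_c": 1, "nad_c": 1},
         subsystem="Nitrogen metabolism", name="Alanine dehydrogenase")
    _add(model, "ALATA_L", {"ala__L_c": -1, "akg_c": -1,
                            "pyr_c": 1, "glu__L_c": 1},
         lb=-INF, subsystem="Nitrogen metabolism", name="Alanine transaminase")
    _add(model, "AMMOipp", {"nh4_p": -1, "o2_p": -1, "q8h2_c": -1,
                            "ham_p": 1, "h2o_p": 1, "q8_c": 1, "h_p": 1},
         subsystem="Nitrogen metabolism",
         name="Ammonium co-oxidation by pMMO (quinol)")
    _add(model, "AMMOi", {"nh4_c": -1, "o2_c": -1, "nadh_c": -1,
                          "ham_c": 1, "h2o_c": 1, "nad_c": 1},
         subsystem="Nitrogen metabolism",
         name="Ammonium co-oxidation by sMMO (NADH)")
    _add(model, "HAMtpp", {"ham_c": -1, "ham_p": 1}, lb=-INF,
         subsystem="Transport", name="Hydroxylamine diffusion")
    _add(model, "HAO", {"ham_p": -1, "h2o_p": -1, "ficytcc553_p": -4,
                        "no2_p": 1, "h_p": 5, "focytcc553_p": 4},
         subsystem="Nitrogen metabolism", name="Hydroxylamine oxidoreductase")
    _add(model, "NIT1",
         {"n2_c": -1, "fdxrd_c": -8, "atp_c": -16, "h2o_c": -16,
          "nh4_c": 2, "h2_c": 1, "fdxox_c": 8, "adp_c": 16, "pi_c": 16,
          "h_c": 6},
         subsystem="Nitrogen metabolism", name="Nitrogenase")
    _add(model, "FNOR", {"fdxox_c": -2, "nadph_c": -1,
                         "fdxrd_c": 2, "nadp_c": 1, "h_c": 1},
         subsystem="Nitrogen metabolism",
         name="Ferredoxin-NADP+ reductase")

    # -- transport -------------------------------------------------------
    for base in ("ch4", "o2", "co2", "h2o", "nh4", "no3", "no2", "n2",
                 "h2", "pi", "so4"):
        _add(model, f"{base.upper()}tex", {f"{base}_e": -1, f"{base}_p": 1},
             lb=-INF, subsystem="Transport", name=f"{base} outer-membrane diffusion")
    _add(model, "Htex", {"h_e": -1, "h_p": 1}, lb=-INF,
         subsystem="Transport", name="proton outer-membrane diffusion")

    for base in ("ch4", "o2", "co2", "h2o", "n2", "h2"):
        _add(model, f"{base.upper()}tpp", {f"{base}_p": -1, f"{base}_c": 1},
             lb=-INF, subsystem="Transport", name=f"{base} inner-membrane diffusion")
    _add(model, "MEOHtpp", {"meoh_c": -1, "meoh_p": 1}, lb=-INF,
         subsystem="Transport", name="Methanol diffusion")
    _add(model, "FALDtpp", {"fald_p": -1, "fald_c": 1}, lb=-INF,
         subsystem="Transport", name="Formaldehyde diffusion")
    _add(model, "FORt2pp", {"for_p": -1, "h_p": -1, "for_c": 1, "h_c": 1},
         lb=-INF, subsystem="Transport", name="Formate-proton symport")
    _add(model, "NH4tpp", {"nh4_p": -1, "nh4_c": 1}, lb=-INF,
         subsystem="Transport", name="Ammonium uniport")
    _add(model, "NO3t2pp", {"no3_p": -1, "h_p": -1, "no3_c": 1, "h_c": 1},
         subsystem="Transport", name="Nitrate-proton symport")
    _add(model, "NO2t2pp", {"no2_p": -1, "h_p": -1, "no2_c": 1, "h_c": 1},
         lb=-INF, subsystem="Transport", name="Nitrite-proton symport")
    _add(model, "PIt2pp", {"pi_p": -1, "h_p": -1, "pi_c": 1, "h_c": 1},
         subsystem="Transport", name="Phosphate-proton symport")
    _add(model, "SO4abcpp", {"so4_p": -1, "atp_c": -1, "h2o_c": -1,
                             "so4_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 1},
         subsystem="Transport", name="Sulfate ABC transport")

    # -- exchanges and biomass -------------------------------------------
    for base in ("ch4", "o2", "co2", "h2o", "h", "nh4", "no3", "no2", "n2",
                 "h2", "pi", "so4"):
        _add(model, f"EX_{base}_e", {f"{base}_e": -1}, lb=-INF, ub=INF,
             subsystem="Exchange", boundary=True, name=f"{base} exchange")

    biomass = _core_biomass_reaction(default_composition(), CONSTANTS.gam_costs, opt.gam)
    for met_id in biomass.stoichiometry:
        base, comp = met_id.rsplit("_", 1)
        _met(model, base, comp)
    model.add_reaction(biomass)
    _add(model, "DM_biomass_c", {"biomass_c": -1}, lb=0.0, ub=INF,
         subsystem="Exchange", boundary=True, name="Biomass drain (demand)")

    model.objective_id = "BIOMASS"
    model.pseudo_reactions = {"BIOMASS"}
    model.validate()
    return model


# ---------------------------------------------------------------------------
# configuration helpers
# ---------------------------------------------------------------------------

def baseline_medium(nitrogen_source: str = "nh4_excess",
                    methane_uptake: float = CONSTANTS.methane_uptake) -> Dict[str, float]:
    """Uptake-limit map: methane bounded, minerals and O2 unconstrained,
    a single nitrogen exchange open."""
    if nitrogen_source not in NITROGEN_SOURCES:
        raise ValueError(f"unknown nitrogen source {nitrogen_source!r}")
    medium = {
        "EX_ch4_e": methane_uptake,
        "EX_o2_e": INF,
        "EX_h2o_e": INF,
        "EX_h_e": INF,
        "EX_pi_e": INF,
        "EX_so4_e": INF,
    }
    n_exchange = {
        "nh4_excess": "EX_nh4_e", "nh4_low": "EX_nh4_e",
        "no3": "EX_no3_e", "n2": "EX_n2_e",
    }[nitrogen_source]
    medium[n_exchange] = INF
    return medium


def set_nitrogen_source(
    model: StoichiometricModel, source: str, inplace: bool = False
) -> StoichiometricModel:
    """Configure assimilation routes and the open nitrogen exchange.

    Excess ammonium represses glutamine synthetase, so ``nh4_excess``
    blocks GLNS and leaves alanine dehydrogenase as the assimilation
    route; every other source opens both routes.
    """
    if source not in NITROGEN_SOURCES:
        raise ValueError(f"unknown nitrogen source {source!r}")
    for required in ("ALAD_L", "GLNS"):
        if required not in model.reactions:
            raise KeyError(f"model lacks reaction {required!r}")
    out = model if inplace else model.copy()

    from .model_core import apply_medium

    apply_medium(out, baseline_medium(source), inplace=True)
    glns = out.reactions["GLNS"]
    if source == "nh4_excess":
        glns.lower_bound = 0.0
        glns.upper_bound = 0.0
    else:
        glns.lower_bound = 0.0
        glns.upper_bound = INF
    return out


def set_mmo_availability(
    model: StoichiometricModel, mmo: str, inplace: bool = False
) -> StoichiometricModel:
    """Restrict methane oxidation to the soluble or particulate enzyme.

    Copper-replete growth (``pmmo``) closes the soluble enzyme and its
    ammonium co-oxidation; copper-limited growth (``smmo``) closes both
    particulate variants.  Which particulate variant carries flux is the
    electron-transfer mode's decision.
    """
    if mmo not in ("smmo", "pmmo"):
        raise ValueError(f"unknown MMO availability {mmo!r}")
    out = model if inplace else model.copy()
    if mmo == "smmo":
        for rid in ("PMMOipp", "PMMODCipp", "AMMOipp"):
            out.reactions[rid].lower_bound = 0.0
            out.reactions[rid].upper_bound = 0.0
    else:
        for rid in ("SMMOi", "AMMOi"):
            out.reactions[rid].lower_bound = 0.0
            out.reactions[rid].upper_bound = 0.0
    return out
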