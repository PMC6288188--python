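"""Turn a measured macromolecular composition into biomass coefficients.

Masses are grams per gram dry weight; coefficients are mmol per gram dry
weight.  Polymer residues (nucleotides in nucleic acid, amino acids in
protein) use monomer-minus-water molar masses; free species use the free
molar mass.  The growth-associated maintenance (GAM) is the dot product
of per-component contents and per-component ATP synthesis costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

from .model_core import Reaction

__all__ = [
    "BiomassComposition",
    "SynthesisCostTable",
    "compute_gam",
    "nucleotide_coefficients",
    "lipid_coefficients",
    "amino_acid_coefficients",
    "assemble_biomass_reaction",
    "RESIDUE_MASS_AA",
    "RESIDUE_MASS_DNMP",
    "RESIDUE_MASS_NMP",
    "SPECIES_MASS_LIPID",
]

WATER_MASS = 18.015

#: Free (hydrated) molar masses of the 20 proteinogenic amino acids.
FREE_MASS_AA: Dict[str, float] = {
    "ala": 89.09, "arg": 174.20, "asn": 132.12, "asp": 133.10,
    "cys": 121.16, "gln": 146.15, "glu": 147.13, "gly": 75.07,
    "his": 155.15, "ile": 131.17, "leu": 131.17, "lys": 146.19,
    "met": 149.21, "phe": 165.19, "pro": 115.13, "ser": 105.09,
    "thr": 119.12, "trp": 204.23, "tyr": 181.19, "val": 117.15,
}

#: Residue (dehydrated) masses for protein polymer accounting.
RESIDUE_MASS_AA: Dict[str, float] = {
    aa: mass - WATER_MASS for aa, mass in FREE_MASS_AA.items()
}

#: Deoxyribonucleotide-monophosphate residue masses (dNMP minus water).
RESIDUE_MASS_DNMP: Dict[str, float] = {
    "damp": 331.22 - WATER_MASS,
    "dtmp": 322.21 - WATER_MASS,
    "dgmp": 347.22 - WATER_MASS,
    "dcmp": 307.20 - WATER_MASS,
}

#: Ribonucleotide-monophosphate residue masses (NMP minus water).
RESIDUE_MASS_NMP: Dict[str, float] = {
    "amp": 347.22 - WATER_MASS,
    "ump": 324.18 - WATER_MASS,
    "gmp": 363.22 - WATER_MASS,
    "cmp": 323.20 - WATER_MASS,
}

#: Representative molar masses for lipid species (di-C16 phospholipids,
#: free fatty acids).
SPECIES_MASS_LIPID: Dict[str, float] = {
    "pe": 691.97,       # phosphatidylethanolamine
    "pc": 734.05,       # phosphatidylcholine
    "pg": 722.97,       # phosphatidylglycerol
    "clpn": 1405.0,     # cardiolipin
    "fa_c14": 228.37,
    "fa_c16": 256.42,
    "fa_c16_1": 254.41,
    "fa_c18_1": 282.46,
}


def _renormalize(distribution: Mapping[str, float]) -> Dict[str, float]:
    total = sum(distribution.values())
    if total <= 0:
        raise ValueError("distribution sums to zero")
    return {k: v / total for k, v in distribution.items()}


@dataclass
class BiomassComposition:
    """Macromolecular fractions (g/gDW) plus monomer distributions.

    Distributions are renormalized to sum to one so that unidentified
    mass is excluded from the split.
    """

    fractions: Dict[str, float] = field(default_factory=dict)
    amino_acids: Dict[str, float] = field(default_factory=dict)  # g / kg DW
    gc_content: float = 0.636
    phospholipid_share_of_fat: float = 0.94
    fatty_acid_distribution: Dict[str, float] = field(
        default_factory=lambda: {"fa_c16": 0.50, "fa_c16_1": 0.40,
                                 "fa_c14": 0.05, "fa_c18_1": 0.05}
    )
    phospholipid_class_distribution: Dict[str, float] = field(
        default_factory=lambda: {"pe": 0.50, "pg": 0.30, "pc": 0.10, "clpn": 0.10}
    )

    def __post_init__(self) -> None:
        for key, value in self.fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"fraction {key!r} = {value} outside [0, 1]")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("GC content must lie in [0, 1]")
        if not 0.0 <= self.phospholipid_share_of_fat <= 1.0:
            raise ValueError("phospholipid share must lie in [0, 1]")
        self.fatty_acid_distribution = _renormalize(self.fatty_acid_distribution)
        self.phospholipid_class_distribution = _renormalize(
            self.phospholipid_class_distribution
        )


@dataclass(frozen=True)
class SynthesisCostTable:
    """Polymerisation ATP costs C_i (mmol ATP / mmol component) and
    contents x_i (mmol component / gDW) for protein, DNA and RNA."""

    c_protein: float
    c_dna: float
    c_rna: float
    x_protein: float
    x_dna: float
    x_rna: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"synthesis-cost entry {name} is negative")


def compute_gam(costs: SynthesisCostTable) -> float:
    """Growth-associated maintenance: sum over components of x_i * C_i."""
    return (costs.x_protein * costs.c_protein
            + costs.x_dna * costs.c_dna
            + costs.x_rna * costs.c_rna)


def nucleotide_coefficients(
    gc: float, rna_fraction: float, dna_fraction: float
) -> Dict[str, float]:
    """Split nucleic-acid mass over individual nucleotide residues.

    DNA places gc/2 of the moles on each of dGMP/dCMP and (1-gc)/2 on
    each of dAMP/dTMP; RNA likewise for A/U/G/C.  Gram fractions are
    converted to mmol via the mole-fraction-weighted mean residue mass,
    which conserves the input grams exactly.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("GC content must lie in [0, 1]")
    if rna_fraction < 0 or dna_fraction < 0:
        raise ValueError("nucleic-acid fractions must be non-negative")

    coefficients: Dict[str, float] = {}
    for fraction, masses, gc_pair in (
        (dna_fraction, RESIDUE_MASS_DNMP, ("dgmp", "dcmp")),
        (rna_fraction, RESIDUE_MASS_NMP, ("gmp", "cmp")),
    ):
        mole_frac = {
            base: (gc / 2 if base in gc_pair else (1 - gc) / 2)
            for base in masses
        }
        mean_mass = sum(mole_frac[b] * masses[b] for b in masses)  # g/mol
        total_mmol = fraction / (mean_mass / 1000.0) if fraction else 0.0
        for base in masses:
            coefficients[base] = mole_frac[base] * total_mmol
    return coefficients


def lipid_coefficients(composition: BiomassComposition) -> Dict[str, float]:
    """Split crude fat into phospholipid classes and free fatty acids.

    The phospholipid share of the crude-fat mass is divided across the
    class distribution, the remainder across the fatty-acid
    distribution; masses convert to mmol via representative species
    masses.
    """
    crude_fat = composition.fractions.get("crude_fat", 0.0)
    share = composition.phospholipid_share_of_fat
    coefficients: Dict[str, float] = {}
    for dist, pool_mass in (
        (composition.phospholipid_class_distribution, crude_fat * share),
        (composition.fatty_acid_distribution, crude_fat * (1.0 - share)),
    ):
        for species, weight in dist.items():
            mass = pool_mass * weight
            coefficients[species] = mass / (SPECIES_MASS_LIPID[species] / 1000.0)
    return coefficients


def amino_acid_coefficients(
    amino_acids: Mapping[str, float], basis: str = "residue"
) -> Dict[str, float]:
    """Convert a g/kg-DW amino-acid table into mmol/gDW coefficients.

    ``basis`` selects residue (dehydrated, for protein polymer) or free
    molar masses.  mmol/gDW = (g/kg) / molar mass, since g/kg equals
    mg/g.
    """
    if basis == "residue":
        masses = RESIDUE_MASS_AA
    elif basis == "free":
        masses = FREE_MASS_AA
    else:
        raise ValueError(f"unknown mass basis {basis!r}")
    coefficients: Dict[str, float] = {}
    for residue, grams_per_kg in amino_acids.items():
        if residue not in masses:
            raise KeyError(f"unknown amino-acid token {residue!r}")
        if grams_per_kg < 0:
            raise ValueError(f"negative amino-acid entry for {residue!r}")
        coefficients[residue] = grams_per_kg / masses[residue]
    return coefficients


def assemble_biomass_reaction(
    coefficient_maps: Mapping[str, Mapping[str, float]],
    gam: float,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str = "biomass_c",
    atp_species: Optional[Mapping[str, str]] = None,
) -> Reaction:
    """Build the biomass drain from monomer/precursor coefficient maps.

    Each map contributes consumed species (negative coefficients, in mmol
    per gDW so that the flux carries units of 1/h).  The GAM appears as
    ``gam ATP + gam H2O -> gam ADP + gam Pi + gam H+`` and one unit of
    biomass is produced.  A species occurring in more than one input map
    is a hard error: silent merging would hide double counting.
    """
    if gam < 0:
        raise ValueError("GAM must be non-negative")
    if not coefficient_maps or all(not m for m in coefficient_maps.values()):
        raise ValueError("need at least one non-empty coefficient map")
    species = atp_species or {
        "atp": "atp_c", "adp": "adp_c", "pi": "pi_c", "h": "h_c", "h2o": "h2o_c",
    }

    stoichiometry: Dict[str, float] = {}
    seen: Dict[str, str] = {}
    for map_name, coefficients in coefficient_maps.items():
        for met_id, value in coefficients.items():
            if met_id in seen:
                raise ValueError(
                    f"species {met_id!r} appears in both {seen[met_id]!r} and "
                    f"{map_name!r} coefficient maps"
                )
            seen[met_id] = map_name
            if value:
                stoichiometry[met_id] = stoichiometry.get(met_id, 0.0) - value

    if gam > 0:
        for key, sign in (("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1), ("h", 1)):
            met = species[key]
            stoichiometry[met] = stoichiometry.get(met, 0.0) + sign * gam
    stoichiometry[biomass_metabolite] = stoichiometry.get(biomass_metabolite, 0.0) + 1.0

    return Reaction(
        id=reaction_id,
        name="Biomass drain",
        stoichiometry=stoichiometry,
        lower_bound=0.0,
        upper_bound=math.inf,
        subsystem="Biomass",
    )
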