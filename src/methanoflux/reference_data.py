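"""Embedded reference constants and seeded synthetic-input generators.

The constants are the worked-example values the analysis consumes:
polymerisation cost coefficients, maintenance demands, the methane uptake
bound and the measured O2/CH4 reference ratios for nitrate- and
ammonium-grown cultures.  The generators produce perturbed compositions
and reference ratios for robustness tests; they are pure functions of
(seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

from .biomass_builder import BiomassComposition, SynthesisCostTable

__all__ = [
    "PaperConstants",
    "CONSTANTS",
    "default_composition",
    "perturbed_composition",
    "perturbed_references",
]


@dataclass(frozen=True)
class PaperConstants:
    """Immutable bundle of the published reference constants."""

    gam_costs: SynthesisCostTable = field(
        default_factory=lambda: SynthesisCostTable(
            c_protein=4.324, c_dna=1.365, c_rna=0.406,
            x_protein=5.312, x_dna=0.047, x_rna=0.135,
        )
    )
    ngam: float = 8.39                   # mmol ATP / gDW / h
    methane_uptake: float = 18.46        # mmol / gDW / h
    reference_ratio_no3: float = 1.43    # mol O2 / mol CH4, nitrate-grown
    reference_ratio_nh4: float = 1.6     # mol O2 / mol CH4, ammonium-grown
    rna_fraction: float = 0.067          # g / gDW
    dna_fraction: float = 0.023
    crude_fat_fraction: float = 0.091
    glucose_fraction: float = 0.045
    phospholipid_share_of_fat: float = 0.94


CONSTANTS = PaperConstants()


def default_composition() -> BiomassComposition:
    """The measured composition as a :class:`BiomassComposition`."""
    return BiomassComposition(
        fractions={
            "rna": CONSTANTS.rna_fraction,
            "dna": CONSTANTS.dna_fraction,
            "crude_fat": CONSTANTS.crude_fat_fraction,
            "glucose": CONSTANTS.glucose_fraction,
        },
        phospholipid_share_of_fat=CONSTANTS.phospholipid_share_of_fat,
    )


def perturbed_composition(seed: int, cv: float) -> BiomassComposition:
    """A composition with each fraction scaled by an independent lognormal
    factor of unit mean and the given coefficient of variation.

    ``cv = 0`` reproduces the embedded composition exactly; equal seeds
    give identical outputs.
    """
    if cv < 0:
        raise ValueError("coefficient of variation must be >= 0")
    base = default_composition()
    if cv == 0:
        return base
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    mu = -0.5 * sigma * sigma  # unit-mean lognormal
    factors = rng.lognormal(mean=mu, sigma=sigma, size=len(base.fractions))
    fractions = {
        key: min(1.0, value * factor)
        for (key, value), factor in zip(sorted(base.fractions.items()), factors)
    }
    return replace(base, fractions=fractions)


def perturbed_references(seed: int, sd: float) -> Tuple[float, float]:
    """Noisy (nitrate, ammonium) reference ratios, truncated below at 1.0."""
    if sd < 0:
        raise ValueError("standard deviation must be >= 0")
    if sd == 0:
        return (CONSTANTS.reference_ratio_no3, CONSTANTS.reference_ratio_nh4)
    rng = np.random.default_rng(seed)
    no3 = max(1.0, float(rng.normal(CONSTANTS.reference_ratio_no3, sd)))
    nh4 = max(1.0, float(rng.normal(CONSTANTS.reference_ratio_nh4, sd)))
    return (no3, nh4)
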