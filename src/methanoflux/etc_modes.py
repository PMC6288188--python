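"""Electron-transfer-mode scenarios, parameter sweeps and reference fitting.

Three hypotheses for how the particulate methane monooxygenase receives
its electrons are encoded as constraint configurations:

* ``redox_arm``  -- the quinol pool feeds the monooxygenase (PMMOipp); the
  methanol dehydrogenase's electrons run downhill to the terminal
  oxidase.  Efficiency knob: the H+/ATP ratio of the ATP synthase.
* ``direct_coupling`` -- the methanol dehydrogenase reduces the
  monooxygenase via cytochrome c555 (PMMODCipp).  Efficiency knob: a
  ratio constraint forcing ``k`` times more flux through the quinol
  variant than the coupled variant.
* ``uphill`` -- reverse flux through the ubiquinol-cytochrome-c reductase
  lets cytochrome electrons re-enter the quinol pool at the expense of
  proton-motive force.  Efficiency knob: the (negative) reverse-flux
  lower bound.

Each scenario bounds methane uptake, leaves oxygen uptake free and runs
parsimonious FBA maximising biomass; the O2/CH4 uptake ratio is the
fitted observable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core_network import (
    set_atp_synthase_stoichiometry,
    set_mmo_availability,
    set_nitrogen_source,
)
from .lp_engine import LinearCoupling, SolveOptions, add_coupling_nh4_no2, pfba
from .model_core import FluxState, StoichiometricModel
from .reference_data import CONSTANTS

__all__ = [
    "MODES",
    "ModeConfig",
    "ScenarioResult",
    "ReferenceDataset",
    "SweepTable",
    "apply_mode",
    "o2_ch4_ratio",
    "simulate_scenario",
    "sweep_parameter",
    "fit_parameter",
    "nh4_oxidation_analysis",
    "default_grid",
]

MODES = ("redox_arm", "direct_coupling", "uphill")

_REQUIRED_REACTIONS = ("PMMOipp", "PMMODCipp", "CYOR_q8ppi", "ATPS4rpp")


@dataclass
class ModeConfig:
    """Which electron-transfer mode is active plus its efficiency knob."""

    mode: str = "redox_arm"
    protons_per_atp: float = 4.0
    pmmo_flux_ratio: float = 0.0       # k: PMMOipp flux per unit PMMODCipp
    uphill_lower_bound: float = 0.0    # <= 0, mmol/gDW/h
    nh4_no2_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.pmmo_flux_ratio < 0:
            raise ValueError("pmmo_flux_ratio k must be >= 0")
        if self.uphill_lower_bound > 0:
            raise ValueError("uphill_lower_bound must be <= 0")
        if self.nh4_no2_ratio is not None and not 0 <= self.nh4_no2_ratio <= 1:
            raise ValueError("nh4_no2_ratio must lie in [0, 1]")

    @property
    def parameter(self) -> float:
        """The efficiency parameter matching the active mode."""
        return {
            "redox_arm": self.protons_per_atp,
            "direct_coupling": self.pmmo_flux_ratio,
            "uphill": self.uphill_lower_bound,
        }[self.mode]

    def with_parameter(self, value: float) -> "ModeConfig":
        kwargs = dict(
            mode=self.mode, protons_per_atp=self.protons_per_atp,
            pmmo_flux_ratio=self.pmmo_flux_ratio,
            uphill_lower_bound=self.uphill_lower_bound,
            nh4_no2_ratio=self.nh4_no2_ratio,
        )
        key = {"redox_arm": "protons_per_atp",
               "direct_coupling": "pmmo_flux_ratio",
               "uphill": "uphill_lower_bound"}[self.mode]
        kwargs[key] = value
        return ModeConfig(**kwargs)


@dataclass(frozen=True)
class ReferenceDataset:
    """Measured quantities the sweeps are fitted against."""

    reference_ratio_no3: float = CONSTANTS.reference_ratio_no3
    reference_ratio_nh4: float = CONSTANTS.reference_ratio_nh4
    methane_uptake: float = CONSTANTS.methane_uptake

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ScenarioResult:
    growth_rate: float
    o2_ch4_ratio: float
    flux_state: FluxState
    config: ModeConfig

    @property
    def feasible(self) -> bool:
        return self.flux_state.ok


@dataclass
class SweepTable:
    """Parameter grid versus predicted ratio and growth."""

    mode: str
    parameter_name: str
    rows: List[Tuple[float, ScenarioResult]] = field(default_factory=list)

    def feasible_rows(self) -> List[Tuple[float, ScenarioResult]]:
        return [(p, r) for p, r in self.rows if r.feasible]

    def ratios(self) -> List[Tuple[float, float]]:
        return [(p, r.o2_ch4_ratio) for p, r in self.feasible_rows()]


def apply_mode(
    model: StoichiometricModel, config: ModeConfig, inplace: bool = False
) -> Tuple[StoichiometricModel, List[LinearCoupling]]:
    """Constrain a model to one electron-transfer mode.

    Returns the configured model plus the ratio couplings the solver must
    honour (couplings cannot be expressed as bounds).
    """
    for rid in _REQUIRED_REACTIONS:
        if rid not in model.reactions:
            raise KeyError(f"model lacks required reaction {rid!r}")
    out = model if inplace else model.copy()
    couplings: List[LinearCoupling] = []

    if config.mode == "redox_arm":
        dc = out.reactions["PMMODCipp"]
        dc.lower_bound = dc.upper_bound = 0.0
        out.reactions["CYOR_q8ppi"].lower_bound = 0.0
        set_atp_synthase_stoichiometry(out, config.protons_per_atp)
    elif config.mode == "direct_coupling":
        out.reactions["CYOR_q8ppi"].lower_bound = 0.0
        couplings.append(LinearCoupling(
            terms={"PMMOipp": 1.0, "PMMODCipp": -config.pmmo_flux_ratio},
            relation="=", rhs=0.0,
        ))
    else:  # uphill
        dc = out.reactions["PMMODCipp"]
        dc.lower_bound = dc.upper_bound = 0.0
        out.reactions["CYOR_q8ppi"].lower_bound = config.uphill_lower_bound

    if config.nh4_no2_ratio is not None:
        couplings.append(add_coupling_nh4_no2(config.nh4_no2_ratio))
    return out, couplings


def o2_ch4_ratio(flux_state: FluxState,
                 o2_exchange: str = "EX_o2_e",
                 ch4_exchange: str = "EX_ch4_e") -> float:
    """Moles of oxygen consumed per mole of methane consumed."""
    ch4 = flux_state.fluxes.get(ch4_exchange, 0.0)
    if ch4 >= 0:
        raise ValueError("no methane uptake in this flux state")
    return abs(flux_state.fluxes.get(o2_exchange, 0.0)) / abs(ch4)


def simulate_scenario(
    model: StoichiometricModel,
    config: ModeConfig,
    nitrogen_source: str = "no3",
    mmo: str = "pmmo",
    reference: Optional[ReferenceDataset] = None,
    options: Optional[SolveOptions] = None,
) -> ScenarioResult:
    """Run one fully configured pFBA scenario.

    Applies the baseline medium with the reference methane-uptake bound,
    the nitrogen-source rules, the MMO availability and the mode
    constraints, then maximises biomass parsimoniously.  Infeasible
    configurations are returned flagged, not raised.
    """
    reference = reference or ReferenceDataset()
    scenario = set_nitrogen_source(model, nitrogen_source)
    scenario.reactions["EX_ch4_e"].lower_bound = -reference.methane_uptake
    set_mmo_availability(scenario, mmo, inplace=True)
    scenario, couplings = apply_mode(scenario, config, inplace=True)

    state = pfba(scenario, couplings, options=options)
    if not state.ok:
        return ScenarioResult(
            growth_rate=math.nan, o2_ch4_ratio=math.nan,
            flux_state=state, config=config,
        )
    ch4 = state.fluxes.get("EX_ch4_e", 0.0)
    ratio = o2_ch4_ratio(state) if ch4 < 0 else 0.0
    return ScenarioResult(
        growth_rate=state.objective_value, o2_ch4_ratio=ratio,
        flux_state=state, config=config,
    )


def default_grid(mode: str) -> List[float]:
    """The default sweep grid for each efficiency parameter."""
    if mode == "redox_arm":
        return [1.0 + 0.5 * i for i in range(11)]          # 1 .. 6
    if mode == "direct_coupling":
        return [0.25 * i for i in range(41)]               # 0 .. 10
    if mode == "uphill":
        return [-0.1 * i for i in range(101)]              # 0 .. -10
    raise ValueError(f"unknown mode {mode!r}")


def sweep_parameter(
    model: StoichiometricModel,
    config: ModeConfig,
    grid: Sequence[float],
    nitrogen_source: str = "no3",
    mmo: str = "pmmo",
    reference: Optional[ReferenceDataset] = None,
    options: Optional[SolveOptions] = None,
) -> SweepTable:
    """Evaluate a scenario at every grid value of the mode's parameter."""
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    name = {"redox_arm": "protons_per_atp",
            "direct_coupling": "pmmo_flux_ratio",
            "uphill": "uphill_lower_bound"}[config.mode]
    table = SweepTable(mode=config.mode, parameter_name=name)
    for value in grid:
        result = simulate_scenario(
            model, config.with_parameter(value), nitrogen_source, mmo,
            reference, options,
        )
        table.rows.append((value, result))
    return table


def fit_parameter(table: SweepTable, reference_ratio: float) -> float:
    """Grid value whose predicted ratio is closest to the reference.

    Ties are broken toward the smaller parameter magnitude.
    """
    feasible = table.feasible_rows()
    if not feasible:
        raise ValueError("no feasible rows in sweep table")
    best_value = None
    best_key: Optional[Tuple[float, float]] = None
    for value, result in feasible:
        key = (abs(result.o2_ch4_ratio - reference_ratio), abs(value))
        if best_key is None or key < best_key:
            best_key = key
            best_value = value
    return best_value


def nh4_oxidation_analysis(
    model: StoichiometricModel,
    fitted_config: ModeConfig,
    grid: Sequence[float],
    reference_ratio: float = CONSTANTS.reference_ratio_nh4,
    reference: Optional[ReferenceDataset] = None,
    options: Optional[SolveOptions] = None,
) -> Tuple[float, SweepTable]:
    """Sweep the ammonium-to-nitrite co-oxidation fraction r.

    The fitted electron-transfer configuration stays fixed; for each r
    the nitrite-secretion coupling is added and the ammonium-grown
    scenario solved.  Returns the best-fitting r and the full table.
    """
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    table = SweepTable(mode=fitted_config.mode, parameter_name="nh4_no2_ratio")
    for r in grid:
        if not 0 <= r <= 1:
            raise ValueError("r values must lie in [0, 1]")
        config = ModeConfig(
            mode=fitted_config.mode,
            protons_per_atp=fitted_config.protons_per_atp,
            pmmo_flux_ratio=fitted_config.pmmo_flux_ratio,
            uphill_lower_bound=fitted_config.uphill_lower_bound,
            nh4_no2_ratio=r,
        )
        result = simulate_scenario(
            model, config, "nh4_excess", "pmmo", reference, options,
        )
        table.rows.append((r, result))
    best = fit_parameter(table, reference_ratio)
    return best, table
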