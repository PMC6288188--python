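# methanoflux

Constraint-based modelling of methanotroph energy metabolism.

The package builds a curated, elementally balanced core model of
*Methylococcus capsulatus*-style C1 metabolism, solves it with flux
balance analysis (FBA) and parsimonious FBA on a pluggable LP backend
(scipy/HiGHS by default), and fits the efficiency parameters of three
hypothesised electron-transfer modes to the particulate methane
monooxygenase — *redox arm*, *direct coupling* and *uphill electron
transfer* — against measured O2/CH4 consumption ratios, including the
coupling of ammonium co-oxidation to nitrite secretion.

## Layout

| module | contents |
| --- | --- |
| `methanoflux.model_core` | metabolites/reactions/model types, formula parsing, mass & charge balance checks, GPR evaluation, medium handling |
| `methanoflux.lp_engine` | FBA, pFBA, FVA, linear flux couplings, closed-exchange ATP assay |
| `methanoflux.core_network` | programmatic construction of the ~100-reaction core model (methane oxidation, three formaldehyde routes, four RuMP variants, CBB, TCA branch, parameterised respiratory chain, nitrogen metabolism, biomass) |
| `methanoflux.biomass_builder` | composition → biomass coefficients, growth-associated maintenance (GAM) |
| `methanoflux.etc_modes` | mode configurations, scenario simulation, parameter sweeps and fitting |
| `methanoflux.model_io` | SBML L3+FBC and COBRA-JSON read/write, round-trip exact |
| `methanoflux.reference_data` | embedded reference constants, seeded synthetic-input generators |
| `methanoflux.cli` | the `methanoflux` command |

## CLI

```sh
methanoflux build --out core.xml            # or core.json
methanoflux qc core.xml                     # balance + energy-cycle checks
methanoflux biomass                         # GAM and monomer coefficients
methanoflux simulate core.xml --mode uphill --param -2.8 --nitrogen no3
methanoflux sweep core.xml --mode direct-coupling --grid 0:10:0.25
methanoflux fit core.xml --mode direct-coupling --reference 1.43
methanoflux fit core.xml --mode uphill --param -2.8 --nh4-oxidation --reference 1.6
methanoflux synth --seed 1 --cv 0.05        # perturbed composition + references
```

All simulation commands accept `--config file.yaml` supplying defaults
for any flag; sweep/fit results are tab-separated tables.

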