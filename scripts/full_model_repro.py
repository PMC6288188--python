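#!/usr/bin/env python
"""Optional full-model reproduction against the published reconstruction.

This script needs the published genome-scale model of the methanotroph
(SBML L3+FBC or COBRA JSON), which must be downloaded separately from
https://github.com/ChristianLieven/memote-m-capsulatus — network access
is required once to fetch it; nothing here downloads automatically.

It then re-runs the headline analyses with this package's own LP engine:

* pFBA growth rates and O2/CH4 ratios on NH4 and NO3 (pMMO active,
  methane uptake bounded at 18.46 mmol/gDW/h, GLNS blocked on NH4),
* the direct-coupling ratio sweep (best k) and the uphill lower-bound
  sweep (best bound magnitude) against the NO3 reference 1.43,
* the NH4->NO2 coupling sweep against the NH4 reference 1.6.

Usage:
    python scripts/full_model_repro.py path/to/iMcBath.xml
"""

import argparse
import json
import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from methanoflux.lp_engine import LinearCoupling, add_coupling_nh4_no2, pfba
from methanoflux.model_core import apply_medium
from methanoflux.model_io import read_model
from methanoflux.reference_data import CONSTANTS

INF = math.inf

MINERALS = ("EX_so4_e", "EX_pi_e", "EX_h2o_e", "EX_h_e", "EX_fe2_e",
            "EX_fe3_e", "EX_mg2_e", "EX_ca2_e", "EX_k_e", "EX_na1_e",
            "EX_cl_e", "EX_cu2_e", "EX_zn2_e", "EX_mobd_e", "EX_cobalt2_e",
            "EX_ni2_e", "EX_mn2_e")


def configure(model, nitrogen: str):
    scenario = model.copy()
    medium = {"EX_ch4_e": CONSTANTS.methane_uptake, "EX_o2_e": INF}
    for mineral in MINERALS:
        if mineral in scenario.reactions:
            medium[mineral] = INF
    medium["EX_nh4_e" if nitrogen == "nh4" else "EX_no3_e"] = INF
    apply_medium(scenario, medium, inplace=True)
    if nitrogen == "nh4" and "GLNS" in scenario.reactions:
        scenario.reactions["GLNS"].lower_bound = 0.0
        scenario.reactions["GLNS"].upper_bound = 0.0
    if "SMMOi" in scenario.reactions:
        scenario.reactions["SMMOi"].lower_bound = 0.0
        scenario.reactions["SMMOi"].upper_bound = 0.0
    return scenario


def ratio_of(state) -> float:
    return abs(state.fluxes["EX_o2_e"]) / abs(state.fluxes["EX_ch4_e"])


def run_full_model_checks(path: str) -> dict:
    model = read_model(path).model
    results = {"n_reactions": len(model.reactions),
               "n_metabolites": len(model.metabolites)}

    for nitrogen in ("nh4", "no3"):
        scenario = configure(model, nitrogen)
        state = pfba(scenario)
        if not state.ok:
            results[f"growth_{nitrogen}"] = float("nan")
            continue
        results[f"growth_{nitrogen}"] = round(state.objective_value, 3)
        results[f"ratio_{nitrogen}"] = round(ratio_of(state), 3)

    # direct-coupling sweep on NO3
    scenario = configure(model, "no3")
    best_k, best_gap = None, INF
    for i in range(41):
        k = 0.25 * i
        coupling = LinearCoupling({"PMMOipp": 1.0, "PMMODCipp": -k}, "=", 0.0)
        state = pfba(scenario, [coupling])
        if not state.ok:
            continue
        gap = abs(ratio_of(state) - CONSTANTS.reference_ratio_no3)
        if gap < best_gap:
            best_k, best_gap = k, gap
    results["best_k"] = best_k

    # uphill sweep on NO3
    best_u, best_gap = None, INF
    for i in range(101):
        bound = -0.1 * i
        sweep_model = configure(model, "no3")
        sweep_model.reactions["PMMODCipp"].upper_bound = 0.0
        sweep_model.reactions["PMMODCipp"].lower_bound = 0.0
        sweep_model.reactions["CYOR_q8ppi"].lower_bound = bound
        state = pfba(sweep_model)
        if not state.ok:
            continue
        gap = abs(ratio_of(state) - CONSTANTS.reference_ratio_no3)
        if gap < best_gap:
            best_u, best_gap = abs(bound), gap
    results["best_uphill_magnitude"] = best_u

    # NH4 -> NO2 coupling sweep at the fitted uphill configuration
    best_r, best_gap = None, INF
    for i in range(21):
        r = 0.05 * i
        sweep_model = configure(model, "nh4")
        sweep_model.reactions["PMMODCipp"].upper_bound = 0.0
        sweep_model.reactions["PMMODCipp"].lower_bound = 0.0
        if best_u is not None:
            sweep_model.reactions["CYOR_q8ppi"].lower_bound = -best_u
        state = pfba(sweep_model, [add_coupling_nh4_no2(r)])
        if not state.ok:
            continue
        gap = abs(ratio_of(state) - CONSTANTS.reference_ratio_nh4)
        if gap < best_gap:
            best_r, best_gap = r, gap
    results["best_r"] = best_r
    return results


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("model_path", help="published model file (.xml/.json)")
    parser.add_argument("--out", default=None, help="optional JSON output")
    args = parser.parse_args(argv)
    results = run_full_model_checks(args.model_path)
    text = json.dumps(results, indent=2)
    print(text)
    if args.out:
        Path(args.out).write_text(text + "\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
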