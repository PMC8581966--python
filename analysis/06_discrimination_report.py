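#!/usr/bin/env python
"""Merge the per-technique results into the combined isomer verdict.

Reads the JSON outputs of scripts 02, 03 and 05 and assembles the
multi-technique discrimination table: spectral ranking, CCS ordering,
reaction efficiency and proton-transfer exergonicity all nominating the
same deprotomer for each ion. Writes results/discrimination.json.
"""

import json
from pathlib import Path

from ionlab.reports import assemble_discrimination_report

RESULTS = Path(__file__).resolve().parents[1] / "results"
LABELS = ("carboxylate", "phenolate")


def load(name):
    path = RESULTS / name
    if not path.exists():
        raise SystemExit(f"missing {path}: run the earlier analysis scripts first")
    return json.loads(path.read_text())


irmpd = load("irmpd_assignment.json")
mob = load("mobility.json")
kin = load("kinetics_acidity.json")

# the T3-like ion: spectral winner from the carboxylate-truth experiment
spectral = {
    "winner": irmpd["carboxylate"]["winner"],
    "candidates": {r["label"]: {"score": r["score"]}
                   for r in irmpd["carboxylate"]["ranking"]},
}
# tighter CCS nominates the carboxylate fold
assign = mob["assignments"]
ccs_by_label = {"carboxylate": assign["carboxylate-like"]["ccs_A2"],
                "phenolate": assign["phenolate-like"]["ccs_A2"]}
mobility_cmp = {
    "winner": min(ccs_by_label, key=ccs_by_label.get),
    "candidates": {k: {"ccs_A2": v} for k, v in ccs_by_label.items()},
}
# higher proton-transfer efficiency goes with the weaker acid (carboxylate ion)
phi = {"carboxylate": kin["systems"]["T3"]["phi_proton_transfer_pct"],
       "phenolate": kin["systems"]["rT3"]["phi_proton_transfer_pct"]}
kinetics_cmp = {
    "winner": max(phi, key=phi.get),
    "candidates": {k: {"phi_pct": v} for k, v in phi.items()},
}
dg = {"carboxylate": kin["proton_transfer"]["TFA->T3"]["dg_rxn_kjmol"],
      "phenolate": kin["proton_transfer"]["TFA->rT3"]["dg_rxn_kjmol"]}
acidity_cmp = {
    "winner": min(dg, key=dg.get),
    "candidates": {k: {"dg_rxn_kjmol": v} for k, v in dg.items()},
}

report = assemble_discrimination_report(
    spectral=spectral, mobility_cmp=mobility_cmp,
    kinetics_cmp=kinetics_cmp, acidity_cmp=acidity_cmp,
)
print("T3-like ion verdict:", report.results["verdict"],
      f"(confidence: {report.results['confidence']})")
print("stage votes:", report.results["votes"])
report.to_json(RESULTS / "discrimination.json")
print(f"wrote {RESULTS / 'discrimination.json'}")
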