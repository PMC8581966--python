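#!/usr/bin/env python
"""Ion-molecule kinetics and the acidity cross-check.

Simulates FT-ICR reaction traces for the two deprotonated isomers
reacting with trifluoroacetic acid (TFA) at the measured magnitudes
(k_exp = 2.53e-10 / 1.12e-10 cm^3 s^-1, proton transfer : addition
branching 22:7 and 10:4), refits the pseudo-first-order decays, converts
to second-order rate constants and ADO efficiencies, and checks the
ordering against the gas-phase acidity ladder (T3 1345, rT3 1326,
TFA 1328, acetylacetone 1409 kJ/mol). Writes results/kinetics_acidity.json.
"""

import json
from pathlib import Path

import numpy as np

from ionlab.kinetics import (
    channel_rates,
    collision_rate_ado,
    efficiency,
    fit_pseudo_first_order,
    number_density,
)
from ionlab.synthetic import GeneratorConfig, gen_kinetic_trace
from ionlab.thermochem import predict_proton_transfer

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_CM3 = number_density(1.0e-8, temperature=300.0)   # 1e-8 mbar at 300 K
TFA = {"mass_da": 114.0237, "alpha_A3": 5.25, "dipole_D": 2.28}
ION_MASS = 649.78
K_ADO_TABLE = 1.14e-9
# tabulated k_exp values are channel-specific (proton transfer); the total
# decay rate adds the addition channel in the observed 22:7 / 10:4 ratios
SYSTEMS = {
    "T3": {"k_pt": 2.53e-10, "k_exp": 2.53e-10 * 29 / 22,
           "branching": {"proton_transfer": 22 / 29, "adduct": 7 / 29}},
    "rT3": {"k_pt": 1.12e-10, "k_exp": 1.12e-10 * 14 / 10,
            "branching": {"proton_transfer": 10 / 14, "adduct": 4 / 14}},
}
ACIDITIES = {"T3": 1345.0, "rT3": 1326.0, "TFA": 1328.0, "acetylacetone": 1409.0}

k_ado = collision_rate_ado(ION_MASS, TFA["mass_da"], TFA["alpha_A3"],
                           TFA["dipole_D"], 298.0)
print(f"neutral density at 1e-8 mbar, 300 K: {N_CM3:.3e} cm^-3")
print(f"ADO capture rate for TFA: {k_ado:.3e} cm^3 s^-1 "
      f"(tabulated benchmark {K_ADO_TABLE:.2e})\n")

report = {"n_cm3": N_CM3, "k_ado_computed": k_ado, "k_ado_table": K_ADO_TABLE,
          "systems": {}}
times = np.linspace(0.0, 20.0, 11)
for label, sys_ in SYSTEMS.items():
    trace = gen_kinetic_trace(sys_["k_exp"], sys_["branching"], N_CM3, times,
                              GeneratorConfig(seed=31, noise_frac=0.02))
    kprime, stderr = fit_pseudo_first_order(trace)
    rates = channel_rates(kprime, N_CM3, trace.product_abundances(), stderr)
    # efficiencies against the tabulated capture rate: total and per channel
    phi_total = efficiency(rates.k_exp, K_ADO_TABLE)
    phi_pt = efficiency(rates.channels["proton_transfer"], K_ADO_TABLE)
    report["systems"][label] = {
        "kprime_s": rates.kprime_s, "k_exp": rates.k_exp,
        "k_exp_true": sys_["k_exp"],
        "k_proton_transfer": rates.channels["proton_transfer"],
        "k_pt_true": sys_["k_pt"],
        "phi_total_pct": round(phi_total, 1),
        "phi_proton_transfer_pct": round(phi_pt, 1),
    }
    print(f"[{label}-H]- + TFA: k' = {kprime:.4f} s^-1, "
          f"k_exp(total) = {rates.k_exp:.3e} (true {sys_['k_exp']:.2e}) cm^3 s^-1")
    print(f"  proton-transfer channel k = {rates.channels['proton_transfer']:.3e} "
          f"(true {sys_['k_pt']:.2e})")
    print(f"  efficiency: proton transfer {phi_pt:.0f}%, total {phi_total:.0f}%")

print("\nproton-transfer thermochemistry (kJ/mol):")
verdicts = {}
for donor in ("TFA", "acetylacetone"):
    for acceptor in ("T3", "rT3"):
        dg, verdict = predict_proton_transfer(ACIDITIES[donor], ACIDITIES[acceptor])
        verdicts[f"{donor}->{acceptor}"] = {"dg_rxn_kjmol": dg, "verdict": verdict}
        print(f"  {donor:14s} -> [{acceptor}-H]-: dG_rxn = {dg:+6.1f}  ({verdict})")
report["proton_transfer"] = verdicts

phis = report["systems"]
ordering_ok = (phis["T3"]["phi_proton_transfer_pct"]
               > phis["rT3"]["phi_proton_transfer_pct"])
print(f"\nefficiency ordering phi(T3) > phi(rT3): {ordering_ok} — consistent "
      "with T3 being the weaker gas-phase acid")
report["efficiency_ordering_matches_acidity"] = bool(ordering_ok)

(OUT / "kinetics_acidity.json").write_text(json.dumps(report, indent=2))
print(f"wrote {OUT / 'kinetics_acidity.json'}")
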