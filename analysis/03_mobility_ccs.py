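#!/usr/bin/env python
"""TWIMS calibration and isomer separation in drift-time space.

Builds a synthetic polyalanine-like calibrant ladder over a power-law
calibration ground truth, fits the calibration, converts the two isomers'
drift times to CCS (ground truth 209 and 215 Å², the tighter carboxylate
vs the more open phenolate), and deconvolves the overlapped two-isomer
mixture mobilogram, showing that the apparent maxima of the mixture are
displaced from the pure-compound drift times while the fitted Gaussian
centers are not. Writes results/mobility.json.
"""

import json
from pathlib import Path

from ionlab.mobility import (
    TWCalibration,
    ccs_to_drift,
    deconvolve_mobilogram,
    drift_to_ccs,
    fit_tw_calibration,
)
from ionlab.synthetic import GeneratorConfig, gen_mobility_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

TRUTH = TWCalibration(A=350.0, B=0.55)
LADDER_MZ = [232.1 + 71.04 * i for i in range(9)]   # Ala_n singly charged series
LADDER_CCS = [150.0 + 15.0 * i for i in range(9)]
ISOMER_CCS = {"carboxylate-like": 209.0, "phenolate-like": 215.0}

ds = gen_mobility_dataset(
    TRUTH, LADDER_MZ, LADDER_CCS, list(ISOMER_CCS.values()),
    GeneratorConfig(seed=21, noise_frac=0.005),
)
cal = fit_tw_calibration(ds.calibrants)
print(f"calibration fit: A = {cal.A:.2f}  B = {cal.B:.4f}  R^2 = {cal.r_squared:.6f}")

assignments = {}
for label, ccs_true in ISOMER_CCS.items():
    td = ccs_to_drift(ccs_true, 649.8, -1, TRUTH)
    ccs_fit = drift_to_ccs(td, 649.8, -1, cal)
    assignments[label] = {"drift_ms": round(td, 3), "ccs_A2": round(ccs_fit, 1),
                          "ccs_true_A2": ccs_true}
    print(f"{label:18s}: drift {td:.3f} ms -> CCS {ccs_fit:.1f} A^2 (truth {ccs_true})")

decon = deconvolve_mobilogram(ds.mobilogram, n_components=2)
centers = [round(c["center_ms"], 3) for c in decon["components"]]
apparent = [round(m, 3) for m in decon.get("apparent_maxima_ms", [])]
print(f"mixture mobilogram: fitted centers {centers} ms, "
      f"apparent maxima {apparent} ms")
print("-> overlapping isomer peaks displace the apparent maxima; the "
      "mixture fit recovers the pure-compound drift times")

report = {
    "calibration": {"A": cal.A, "B": cal.B, "r_squared": cal.r_squared},
    "assignments": assignments,
    "mixture_deconvolution": {"fitted_centers_ms": centers,
                              "apparent_maxima_ms": apparent,
                              "true_drift_ms": [round(t, 3) for t in
                                                ds.truth["analyte_drift_ms"]]},
}
(OUT / "mobility.json").write_text(json.dumps(report, indent=2))
print(f"wrote {OUT / 'mobility.json'}")
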