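#!/usr/bin/env python
"""Exact-mass bookkeeping for the deprotonated T3/rT3 isomer pair.

Computes the monoisotopic m/z of [C15H11NO4I3]- (both isomers share the
composition), the mass accuracy of the FT-ICR measurement, and the m/z of
the diagnostic fragments that distinguish the carboxylate deprotomer
(ammonia loss, HI + HN=CHCOOH loss, iodide) from the phenolate one.
Writes results/mass_bookkeeping.csv.
"""

from pathlib import Path

import pandas as pd

from ionlab.formula_mass import format_one_decimal, ion_mz, neutral_loss_mz, ppm_error

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

mz = ion_mz("C15H11NO4I3", -1)
measured = 649.78319
print(f"[T3-H]-/[rT3-H]- computed m/z : {mz:.5f}")
print(f"measured (FT-ICR)             : {measured:.5f}")
print(f"mass error                    : {ppm_error(measured, mz):+.2f} ppm")

fragments = [
    ("NH3 loss", ["NH3"]),
    ("HI + HN=CHCOOH loss", ["HI", "C2H3NO2"]),
]
rows = [{"assignment": "[M-H]- precursor", "mz": round(mz, 5),
         "mz_nominal": format_one_decimal(mz)}]
for name, losses in fragments:
    f = neutral_loss_mz(mz, losses)
    rows.append({"assignment": name, "mz": round(f, 4),
                 "mz_nominal": format_one_decimal(f)})
    print(f"{name:28s}: {f:.4f}  -> m/z {format_one_decimal(f)}")
iodide = ion_mz("I", -1)
rows.append({"assignment": "iodide anion", "mz": round(iodide, 4),
             "mz_nominal": format_one_decimal(iodide)})
print(f"{'iodide anion':28s}: {iodide:.4f}  -> m/z {format_one_decimal(iodide)}")

pd.DataFrame(rows).to_csv(OUT / "mass_bookkeeping.csv", index=False)
print(f"\nwrote {OUT / 'mass_bookkeeping.csv'}")
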