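"""Physical constants and unit conversions used across the package.

All values are CODATA-2018 unless noted. Mass spectrometry bookkeeping is
done in Da and elementary charges; collision-rate theory is evaluated in
cgs units internally (the convention in the ion-molecule kinetics
literature, where rate constants are quoted in cm^3 s^-1).
"""

# Electron mass in Da
ELECTRON_MASS_DA = 0.000548579909065

# Boltzmann constant
KB_J = 1.380649e-23        # J/K
KB_ERG = 1.380649e-16      # erg/K (cgs)

# Molar gas constant, J mol^-1 K^-1
R_GAS = 8.314462618

# Hartree -> kJ/mol
HARTREE_TO_KJMOL = 2625.4996

# Elementary charge in esu (statC), for cgs capture-rate formulas
E_ESU = 4.80320425e-10

# Unit conversions
DA_TO_G = 1.66053906660e-24    # Da -> gram
A3_TO_CM3 = 1e-24              # Angstrom^3 -> cm^3
DEBYE_TO_ESU_CM = 1e-18        # Debye -> esu*cm
MBAR_TO_PA = 100.0

# Default drift gas (N2) monoisotopic-ish mass used in TWIMS reduced-mass
# corrections; the conventional value used by calibration software.
N2_MASS_DA = 28.006
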