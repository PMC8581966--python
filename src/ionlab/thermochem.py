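"""Gas-phase acidity bookkeeping and proton-transfer reactivity.

Gas-phase acidity is the Gibbs free energy of heterolytic deprotonation
HA -> A- + H+ in vacuo:

    dG_acid = G(A-) + G(H+) - G(HA),

assembled here from externally computed component free energies (the
quantum chemistry itself is out of scope). The proton's standard Gibbs
free energy at 298.15 K is a convention-dependent constant (Sackur-Tetrode
translational partition function plus the TS term); the default -26.28
kJ/mol is exposed as configuration.

For a proton-transfer bracketing experiment [X-H]- + HA -> X + [A-]-, the
reaction free energy is the acidity difference dG_acid(HA) - dG_acid(X):
an anion abstracts a proton spontaneously only from acids stronger than
its own conjugate acid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .constants import HARTREE_TO_KJMOL

__all__ = [
    "SpeciesThermo",
    "AcidityResult",
    "gas_phase_acidity",
    "relative_free_energies",
    "predict_proton_transfer",
    "PROTON_G_KJMOL",
]

# Standard-state Gibbs free energy of the gas-phase proton at 298.15 K
PROTON_G_KJMOL = -26.28

_UNITS = {"hartree", "kj/mol"}


@dataclass(frozen=True)
class SpeciesThermo:
    """A species' Gibbs free energy with an explicit unit tag."""

    label: str
    g: float
    unit: str = "hartree"
    temperature: float = 298.15

    def __post_init__(self):
        if self.unit.lower() not in _UNITS:
            raise ValueError(f"unit must be one of {sorted(_UNITS)}, got {self.unit!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def g_kjmol(self) -> float:
        if self.unit.lower() == "hartree":
            return self.g * HARTREE_TO_KJMOL
        return self.g


@dataclass(frozen=True)
class AcidityResult:
    label: str
    dg_acid_kjmol: float
    g_neutral_kjmol: float
    g_anion_kjmol: float
    proton_g_kjmol: float
    temperature: float


def gas_phase_acidity(
    neutral: SpeciesThermo,
    anion: SpeciesThermo,
    proton_g_kjmol: float = PROTON_G_KJMOL,
) -> AcidityResult:
    """dG_acid = G(anion) + G(H+) - G(neutral), in kJ/mol."""
    if neutral.temperature != anion.temperature:
        warnings.warn(
            f"temperature mismatch: neutral at {neutral.temperature} K, "
            f"anion at {anion.temperature} K",
            stacklevel=2,
        )
    dg = anion.g_kjmol + proton_g_kjmol - neutral.g_kjmol
    return AcidityResult(
        label=neutral.label,
        dg_acid_kjmol=dg,
        g_neutral_kjmol=neutral.g_kjmol,
        g_anion_kjmol=anion.g_kjmol,
        proton_g_kjmol=proton_g_kjmol,
        temperature=neutral.temperature,
    )


def relative_free_energies(species: Sequence[SpeciesThermo]) -> List[float]:
    """Free energies relative to the most stable species (min = 0), kJ/mol."""
    if not species:
        raise ValueError("need at least one species")
    temps = {s.temperature for s in species}
    if len(temps) > 1:
        warnings.warn(f"mixed temperatures in ladder: {sorted(temps)}", stacklevel=2)
    gs = [s.g_kjmol for s in species]
    g0 = min(gs)
    return [g - g0 for g in gs]


def predict_proton_transfer(
    dg_acid_donor_kjmol: float,
    dg_acid_acceptor_kjmol: float,
    thermoneutral_band_kjmol: float = 5.0,
) -> Tuple[float, str]:
    """Reaction free energy and verdict for [X-H]- + HA -> X + [A]-.

    The donor is the neutral acid HA; the acceptor X is the conjugate acid
    of the reacting anion. dG_rxn = dG_acid(HA) - dG_acid(X); verdicts
    within ±band of zero are called ~thermoneutral (observable but slow).
    """
    dg_rxn = dg_acid_donor_kjmol - dg_acid_acceptor_kjmol
    if dg_rxn < -thermoneutral_band_kjmol:
        verdict = "exergonic"
    elif dg_rxn > thermoneutral_band_kjmol:
        verdict = "endergonic"
    else:
        verdict = "~thermoneutral"
    return dg_rxn, verdict
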