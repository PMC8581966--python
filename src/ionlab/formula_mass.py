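"""Molecular formulas, monoisotopic ion m/z, ppm errors and neutral-loss
arithmetic.

The monoisotopic atomic masses come from the NIST table bundled with
pyteomics (``pyteomics.mass.nist_mass``). Ion m/z follows the convention
for even-electron ions whose formula already includes/excludes the mobile
proton: the formula given IS the ion's elemental composition, and only the
electron mass is added or removed according to the charge,

    m/z = (sum_i n_i * m_i - z * m_e) / |z|.

So the deprotonated anion written [C15H11NO4I3]- (triiodothyronine minus a
proton) is parsed as the eleven-hydrogen composition and picks up one
electron mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Union

from pyteomics.mass import nist_mass

from .constants import ELECTRON_MASS_DA

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "IonSpec",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "neutral_loss_mz",
    "format_one_decimal",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _element_mass(symbol: str) -> float:
    try:
        return nist_mass[symbol][0][0]
    except KeyError:
        raise FormulaError(f"unknown element symbol: {symbol!r}")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with Hill-notation formatting.

    Counts are strictly positive integers; construction via
    :func:`parse_formula` or :meth:`from_counts` validates symbols against
    the isotope table.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts:
            raise FormulaError("formula must contain at least one element")
        for el, n in self.counts.items():
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {el} must be a positive integer, got {n!r}")
            _element_mass(el)  # validates the symbol
        object.__setattr__(self, "counts", dict(self.counts))

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        return cls(dict(counts))

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return sum(n * _element_mass(el) for el, n in self.counts.items())

    def merge(self, other: "MolecularFormula") -> "MolecularFormula":
        out: Dict[str, int] = dict(self.counts)
        for el, n in other.counts.items():
            out[el] = out.get(el, 0) + n
        return MolecularFormula(out)

    def hill(self) -> str:
        """Canonical Hill string: C first, then H, then alphabetical."""
        parts = []
        rest = dict(self.counts)
        for el in ("C", "H"):
            if "C" in self.counts and el in rest:
                n = rest.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(rest):
            n = rest[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string like ``"C15H11NO4I3"``.

    Raises
    ------
    FormulaError
        On empty input, tokens that are not known element symbols, or
        explicit zero counts.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}: {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        _element_mass(el)
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"zero/negative count for element {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def _as_formula(f: Union[str, MolecularFormula]) -> MolecularFormula:
    return parse_formula(f) if isinstance(f, str) else f


def monoisotopic_mass(formula: Union[str, MolecularFormula]) -> float:
    """Neutral monoisotopic mass (Da) of a formula."""
    return _as_formula(formula).monoisotopic_mass


@dataclass(frozen=True)
class IonSpec:
    """An ion: elemental composition plus signed charge in units of e."""

    formula: MolecularFormula
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("ions must have charge != 0; use monoisotopic_mass for neutrals")

    @property
    def mz(self) -> float:
        m = self.formula.monoisotopic_mass - self.charge * ELECTRON_MASS_DA
        return m / abs(self.charge)


def ion_mz(formula: Union[str, MolecularFormula], charge: int) -> float:
    """Monoisotopic m/z of an ion whose elemental composition is `formula`.

    The electron mass is subtracted `charge` times (so anions gain
    electron mass), then divided by |charge|.
    """
    return IonSpec(_as_formula(formula), charge).mz


def ppm_error(measured: float, reference: float) -> float:
    """Signed relative mass error in parts per million."""
    if reference <= 0:
        raise ValueError(f"reference m/z must be positive, got {reference}")
    return 1e6 * (measured - reference) / reference


def neutral_loss_mz(
    precursor_mz: float,
    losses: Iterable[Union[str, MolecularFormula]],
) -> float:
    """m/z after subtracting neutral-loss monoisotopic masses.

    Assumes a singly charged precursor that retains the charge, so the
    fragment m/z is just the precursor m/z minus the summed neutral masses.
    """
    if precursor_mz <= 0:
        raise ValueError("precursor m/z must be positive")
    out = precursor_mz - sum(_as_formula(f).monoisotopic_mass for f in losses)
    if out <= 0:
        raise ValueError(
            f"neutral losses exceed precursor mass (result {out:.4f} <= 0)"
        )
    return out


def format_one_decimal(mz: float) -> str:
    """Instrument-style nominal formatting of an m/z to one decimal place."""
    return f"{mz:.1f}"
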