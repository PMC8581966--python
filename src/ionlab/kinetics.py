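"""FT-ICR ion-molecule reaction kinetics.

A mass-selected ion stored at a stationary neutral pressure decays
pseudo-first-order: the parent fraction follows exp(-k' t), and k' is the
negated slope of the semilog plot ln(parent fraction) vs reaction time.
Dividing by the neutral number density n gives the second-order rate
constant k_exp = k'/n (cm^3 s^-1); with several product channels, k_exp is
partitioned by the product-abundance ratios.

The capture limit for an ion colliding with a polar neutral is computed
with average-dipole-orientation (ADO) / parametrized trajectory theory in
the Su-Chesnavich form: the Langevin rate

    k_L = 2 pi q sqrt(alpha / mu)          (cgs)

is multiplied by an enhancement factor depending on

    x = mu_D / sqrt(2 alpha kB T),

with the published two-branch fit (quadratic below x = 2, linear above).
The reaction efficiency phi = 100 * k_exp / k_ADO is the percentage of
capture collisions that lead to reaction.

Ion-gauge readings in FT-ICR cells need calibration; the conventional
anchor is the reference reaction CH4+. + CH4 -> CH5+ + CH3. with
k = 1.1e-9 cm^3 s^-1, from which a gauge correction factor follows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import stats

from .constants import (
    A3_TO_CM3,
    DA_TO_G,
    DEBYE_TO_ESU_CM,
    E_ESU,
    KB_ERG,
    KB_J,
    MBAR_TO_PA,
)

__all__ = [
    "KineticTrace",
    "GaugeCalibration",
    "ChannelRates",
    "fit_pseudo_first_order",
    "number_density",
    "gauge_factor_from_reference",
    "channel_rates",
    "langevin_rate",
    "collision_rate_ado",
    "efficiency",
    "REFERENCE_K_CH4",
]

# CH4+. + CH4 -> CH5+ + CH3. ; standard pressure-calibration anchor
REFERENCE_K_CH4 = 1.1e-9  # cm^3 s^-1

SYSTEMATIC_UNCERTAINTY = 0.30  # fractional, absolute-rate systematic


@dataclass
class KineticTrace:
    """Abundances of parent and product ions vs reaction time.

    `species` maps name -> abundance array; rows are normalised to total
    abundance 1 at each time so drifts in absolute signal cancel.
    """

    times_s: np.ndarray
    species: Dict[str, np.ndarray]
    parent: str
    neutral: str = ""

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.parent not in self.species:
            raise ValueError(f"parent {self.parent!r} missing from species")
        mat = np.vstack([np.asarray(v, dtype=float) for v in self.species.values()])
        if mat.shape[1] != self.times_s.size:
            raise ValueError("species arrays must match the time grid")
        if np.any(mat < 0):
            raise ValueError("abundances must be >= 0")
        total = mat.sum(axis=0)
        if np.any(total <= 0):
            raise ValueError("zero total abundance at some time point")
        names = list(self.species)
        mat = mat / total
        self.species = {k: mat[i] for i, k in enumerate(names)}

    @property
    def parent_fraction(self) -> np.ndarray:
        return self.species[self.parent]

    def product_abundances(self) -> Dict[str, float]:
        """Time-integrated product abundances (for branching ratios)."""
        return {
            k: float(np.trapezoid(v, self.times_s))
            for k, v in self.species.items()
            if k != self.parent
        }


def fit_pseudo_first_order(trace: KineticTrace) -> Tuple[float, float]:
    """(k' in s^-1, stderr) from the semilog parent-decay regression.

    Points with nonpositive parent fraction are excluded with a warning
    (they carry no log information); at least 3 usable points required.
    """
    frac = trace.parent_fraction
    usable = frac > 0
    if not np.all(usable):
        warnings.warn(
            f"excluding {np.count_nonzero(~usable)} point(s) with nonpositive "
            "parent fraction from the semilog fit",
            stacklevel=2,
        )
    t = trace.times_s[usable]
    y = np.log(frac[usable])
    if t.size < 3:
        raise ValueError("need at least 3 usable points for the semilog fit")
    res = stats.linregress(t, y)
    return -float(res.slope), float(res.stderr)


@dataclass(frozen=True)
class GaugeCalibration:
    """Cold-cathode gauge correction: reading -> true pressure.

    `factor` is the gauge calibration factor (from the reference reaction),
    `response` the neutral-specific ionisation response factor.
    """

    factor: float = 1.0
    response: float = 1.0
    reference_k: float = REFERENCE_K_CH4

    def __post_init__(self):
        if self.factor <= 0 or self.response <= 0:
            raise ValueError("calibration factors must be positive")


def number_density(
    pressure_reading_mbar: float,
    cal: GaugeCalibration = GaugeCalibration(),
    temperature: float = 300.0,
) -> float:
    """Neutral number density in cm^-3 from a corrected gauge reading."""
    if pressure_reading_mbar <= 0 or temperature <= 0:
        raise ValueError("pressure and temperature must be positive")
    p_pa = pressure_reading_mbar * cal.factor * cal.response * MBAR_TO_PA
    return p_pa / (KB_J * temperature) * 1e-6  # m^-3 -> cm^-3


def gauge_factor_from_reference(
    kprime_ref: float,
    n_gauge: float,
    reference_k: float = REFERENCE_K_CH4,
) -> float:
    """Gauge factor from a measured reference-reaction decay.

    If the uncorrected gauge reading implies density n_gauge but the
    measured pseudo-first-order constant is k'_ref, the true density is
    k'_ref / k_ref and the correction factor their ratio.
    """
    if min(kprime_ref, n_gauge, reference_k) <= 0:
        raise ValueError("inputs must be positive")
    return kprime_ref / (reference_k * n_gauge)


@dataclass
class ChannelRates:
    """Second-order kinetics summary for one ion + neutral system."""

    kprime_s: float
    kprime_stderr: float
    n_cm3: float
    k_exp: float                       # cm^3 s^-1
    channels: Dict[str, float]         # per-channel k, cm^3 s^-1
    k_ado: Optional[float] = None      # cm^3 s^-1
    efficiency_pct: Optional[float] = None
    systematic_frac: float = SYSTEMATIC_UNCERTAINTY

    @property
    def k_exp_uncertainty(self) -> float:
        """Combined fractional systematic (±30%) and fit uncertainty, absolute."""
        fit_frac = self.kprime_stderr / self.kprime_s if self.kprime_s > 0 else 0.0
        return self.k_exp * math.hypot(self.systematic_frac, fit_frac)


def channel_rates(
    kprime_s: float,
    n_cm3: float,
    product_abundances: Optional[Mapping[str, float]] = None,
    kprime_stderr: float = 0.0,
) -> ChannelRates:
    """k_exp = k'/n, partitioned over product channels by abundance ratio.

    Channel rate constants sum to k_exp exactly.
    """
    if n_cm3 <= 0:
        raise ValueError("number density must be positive")
    if kprime_s < 0:
        raise ValueError("k' must be >= 0")
    k_exp = kprime_s / n_cm3
    channels: Dict[str, float] = {}
    if product_abundances:
        total = float(sum(product_abundances.values()))
        if total <= 0:
            if kprime_s > 0:
                warnings.warn(
                    "nonzero parent decay but zero total product abundance; "
                    "channel partitioning skipped",
                    stacklevel=2,
                )
        else:
            channels = {k: k_exp * v / total for k, v in product_abundances.items()}
    return ChannelRates(kprime_s, kprime_stderr, n_cm3, k_exp, channels)


def _reduced_mass_g(m1_da: float, m2_da: float) -> float:
    return (m1_da * m2_da / (m1_da + m2_da)) * DA_TO_G


def langevin_rate(ion_mass_da: float, neutral_mass_da: float, alpha_A3: float) -> float:
    """Langevin capture rate k_L = 2 pi q sqrt(alpha/mu) in cm^3 s^-1."""
    if min(ion_mass_da, neutral_mass_da) <= 0:
        raise ValueError("masses must be positive")
    if alpha_A3 < 0:
        raise ValueError("polarizability must be >= 0")
    mu = _reduced_mass_g(ion_mass_da, neutral_mass_da)
    return 2.0 * math.pi * E_ESU * math.sqrt(alpha_A3 * A3_TO_CM3 / mu)


def collision_rate_ado(
    ion_mass_da: float,
    neutral_mass_da: float,
    alpha_A3: float,
    dipole_D: float,
    temperature: float = 298.0,
) -> float:
    """Su-Chesnavich parametrized capture rate constant (cm^3 s^-1).

    Reduces exactly to the Langevin rate for a nonpolar neutral
    (dipole_D = 0); returns 0 with a warning if there is no long-range
    attraction at all (alpha = dipole = 0).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if dipole_D < 0:
        raise ValueError("dipole moment must be >= 0")
    if alpha_A3 == 0 and dipole_D == 0:
        warnings.warn("no polarizability and no dipole: capture rate is 0", stacklevel=2)
        return 0.0
    if alpha_A3 == 0:
        raise ValueError("pure-dipole capture (alpha = 0) is not parametrized")
    k_l = langevin_rate(ion_mass_da, neutral_mass_da, alpha_A3)
    if dipole_D == 0:
        return k_l
    mu_d = dipole_D * DEBYE_TO_ESU_CM
    x = mu_d / math.sqrt(2.0 * alpha_A3 * A3_TO_CM3 * KB_ERG * temperature)
    if x < 2.0:
        enhancement = (x + 0.5090) ** 2 / 10.526 + 0.9754
    else:
        enhancement = 0.4767 * x + 0.6200
    return k_l * enhancement


def efficiency(k_exp: float, k_ado: float) -> float:
    """Reaction efficiency phi = 100 * k_exp / k_ado (percent)."""
    if k_ado <= 0:
        raise ValueError("k_ADO must be positive")
    if k_exp < 0:
        raise ValueError("k_exp must be >= 0")
    return 100.0 * k_exp / k_ado
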