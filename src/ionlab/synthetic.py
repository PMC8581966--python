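"""Seeded synthetic-data generators for every analysis stage.

Each generator emulates the statistical structure its analysis stage
assumes — exponential parent decay with competitive product channels,
Gaussian mobilogram peaks over a power-law calibration ground truth,
band-shaped photofragmentation probability vs photon energy, toy
geometries with known projection behaviour — and is exactly inverted by
that stage on noiseless output. Noise is multiplicative Gaussian (default
2%, the scale of ion-count fluctuations in trapped-ion experiments) plus a
small additive floor; all of it is controlled by `GeneratorConfig` and a
single integer seed, so every fixture is reproducible.

Generators return the same in-memory types the analysis readers produce
from files, and writers are provided so CLI/driver scripts can round-trip
through CSV/XYZ with no privileged path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .action_spec import FragmentationScan
from .ccs_theory import Geometry
from .kinetics import KineticTrace
from .mobility import CalibrationPoint, Mobilogram, TWCalibration, ccs_to_drift
from .theory_spectra import StickSpectrum

__all__ = [
    "GeneratorConfig",
    "Band",
    "gen_action_scans",
    "gen_kinetic_trace",
    "gen_mobility_dataset",
    "gen_toy_geometry",
    "carboxylate_template",
    "phenolate_template",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared noise/seed configuration for all generators."""

    seed: int = 0
    noise_frac: float = 0.02      # multiplicative Gaussian fraction
    noise_floor: float = 0.0      # additive noise in intensity units

    def __post_init__(self):
        if self.noise_frac < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _apply_noise(values: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    noisy = values * (1.0 + cfg.noise_frac * rng.standard_normal(values.shape))
    if cfg.noise_floor > 0:
        noisy = noisy + cfg.noise_floor * rng.standard_normal(values.shape)
    return np.clip(noisy, 0.0, None)


@dataclass(frozen=True)
class Band:
    """Gaussian fragmentation band: center (cm^-1), fwhm (cm^-1), peak
    fragment fraction in [0, 1)."""

    center: float
    fwhm: float
    peak_fraction: float

    def fraction(self, energies: np.ndarray) -> np.ndarray:
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.peak_fraction * np.exp(-0.5 * ((energies - self.center) / sigma) ** 2)


def gen_action_scans(
    bands: Sequence[Band],
    energies: np.ndarray,
    cfg: GeneratorConfig = GeneratorConfig(),
    precursor_mz: float = 649.8,
    fragment_mzs: Sequence[float] = (632.7, 448.9, 126.9),
    total_ions: float = 1.0e4,
) -> List[FragmentationScan]:
    """Fragmentation scans with band-shaped depletion.

    At each photon energy the fragment fraction is the sum of Gaussian
    bands (must stay < 1 everywhere); the precursor carries (1-f) of the
    total ion count and the fragment intensity is split evenly over the
    configured fragment m/z values. Noiseless output inverts exactly to f
    through the yield formula.
    """
    energies = np.asarray(energies, dtype=float)
    f = np.zeros_like(energies)
    for b in bands:
        f = f + b.fraction(energies)
    if np.any(f >= 1.0):
        raise ValueError("summed band fractions reach 1: depletion model invalid")
    rng = cfg.rng()
    scans = []
    for e, fi in zip(energies, f):
        i_p = total_ions * (1.0 - fi)
        frag_each = total_ions * fi / len(fragment_mzs)
        raw = np.array([i_p] + [frag_each] * len(fragment_mzs))
        noisy = _apply_noise(raw, cfg, rng)
        peaks = [(precursor_mz, noisy[0])] + [
            (mz, inten) for mz, inten in zip(fragment_mzs, noisy[1:])
        ]
        scans.append(FragmentationScan(e, np.array(peaks), precursor_mz))
    return scans


def gen_kinetic_trace(
    k_exp: float,
    branching: Dict[str, float],
    n_cm3: float,
    times_s: np.ndarray,
    cfg: GeneratorConfig = GeneratorConfig(),
    parent: str = "parent",
) -> KineticTrace:
    """Exponential parent decay with competitive product channels.

    parent(t) = exp(-k_exp * n * t); the depleted fraction is split over
    the channels by the (unit-sum) branching ratios. Noise is applied per
    species per time point and rows renormalised by the KineticTrace
    constructor.
    """
    total = sum(branching.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"branching ratios must sum to 1, got {total}")
    times_s = np.asarray(times_s, dtype=float)
    rng = cfg.rng()
    kprime = k_exp * n_cm3
    parent_frac = np.exp(-kprime * times_s)
    species = {parent: _apply_noise(parent_frac, cfg, rng)}
    for name, ratio in branching.items():
        species[name] = _apply_noise(ratio * (1.0 - parent_frac), cfg, rng)
    return KineticTrace(times_s, species, parent=parent)


@dataclass
class MobilityDataset:
    calibrants: List[CalibrationPoint]
    mobilogram: Mobilogram
    truth: dict = field(default_factory=dict)


def gen_mobility_dataset(
    cal_truth: TWCalibration,
    calibrant_mzs: Sequence[float],
    calibrant_ccs: Sequence[float],
    analyte_ccs: Sequence[float],
    cfg: GeneratorConfig = GeneratorConfig(),
    analyte_mz: float = 649.8,
    analyte_charge: int = -1,
    calibrant_charge: int = 1,
    peak_fwhm_ms: float = 0.30,
    grid_step_ms: float = 0.005,
) -> MobilityDataset:
    """Calibrant ladder plus analyte mobilogram from a power-law truth.

    Calibrant drift times come from the inverse calibration (with
    multiplicative noise on the drift time); the analyte mobilogram is a
    sum of Gaussian peaks at the inverse-mapped drift times of the true
    analyte CCS values. Noiseless output round-trips exactly.
    """
    if any(c <= 0 for c in list(calibrant_ccs) + list(analyte_ccs)):
        raise ValueError("CCS values must be positive")
    rng = cfg.rng()
    calibrants = []
    for i, (mz, ccs) in enumerate(zip(calibrant_mzs, calibrant_ccs)):
        td = ccs_to_drift(ccs, mz, calibrant_charge, cal_truth)
        td_noisy = td * (1.0 + cfg.noise_frac * rng.standard_normal())
        calibrants.append(
            CalibrationPoint(f"cal{i+1}", mz, calibrant_charge, ccs, td_noisy)
        )

    analyte_td = [
        ccs_to_drift(ccs, analyte_mz, analyte_charge, cal_truth) for ccs in analyte_ccs
    ]
    sigma = peak_fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lo = min(analyte_td) - 6 * sigma
    hi = max(analyte_td) + 6 * sigma
    grid = np.arange(lo, hi, grid_step_ms)
    intensity = np.zeros_like(grid)
    for td in analyte_td:
        intensity += np.exp(-0.5 * ((grid - td) / sigma) ** 2)
    intensity = _apply_noise(intensity, cfg, rng)
    mob = Mobilogram(grid, intensity, mz_window=(analyte_mz - 0.5, analyte_mz + 0.5))
    truth = {
        "A": cal_truth.A,
        "B": cal_truth.B,
        "edc": cal_truth.edc,
        "analyte_ccs": list(analyte_ccs),
        "analyte_drift_ms": analyte_td,
        "peak_fwhm_ms": peak_fwhm_ms,
    }
    return MobilityDataset(calibrants, mob, truth)


def gen_toy_geometry(
    kind: str,
    n_atoms: int = 10,
    spacing: float = 1.5,
    element: str = "C",
    separation: float = 2.0,
) -> Geometry:
    """Deterministic toy geometries with known projection behaviour.

    kinds:
      - "sphere_pair": two atoms `separation` apart on x
      - "chain": `n_atoms` collinear atoms at `spacing` (the extended
        variant of a fixed composition)
      - "ring": the same composition closed into a planar ring (compact
        variant; pairwise distances shrink, so PA CCS cannot exceed the
        chain's)
    """
    if kind == "sphere_pair":
        coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
        return Geometry([element, element], coords, label=f"sphere_pair_d{separation}")
    if kind == "chain":
        coords = np.array([[i * spacing, 0.0, 0.0] for i in range(n_atoms)])
        return Geometry([element] * n_atoms, coords, label=f"chain_{n_atoms}")
    if kind == "ring":
        # same composition and bond length as the chain, closed into a circle
        r = spacing / (2.0 * np.sin(np.pi / n_atoms))
        ang = 2.0 * np.pi * np.arange(n_atoms) / n_atoms
        coords = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n_atoms)])
        return Geometry([element] * n_atoms, coords, label=f"ring_{n_atoms}")
    raise ValueError(f"unknown toy-geometry kind {kind!r}")


def carboxylate_template(label: str = "carboxylate") -> StickSpectrum:
    """Template stick spectrum of a carboxylate-type deprotomer.

    Diagnostic pattern: strong asymmetric COO- stretch plus NH2 scissoring
    bands near 1600/1625 cm^-1 and no activity above 1700 cm^-1.
    """
    return StickSpectrum(
        label,
        frequencies=np.array([1130.0, 1280.0, 1440.0, 1600.0, 1625.0]),
        intensities=np.array([120.0, 180.0, 150.0, 500.0, 350.0]),
    )


def phenolate_template(label: str = "phenolate") -> StickSpectrum:
    """Template stick spectrum of a phenolate-type deprotomer.

    Diagnostic pattern: free carboxylic-acid C=O stretch near 1790 cm^-1
    and a strong phenolate C-O stretch near 1528 cm^-1.
    """
    return StickSpectrum(
        label,
        frequencies=np.array([1100.0, 1290.0, 1528.0, 1790.0]),
        intensities=np.array([100.0, 160.0, 420.0, 450.0]),
    )
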