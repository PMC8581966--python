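"""Harmonic stick spectra: frequency scaling, line broadening, Boltzmann
populations, and similarity ranking against an experimental action spectrum.

Hybrid-DFT harmonic frequencies systematically overestimate observed band
positions; a single multiplicative scale factor (here defaulting to 0.978,
appropriate for B3LYP fingerprint-region frequencies of iodinated aromatic
systems) compensates. Scaled sticks are convolved with a Gaussian or
Lorentzian lineshape — FEL action-spectroscopy bands in the fingerprint
region are typically 20-30 cm^-1 wide — and compared to experiment via
cosine similarity of max-normalised profiles on the common grid. Isomer
populations follow Boltzmann statistics over relative Gibbs free energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .action_spec import ActionSpectrum
from .constants import R_GAS

__all__ = [
    "StickSpectrum",
    "BroadenedSpectrum",
    "scale_and_broaden",
    "boltzmann_weights",
    "spectral_similarity",
    "match_and_rank",
    "DEFAULT_SCALE",
    "DEFAULT_FWHM",
]

DEFAULT_SCALE = 0.978
DEFAULT_FWHM = 25.0  # cm^-1


@dataclass
class StickSpectrum:
    """Calculated harmonic lines: (frequency cm^-1, IR intensity km/mol)."""

    label: str
    frequencies: np.ndarray
    intensities: np.ndarray
    delta_g_kjmol: Optional[float] = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frequencies.size == 0:
            raise ValueError("stick spectrum has no lines")
        if self.frequencies.shape != self.intensities.shape:
            raise ValueError("frequencies and intensities must align")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class BroadenedSpectrum:
    label: str
    grid: np.ndarray
    profile: np.ndarray
    scale: float = 1.0
    fwhm: float = DEFAULT_FWHM
    lineshape: str = "gaussian"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.profile = np.asarray(self.profile, dtype=float)
        steps = np.diff(self.grid)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("grid must be strictly increasing and uniform")
        if np.any(self.profile < 0):
            raise ValueError("profile must be >= 0")


def _gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return hwhm**2 / ((x - center) ** 2 + hwhm**2)


def scale_and_broaden(
    stick: StickSpectrum,
    scale: float = DEFAULT_SCALE,
    fwhm: float = DEFAULT_FWHM,
    lineshape: str = "gaussian",
    grid: Optional[np.ndarray] = None,
    grid_range: Tuple[float, float] = (900.0, 1900.0),
    grid_step: float = 1.0,
) -> BroadenedSpectrum:
    """Convolve a scaled stick spectrum onto a uniform wavenumber grid.

    Each line contributes intensity * lineshape(center = scale*freq, fwhm);
    line contributions are additive (the weak-absorption limit).
    """
    if not 0.5 < scale < 1.5:
        raise ValueError(f"scale factor {scale} outside the sane range (0.5, 1.5)")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    shapes = {"gaussian": _gaussian, "lorentzian": _lorentzian}
    if lineshape not in shapes:
        raise ValueError(f"lineshape must be one of {sorted(shapes)}")
    if grid is None:
        grid = np.arange(grid_range[0], grid_range[1] + 0.5 * grid_step, grid_step)
    grid = np.asarray(grid, dtype=float)
    step = float(grid[1] - grid[0])
    if step > fwhm:
        warnings.warn(
            f"grid step {step} cm^-1 exceeds fwhm {fwhm} cm^-1: bands undersampled",
            stacklevel=2,
        )
    fn = shapes[lineshape]
    profile = np.zeros_like(grid)
    for f, inten in zip(stick.frequencies, stick.intensities):
        profile += inten * fn(grid, scale * f, fwhm)
    return BroadenedSpectrum(stick.label, grid, profile, scale, fwhm, lineshape)


def boltzmann_weights(delta_g_kjmol: Sequence[float], temperature: float = 298.15) -> np.ndarray:
    """Normalized populations w_i ∝ exp(-ΔG_i / RT).

    Invariant to adding a constant to all ΔG (only differences matter).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dg = np.asarray(delta_g_kjmol, dtype=float)
    if dg.size == 0:
        raise ValueError("need at least one free energy")
    x = -(dg - dg.min()) * 1000.0 / (R_GAS * temperature)
    w = np.exp(x)
    return w / w.sum()


def _resample(spec: BroadenedSpectrum, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, spec.grid, spec.profile, left=0.0, right=0.0)


def spectral_similarity(
    a: np.ndarray, b: np.ndarray, method: str = "cosine"
) -> float:
    """Similarity of two profiles on a shared grid, in [0, 1] for cosine."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(np.dot(a, b) / (na * nb))
    if method == "pearson":
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])
    raise ValueError("method must be 'cosine' or 'pearson'")


def match_and_rank(
    experimental: ActionSpectrum,
    candidates: Sequence[BroadenedSpectrum],
    weights: Optional[Sequence[float]] = None,
    method: str = "cosine",
    include_composite: bool = False,
) -> List[Tuple[str, float]]:
    """Rank candidate isomer spectra by similarity to the experiment.

    Candidates are linearly resampled onto the part of the experimental
    grid they overlap; both sides are max-normalised so similarity is
    invariant to overall intensity scaling. With `weights` and
    `include_composite`, a population-weighted sum of the candidates is
    scored as an extra entry labelled "composite".
    """
    if not candidates:
        raise ValueError("no candidate spectra supplied")
    lo = max(c.grid[0] for c in candidates)
    hi = min(c.grid[-1] for c in candidates)
    mask = (experimental.energies >= lo) & (experimental.energies <= hi)
    if mask.sum() < 2:
        raise ValueError("no overlap between experimental grid and candidate grids")
    grid = experimental.energies[mask]
    exp = experimental.yields[mask]
    exp = exp / exp.max() if exp.max() > 0 else exp

    profiles = {}
    for c in candidates:
        p = _resample(c, grid)
        profiles[c.label] = p / p.max() if p.max() > 0 else p

    scored = [
        (label, spectral_similarity(exp, p, method)) for label, p in profiles.items()
    ]
    if include_composite:
        if weights is None:
            raise ValueError("include_composite requires population weights")
        w = np.asarray(weights, dtype=float)
        comp = sum(wi * profiles[c.label] for wi, c in zip(w, candidates))
        if comp.max() > 0:
            comp = comp / comp.max()
        scored.append(("composite", spectral_similarity(exp, comp, method)))
    return sorted(scored, key=lambda t: t[1], reverse=True)
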