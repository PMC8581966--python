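"""IRMPD action spectra from per-photon-energy fragmentation scans.

In an infrared multiple-photon dissociation (IRMPD) experiment a mass-
selected ion is irradiated at a series of photon energies; on resonance it
fragments. The photofragmentation yield at one energy is

    R = -log( I_p / (I_p + sum(I_f)) )

with I_p the integrated precursor abundance and sum(I_f) the summed
fragment abundances. Plotting R against photon energy gives the action
spectrum, a proxy for the ion's linear IR absorption spectrum.

The log base is a convention choice that differs between groups; it only
rescales R globally (R_log10 = R_ln / ln 10), so band positions are
unaffected. The base used is recorded in the spectrum provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "MzWindow",
    "FragmentationScan",
    "ActionSpectrum",
    "photofragment_yield",
    "build_action_spectrum",
    "detect_bands",
    "EmptyScanError",
    "DegenerateSpectrumError",
]

DEFAULT_WINDOW_TOL = 0.5  # m/z; unit-resolution quadrupole isolation


class EmptyScanError(ValueError):
    """No precursor and no fragment signal in the requested windows."""


class DegenerateSpectrumError(ValueError):
    """All scans share a single photon energy; no spectrum can be built."""


@dataclass(frozen=True)
class MzWindow:
    center: float
    tol: float = DEFAULT_WINDOW_TOL

    def contains(self, mz: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(mz) - self.center) <= self.tol


@dataclass
class FragmentationScan:
    """One mass spectrum acquired at a fixed photon energy.

    peaks: array-like of (m/z, integrated intensity >= 0).
    """

    energy_cm1: float
    peaks: np.ndarray
    precursor_mz: float
    irradiation_ms: float | None = None

    def __post_init__(self):
        if self.energy_cm1 <= 0:
            raise ValueError("photon energy must be positive")
        self.peaks = np.atleast_2d(np.asarray(self.peaks, dtype=float))
        if self.peaks.shape[1] != 2:
            raise ValueError("peaks must be (m/z, intensity) pairs")
        if np.any(self.peaks[:, 1] < 0):
            raise ValueError("peak intensities must be >= 0")

    def window_intensity(self, window: MzWindow) -> float:
        mask = window.contains(self.peaks[:, 0])
        return float(self.peaks[mask, 1].sum())


@dataclass
class ActionSpectrum:
    """Photon energy (cm^-1) vs photofragmentation yield R."""

    energies: np.ndarray
    yields: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.energies.ndim != 1 or self.energies.shape != self.yields.shape:
            raise ValueError("energies and yields must be 1-D arrays of equal length")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(self.yields < 0):
            raise ValueError("yields must be >= 0")

    def __len__(self) -> int:
        return self.energies.size


def _log(x: float, base: str) -> float:
    return math.log(x) if base == "e" else math.log10(x)


def photofragment_yield(
    scan: FragmentationScan,
    precursor_window: MzWindow,
    fragment_windows: Sequence[MzWindow],
    log_base: str = "e",
) -> float:
    """Yield R = -log(I_p / (I_p + sum I_f)) for one scan.

    Returns 0 when no fragment signal is present, and +inf (with a
    warning) on total precursor depletion, where R is undefined upward.
    """
    if log_base not in ("e", "10"):
        raise ValueError("log_base must be 'e' or '10'")
    i_p = scan.window_intensity(precursor_window)
    i_f = sum(scan.window_intensity(w) for w in fragment_windows)
    if i_p <= 0 and i_f <= 0:
        raise EmptyScanError(
            f"no signal in precursor or fragment windows at {scan.energy_cm1} cm^-1"
        )
    if i_p <= 0:
        warnings.warn(
            f"total precursor depletion at {scan.energy_cm1} cm^-1; R reported as +inf",
            stacklevel=2,
        )
        return math.inf
    if i_f <= 0:
        return 0.0
    return -_log(i_p / (i_p + i_f), log_base)


def build_action_spectrum(
    scans: Iterable[FragmentationScan],
    precursor_window: MzWindow,
    fragment_windows: Sequence[MzWindow],
    log_base: str = "e",
) -> ActionSpectrum:
    """One (energy, R) point per distinct photon energy, replicates averaged."""
    scans = list(scans)
    if len(scans) < 2:
        raise DegenerateSpectrumError("need at least two scans")
    by_energy: dict = {}
    for s in scans:
        by_energy.setdefault(s.energy_cm1, []).append(
            photofragment_yield(s, precursor_window, fragment_windows, log_base)
        )
    if len(by_energy) < 2:
        raise DegenerateSpectrumError("all scans share a single photon energy")
    energies = np.array(sorted(by_energy))
    yields = np.array([float(np.mean(by_energy[e])) for e in energies])
    return ActionSpectrum(
        energies,
        yields,
        provenance={
            "n_scans": len(scans),
            "log_base": log_base,
            "precursor_window": (precursor_window.center, precursor_window.tol),
        },
    )


def detect_bands(spectrum: ActionSpectrum, min_prominence: float = 0.1) -> List[float]:
    """Band centers (cm^-1) as prominence-filtered local maxima.

    `min_prominence` is a fraction of max(R). Centers are refined by
    3-point parabolic interpolation, which recovers sub-grid positions for
    approximately Gaussian bands.
    """
    if len(spectrum) < 5:
        raise ValueError("need at least 5 spectrum points to detect bands")
    y = spectrum.yields
    ymax = float(y.max())
    if ymax <= 0:
        return []
    idx, _ = find_peaks(y, prominence=min_prominence * ymax)
    centers = []
    x = spectrum.energies
    for i in idx:
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom != 0:
                # parabolic vertex offset in grid units, assumes locally uniform grid
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                step = 0.5 * (x[i + 1] - x[i - 1])
                centers.append(float(x[i] + delta * step))
                continue
        centers.append(float(x[i]))
    return sorted(centers)
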