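"""Traveling-wave ion mobility (TWIMS): power-law CCS calibration and
mobilogram deconvolution.

TWIMS drift times have no closed-form relation to collision cross section
(CCS), so CCS is obtained empirically from a calibrant ladder (commonly
polyalanine oligomers with literature CCS values in N2). The standard
protocol:

1. correct each drift time for the mass-dependent transfer delay
   (EDC delay coefficient):  t' = t_d - edc * sqrt(m/z) / 1000,
2. reduce the reference CCS for charge and reduced mass:
   CCS' = CCS * sqrt(mu) / |z|,  mu = m_ion * m_gas / (m_ion + m_gas),
3. fit the power law CCS' = A * t'^B by least squares in log-log space.

Unknown ions are then assigned CCS = A * t'^B * |z| / sqrt(mu).

Overlapping isomer peaks in a mobilogram shift each other's apparent
maxima; `deconvolve_mobilogram` fits a 1- or 2-component Gaussian mixture
to recover the underlying centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from lmfit.models import GaussianModel

from .constants import N2_MASS_DA

__all__ = [
    "CalibrationPoint",
    "TWCalibration",
    "Mobilogram",
    "fit_tw_calibration",
    "drift_to_ccs",
    "ccs_to_drift",
    "deconvolve_mobilogram",
    "DeconvolutionError",
    "DEFAULT_EDC",
]

DEFAULT_EDC = 1.41

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # fwhm = GAUSS_FWHM * sigma


class DeconvolutionError(RuntimeError):
    """Gaussian-mixture fit failed to converge."""


@dataclass(frozen=True)
class CalibrationPoint:
    name: str
    mz: float
    charge: int
    ccs_A2: float      # reference CCS in N2
    drift_time_ms: float

    def __post_init__(self):
        if min(self.mz, self.ccs_A2, self.drift_time_ms) <= 0 or self.charge == 0:
            raise ValueError(f"invalid calibration point {self.name!r}")


@dataclass
class TWCalibration:
    """CCS' = A * t'^B with EDC drift-time correction."""

    A: float
    B: float
    edc: float = DEFAULT_EDC
    gas_mass: float = N2_MASS_DA
    r_squared: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if self.A <= 0 or self.B <= 0:
            raise ValueError("calibration requires A > 0 and B > 0")

    def corrected_time(self, drift_time_ms: float, mz: float) -> float:
        return drift_time_ms - self.edc * np.sqrt(mz) / 1000.0


def _reduced_sqrt(mz: float, charge: int, gas_mass: float) -> float:
    m_ion = mz * abs(charge)
    mu = m_ion * gas_mass / (m_ion + gas_mass)
    return np.sqrt(mu)


def fit_tw_calibration(
    points: Sequence[CalibrationPoint],
    edc: float = DEFAULT_EDC,
    gas_mass: float = N2_MASS_DA,
) -> TWCalibration:
    """Least-squares power-law fit of a calibrant ladder.

    Fits ln(CCS') = ln A + B ln t' over the EDC-corrected drift times.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    t_corr, ccs_red = [], []
    for p in points:
        tc = p.drift_time_ms - edc * np.sqrt(p.mz) / 1000.0
        if tc <= 0:
            raise ValueError(f"nonpositive corrected drift time for calibrant {p.name!r}")
        t_corr.append(tc)
        ccs_red.append(p.ccs_A2 * _reduced_sqrt(p.mz, p.charge, gas_mass) / abs(p.charge))
    x = np.log(np.asarray(t_corr))
    y = np.log(np.asarray(ccs_red))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    residuals = y - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TWCalibration(
        A=float(np.exp(intercept)),
        B=float(slope),
        edc=edc,
        gas_mass=gas_mass,
        r_squared=r2,
        residuals=residuals,
    )


def drift_to_ccs(drift_time_ms: float, mz: float, charge: int, cal: TWCalibration) -> float:
    """CCS (Å²) of an ion from its drift time under a fitted calibration."""
    tc = cal.corrected_time(drift_time_ms, mz)
    if tc <= 0:
        raise ValueError(f"nonpositive corrected drift time {tc:.4f} ms")
    ccs_red = cal.A * tc**cal.B
    return float(ccs_red * abs(charge) / _reduced_sqrt(mz, charge, cal.gas_mass))


def ccs_to_drift(ccs_A2: float, mz: float, charge: int, cal: TWCalibration) -> float:
    """Inverse mapping: drift time (ms) an ion of given CCS would show."""
    if ccs_A2 <= 0:
        raise ValueError("CCS must be positive")
    ccs_red = ccs_A2 * _reduced_sqrt(mz, charge, cal.gas_mass) / abs(charge)
    tc = (ccs_red / cal.A) ** (1.0 / cal.B)
    return float(tc + cal.edc * np.sqrt(mz) / 1000.0)


@dataclass
class Mobilogram:
    """Intensity vs drift time for one extracted m/z window."""

    drift_time_ms: np.ndarray
    intensity: np.ndarray
    mz_window: tuple | None = None

    def __post_init__(self):
        self.drift_time_ms = np.asarray(self.drift_time_ms, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.drift_time_ms) <= 0):
            raise ValueError("drift-time grid must be increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


def _apparent_maxima(x: np.ndarray, y: np.ndarray) -> List[float]:
    from scipy.signal import find_peaks

    idx, _ = find_peaks(y, prominence=0.02 * y.max())
    return [float(x[i]) for i in idx]


def deconvolve_mobilogram(
    mob: Mobilogram, n_components: int = 1, share_width: bool = True
) -> dict:
    """Fit a 1- or 2-component Gaussian mixture to a mobilogram.

    Returns a dict with `components` (list of {center_ms, fwhm_ms, area},
    sorted by center) and, for n=2, `apparent_maxima_ms`: the maxima of the
    summed fitted curve, which are displaced from the true centers when the
    components overlap.

    With `share_width` (default) the two components are constrained to a
    common width: isomer peaks at one m/z share the instrument resolution,
    and the constraint removes the near-degeneracy between separation and
    width that otherwise dominates the fit of strongly overlapped pairs.
    """
    if n_components not in (1, 2):
        raise ValueError("only 1 or 2 components supported")
    x, y = mob.drift_time_ms, mob.intensity
    if np.count_nonzero(y > 0.05 * y.max()) < 10:
        raise ValueError("need at least 10 points above baseline")

    model = GaussianModel(prefix="g0_")
    for i in range(1, n_components):
        model = model + GaussianModel(prefix=f"g{i}_")
    params = model.make_params()

    # moment-based seeds; for n=2 split around the weighted mean
    mean = float(np.average(x, weights=y))
    sigma0 = max(float(np.sqrt(np.average((x - mean) ** 2, weights=y))), 2 * (x[1] - x[0]))
    if n_components == 1:
        seeds = [mean]
    else:
        seeds = [mean - 0.7 * sigma0, mean + 0.7 * sigma0]
    for i, c in enumerate(seeds):
        params[f"g{i}_center"].set(value=c, min=x[0], max=x[-1])
        params[f"g{i}_sigma"].set(value=sigma0 / n_components, min=(x[1] - x[0]) / 2)
        params[f"g{i}_amplitude"].set(value=float(np.trapezoid(y, x)) / n_components, min=0)
    if n_components == 2 and share_width:
        params["g1_sigma"].set(expr="g0_sigma")

    result = model.fit(y, params, x=x)
    if not result.success:
        raise DeconvolutionError(f"mixture fit did not converge: {result.message}")

    comps = []
    for i in range(n_components):
        sigma = result.params[f"g{i}_sigma"].value
        comps.append(
            {
                "center_ms": float(result.params[f"g{i}_center"].value),
                "fwhm_ms": float(GAUSS_FWHM * sigma),
                "area": float(result.params[f"g{i}_amplitude"].value),
            }
        )
    comps.sort(key=lambda c: c["center_ms"])
    out = {"components": comps, "redchi": float(result.redchi)}
    if n_components == 2:
        fine = np.linspace(x[0], x[-1], 4000)
        out["apparent_maxima_ms"] = _apparent_maxima(fine, result.eval(x=fine))
    return out
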