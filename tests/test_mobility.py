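"""TWIMS power-law calibration and mobilogram deconvolution."""

import numpy as np
import pytest

from ionlab.mobility import (
    CalibrationPoint,
    Mobilogram,
    TWCalibration,
    ccs_to_drift,
    deconvolve_mobilogram,
    drift_to_ccs,
    fit_tw_calibration,
)
from ionlab.synthetic import GeneratorConfig, gen_mobility_dataset

TRUTH = TWCalibration(A=350.0, B=0.55)
CAL_MZS = [232.1 + 71.04 * i for i in range(9)]  # polyalanine-like ladder
CAL_CCS = [150.0 + 15.0 * i for i in range(9)]


def ladder(noise=0.0, seed=0):
    cfg = GeneratorConfig(seed=seed, noise_frac=noise)
    return gen_mobility_dataset(TRUTH, CAL_MZS, CAL_CCS, [209.0, 215.0], cfg)


def test_two_exact_points_determine_calibration():
    pts = []
    cal = TWCalibration(A=300.0, B=0.5, edc=0.0)
    for mz, ccs in [(300.0, 180.0), (600.0, 260.0)]:
        pts.append(CalibrationPoint("p", mz, 1, ccs, ccs_to_drift(ccs, mz, 1, cal)))
    fit = fit_tw_calibration(pts, edc=0.0)
    assert fit.A == pytest.approx(300.0, abs=1e-10)
    assert fit.B == pytest.approx(0.5, abs=1e-12)


def test_noiseless_ladder_recovers_parameters_exactly():
    ds = ladder()
    fit = fit_tw_calibration(ds.calibrants)
    assert fit.A == pytest.approx(TRUTH.A, rel=1e-8)
    assert fit.B == pytest.approx(TRUTH.B, rel=1e-8)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_noisy_ladder_recovers_parameters_within_3pct():
    ds = ladder(noise=0.01, seed=11)
    fit = fit_tw_calibration(ds.calibrants)
    assert fit.A == pytest.approx(TRUTH.A, rel=0.03)
    assert fit.B == pytest.approx(TRUTH.B, rel=0.03)


def test_calibration_round_trip_identity():
    ds = ladder()
    fit = fit_tw_calibration(ds.calibrants)
    td = ccs_to_drift(209.0, 649.8, -1, TRUTH)
    assert drift_to_ccs(td, 649.8, -1, fit) == pytest.approx(209.0, abs=1e-6)


def test_ccs_monotone_in_drift_time():
    ds = ladder()
    fit = fit_tw_calibration(ds.calibrants)
    # longer drift time -> larger CCS at fixed m/z and charge
    assert drift_to_ccs(4.34, 649.8, -1, fit) > drift_to_ccs(4.18, 649.8, -1, fit)


def test_linear_limit():
    cal = TWCalibration(A=50.0, B=1.0, edc=0.0)
    c1 = drift_to_ccs(2.0, 500.0, 1, cal)
    c2 = drift_to_ccs(4.0, 500.0, 1, cal)
    assert c2 == pytest.approx(2.0 * c1, rel=1e-12)


def test_fit_requires_two_points():
    with pytest.raises(ValueError):
        fit_tw_calibration(ladder().calibrants[:1])


def test_nonpositive_corrected_time_names_point():
    pts = [CalibrationPoint("tiny", 400.0, 1, 150.0, 0.01),
           CalibrationPoint("ok", 400.0, 1, 200.0, 5.0)]
    with pytest.raises(ValueError, match="tiny"):
        fit_tw_calibration(pts, edc=1.41)


def _gaussian_mob(centers, fwhm=0.30, areas=None, grid=(3.0, 5.6, 0.005)):
    x = np.arange(*grid)
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    areas = areas or [1.0] * len(centers)
    y = np.zeros_like(x)
    for c, a in zip(centers, areas):
        y += a * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return Mobilogram(x, y)


def test_deconvolve_single_gaussian():
    res = deconvolve_mobilogram(_gaussian_mob([4.18]), 1)
    assert res["components"][0]["center_ms"] == pytest.approx(4.18, abs=0.005)
    assert res["components"][0]["fwhm_ms"] == pytest.approx(0.30, abs=0.01)


def test_deconvolve_overlapping_pair_recovers_true_centers():
    """Fitted centers stay true while the summed curve's maxima shift."""
    res = deconvolve_mobilogram(_gaussian_mob([4.18, 4.34]), 2)
    centers = [c["center_ms"] for c in res["components"]]
    assert centers[0] == pytest.approx(4.18, abs=0.01)
    assert centers[1] == pytest.approx(4.34, abs=0.01)
    # heavily overlapped equal Gaussians: apparent maxima pulled inward
    apparent = res["apparent_maxima_ms"]
    for m in apparent:
        assert 4.18 - 0.05 < m < 4.34 + 0.05
    inner = [m for m in apparent if 4.19 < m < 4.33]
    assert inner, "summed-curve maxima should deviate from the true centers"


def test_deconvolve_noisy_mixture_over_seeds():
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        mob = _gaussian_mob([4.18, 4.34])
        # generator-style multiplicative noise at SNR 20 (5% of signal)
        noisy = np.clip(
            mob.intensity * (1.0 + 0.05 * rng.standard_normal(mob.intensity.size)),
            0.0, None,
        )
        res = deconvolve_mobilogram(Mobilogram(mob.drift_time_ms, noisy), 2)
        centers = [c["center_ms"] for c in res["components"]]
        if abs(centers[0] - 4.18) < 0.03 and abs(centers[1] - 4.34) < 0.03:
            hits += 1
    assert hits >= 0.95 * n_seeds


def test_deconvolve_rejects_unsupported_component_count():
    with pytest.raises(ValueError):
        deconvolve_mobilogram(_gaussian_mob([4.2]), 3)


def test_deconvolve_needs_points_above_baseline():
    x = np.arange(0.0, 1.0, 0.1)
    y = np.zeros_like(x)
    y[5] = 1.0
    with pytest.raises(ValueError):
        deconvolve_mobilogram(Mobilogram(x, y), 1)
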