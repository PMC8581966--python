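"""Generators: determinism and exact inversion by the analysis stages."""

import numpy as np
import pytest

from ionlab.action_spec import MzWindow, build_action_spectrum
from ionlab.kinetics import fit_pseudo_first_order
from ionlab.mobility import TWCalibration, deconvolve_mobilogram, fit_tw_calibration
from ionlab.synthetic import (
    Band,
    GeneratorConfig,
    gen_action_scans,
    gen_kinetic_trace,
    gen_mobility_dataset,
    gen_toy_geometry,
)

PREC = MzWindow(649.8)
FRAGS = [MzWindow(632.7), MzWindow(448.9), MzWindow(126.9)]
ENERGIES = np.arange(1500.0, 1900.0, 5.0)


def test_same_seed_identical_scans():
    cfg = GeneratorConfig(seed=7, noise_frac=0.02)
    a = gen_action_scans([Band(1780.0, 30.0, 0.3)], ENERGIES, cfg)
    b = gen_action_scans([Band(1780.0, 30.0, 0.3)], ENERGIES, cfg)
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.peaks, sb.peaks)


def test_zero_amplitude_bands_give_zero_yield():
    cfg = GeneratorConfig(seed=0, noise_frac=0.0)
    scans = gen_action_scans([Band(1780.0, 30.0, 0.0)], ENERGIES, cfg)
    spec = build_action_spectrum(scans, PREC, FRAGS)
    assert np.all(spec.yields == 0.0)


def test_noiseless_scans_invert_to_band_truth():
    """R at the band center equals -ln(1 - peak_fraction) exactly."""
    cfg = GeneratorConfig(seed=0, noise_frac=0.0)
    scans = gen_action_scans([Band(1780.0, 30.0, 0.3)], ENERGIES, cfg)
    spec = build_action_spectrum(scans, PREC, FRAGS)
    peak_idx = np.argmax(spec.yields)
    assert spec.energies[peak_idx] == pytest.approx(1780.0, abs=5.0)
    assert spec.yields[peak_idx] == pytest.approx(-np.log(0.7), rel=1e-9)


def test_band_fraction_reaching_one_rejected():
    with pytest.raises(ValueError):
        gen_action_scans([Band(1780.0, 30.0, 0.7), Band(1785.0, 30.0, 0.5)],
                         ENERGIES, GeneratorConfig(noise_frac=0.0))


def test_kinetic_trace_closed_form_point():
    # parent fraction after 2 s at k_exp*n = 0.1222 s^-1
    cfg = GeneratorConfig(seed=0, noise_frac=0.0)
    trace = gen_kinetic_trace(2.53e-10, {"p": 1.0}, 2.414e8,
                              np.array([0.0, 2.0, 4.0]), cfg)
    assert trace.parent_fraction[1] == pytest.approx(np.exp(-2.53e-10 * 2.414e8 * 2.0),
                                                     rel=1e-9)
    assert trace.parent_fraction[1] == pytest.approx(0.885, abs=5e-3)


def test_zero_rate_parent_stays_one():
    cfg = GeneratorConfig(seed=0, noise_frac=0.0)
    trace = gen_kinetic_trace(0.0, {"p": 1.0}, 2.4e8, np.linspace(0, 10, 5), cfg)
    assert np.all(trace.parent_fraction == 1.0)


def test_branching_must_sum_to_one():
    with pytest.raises(ValueError):
        gen_kinetic_trace(1e-10, {"a": 0.5, "b": 0.4}, 1e8, np.linspace(0, 5, 4),
                          GeneratorConfig())


def test_noiseless_trace_inverts_to_true_kprime():
    cfg = GeneratorConfig(seed=0, noise_frac=0.0)
    trace = gen_kinetic_trace(2.53e-10, {"p": 22 / 29, "q": 7 / 29}, 2.414e8,
                              np.linspace(0.0, 20.0, 11), cfg)
    k, _ = fit_pseudo_first_order(trace)
    assert k == pytest.approx(2.53e-10 * 2.414e8, rel=1e-9)


def test_mobility_noiseless_round_trip_exact():
    truth = TWCalibration(A=350.0, B=0.55)
    cfg = GeneratorConfig(seed=0, noise_frac=0.0)
    ds = gen_mobility_dataset(truth, [300.0, 450.0, 600.0, 750.0],
                              [160.0, 190.0, 220.0, 250.0], [209.0], cfg)
    fit = fit_tw_calibration(ds.calibrants)
    assert fit.A == pytest.approx(350.0, rel=1e-9)
    assert fit.B == pytest.approx(0.55, rel=1e-9)


def test_mobilogram_peak_order_follows_ccs():
    """Larger CCS maps to the later mobilogram peak."""
    truth = TWCalibration(A=350.0, B=0.55)
    cfg = GeneratorConfig(seed=3, noise_frac=0.01)
    ds = gen_mobility_dataset(truth, [300.0, 500.0, 700.0],
                              [160.0, 200.0, 240.0], [209.0, 215.0], cfg)
    res = deconvolve_mobilogram(ds.mobilogram, 2)
    centers = [c["center_ms"] for c in res["components"]]
    assert centers[0] < centers[1]
    assert ds.truth["analyte_drift_ms"][0] < ds.truth["analyte_drift_ms"][1]
    assert centers[0] == pytest.approx(ds.truth["analyte_drift_ms"][0], abs=0.02)
    assert centers[1] == pytest.approx(ds.truth["analyte_drift_ms"][1], abs=0.02)


def test_single_analyte_single_peak():
    truth = TWCalibration(A=350.0, B=0.55)
    ds = gen_mobility_dataset(truth, [300.0, 600.0], [160.0, 230.0], [209.0],
                              GeneratorConfig(noise_frac=0.0))
    res = deconvolve_mobilogram(ds.mobilogram, 1)
    assert res["components"][0]["center_ms"] == pytest.approx(
        ds.truth["analyte_drift_ms"][0], abs=0.01
    )


def test_nonpositive_ccs_rejected():
    with pytest.raises(ValueError):
        gen_mobility_dataset(TWCalibration(A=350.0, B=0.55), [300.0, 600.0],
                             [160.0, 230.0], [-1.0], GeneratorConfig())


def test_toy_geometries():
    pair = gen_toy_geometry("sphere_pair", separation=0.0)
    assert np.allclose(pair.coords[0], pair.coords[1])
    chain = gen_toy_geometry("chain", n_atoms=5, spacing=1.5)
    assert np.linalg.norm(chain.coords[-1] - chain.coords[0]) == pytest.approx(6.0)
    ring = gen_toy_geometry("ring", n_atoms=5, spacing=1.5)
    # ring preserves the bond length of the chain variant
    d = np.linalg.norm(ring.coords[1] - ring.coords[0])
    assert d == pytest.approx(1.5, rel=1e-9)
    with pytest.raises(ValueError):
        gen_toy_geometry("helix")
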