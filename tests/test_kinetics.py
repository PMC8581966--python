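"""Pseudo-first-order fits, pressure calibration, branching, ADO rates."""

import math

import numpy as np
import pytest

from ionlab.constants import A3_TO_CM3, DA_TO_G, E_ESU
from ionlab.kinetics import (
    GaugeCalibration,
    KineticTrace,
    channel_rates,
    collision_rate_ado,
    efficiency,
    fit_pseudo_first_order,
    gauge_factor_from_reference,
    langevin_rate,
    number_density,
)
from ionlab.synthetic import GeneratorConfig, gen_kinetic_trace


def exponential_trace(kprime=0.5, n_points=6, t_max=5.0):
    t = np.linspace(0.0, t_max, n_points)
    parent = np.exp(-kprime * t)
    return KineticTrace(t, {"parent": parent, "product": 1 - parent}, parent="parent")


def test_exact_exponential_recovered():
    k, stderr = fit_pseudo_first_order(exponential_trace(0.5))
    assert k == pytest.approx(0.5, abs=1e-10)
    assert stderr == pytest.approx(0.0, abs=1e-9)


def test_constant_parent_gives_zero_rate():
    t = np.linspace(0.0, 5.0, 5)
    trace = KineticTrace(t, {"parent": np.ones(5)}, parent="parent")
    k, _ = fit_pseudo_first_order(trace)
    assert k == pytest.approx(0.0, abs=1e-12)


def test_noisy_recovery_median_within_5pct():
    errs = []
    for seed in range(50):
        cfg = GeneratorConfig(seed=seed, noise_frac=0.02)
        trace = gen_kinetic_trace(0.5, {"p": 1.0}, 1.0, np.linspace(0.0, 5.0, 10), cfg)
        k, _ = fit_pseudo_first_order(trace)
        errs.append(abs(k - 0.5) / 0.5)
    assert np.median(errs) < 0.05


def test_nonpositive_fraction_points_excluded_with_warning():
    t = np.linspace(0.0, 5.0, 6)
    parent = np.exp(-0.5 * t)
    product = 1 - parent
    parent[-1] = 0.0
    product[-1] = 1.0
    trace = KineticTrace(t, {"parent": parent, "product": product}, parent="parent")
    with pytest.warns(UserWarning, match="excluding"):
        k, _ = fit_pseudo_first_order(trace)
    assert k == pytest.approx(0.5, abs=1e-9)


def test_too_few_points_rejected():
    t = np.array([0.0, 1.0, 2.0])
    trace = KineticTrace(t, {"parent": np.array([1.0, 0.5, 0.0]),
                             "p": np.array([0.0, 0.5, 1.0])}, parent="parent")
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError):
            fit_pseudo_first_order(trace)


def test_number_density_ideal_gas():
    # 1e-8 mbar at 300 K: P/(kB T) = 2.414e8 cm^-3
    n = number_density(1.0e-8, GaugeCalibration(), 300.0)
    assert n == pytest.approx(2.414e8, rel=1e-3)


def test_number_density_linearity_in_factor():
    base = number_density(1.0e-8, GaugeCalibration(factor=1.0), 300.0)
    assert number_density(1.0e-8, GaugeCalibration(factor=2.0), 300.0) == pytest.approx(
        2.0 * base, rel=1e-12
    )


def test_gauge_factor_from_reference_reaction():
    # true density = k'_ref / k_ref; factor is its ratio to the gauge value
    n_gauge = 2.414e8
    kprime_ref = 1.1e-9 * n_gauge * 1.3
    assert gauge_factor_from_reference(kprime_ref, n_gauge) == pytest.approx(1.3)


def test_channel_rates_magnitude_and_conservation():
    rates = channel_rates(0.0611, 2.414e8, {"proton_transfer": 22.0, "adduct": 7.0})
    assert rates.k_exp == pytest.approx(2.53e-10, rel=0.01)
    assert sum(rates.channels.values()) == pytest.approx(rates.k_exp, rel=1e-12)
    ratio = rates.channels["proton_transfer"] / rates.channels["adduct"]
    assert ratio == pytest.approx(22.0 / 7.0, rel=1e-12)


def test_single_channel_takes_all():
    rates = channel_rates(0.05, 1e8, {"only": 5.0})
    assert rates.channels["only"] == pytest.approx(rates.k_exp, rel=1e-12)


def test_zero_products_with_decay_warns():
    with pytest.warns(UserWarning, match="zero total product"):
        channel_rates(0.05, 1e8, {"a": 0.0})


def test_langevin_closed_form_oracle():
    """Independent cgs evaluation of k_L = 2 pi q sqrt(alpha/mu)."""
    m_ion, m_n, alpha = 16.031, 16.031, 2.59  # CH4+. + CH4
    mu_g = (m_ion * m_n / (m_ion + m_n)) * DA_TO_G
    expected = 2 * math.pi * E_ESU * math.sqrt(alpha * A3_TO_CM3 / mu_g)
    assert langevin_rate(m_ion, m_n, alpha) == pytest.approx(expected, rel=1e-12)
    # magnitude sanity: capture limit sits near the 1.1e-9 cm^3/s benchmark
    assert expected == pytest.approx(1.1e-9, rel=0.25)


def test_ado_reduces_to_langevin_for_nonpolar():
    k = collision_rate_ado(649.78, 114.02, 5.25, 0.0, 298.0)
    assert k == pytest.approx(langevin_rate(649.78, 114.02, 5.25), rel=1e-12)


def test_ado_enhancement_bounds_and_temperature_trend():
    kl = langevin_rate(649.78, 114.02, 5.25)
    k_cold = collision_rate_ado(649.78, 114.02, 5.25, 2.28, 200.0)
    k_warm = collision_rate_ado(649.78, 114.02, 5.25, 2.28, 400.0)
    assert k_cold > k_warm > kl


def test_ado_tfa_magnitude():
    """TFA + [T3-H]-: capture rate near the 1.14e-9 cm^3/s benchmark."""
    k = collision_rate_ado(649.78, 114.0237, 5.25, 2.28, 298.0)
    assert k == pytest.approx(1.14e-9, rel=0.10)


def test_ado_no_attraction_returns_zero_with_warning():
    with pytest.warns(UserWarning, match="capture"):
        assert collision_rate_ado(100.0, 50.0, 0.0, 0.0) == 0.0


@pytest.mark.parametrize(
    "k_exp,k_ado,expected",
    [(2.53e-10, 1.14e-9, 22), (1.12e-10, 1.14e-9, 10), (1.14e-9, 1.14e-9, 100)],
)
def test_efficiency_rounding_layer(k_exp, k_ado, expected):
    assert round(efficiency(k_exp, k_ado)) == expected


def test_efficiency_requires_positive_k_ado():
    with pytest.raises(ValueError):
        efficiency(1e-10, 0.0)


def test_trace_rows_normalised():
    t = np.linspace(0.0, 2.0, 4)
    trace = KineticTrace(
        t, {"parent": np.full(4, 300.0), "p": np.full(4, 100.0)}, parent="parent"
    )
    assert trace.parent_fraction == pytest.approx(np.full(4, 0.75))
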