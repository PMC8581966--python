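"""Stick-spectrum broadening, Boltzmann populations and isomer ranking."""

import numpy as np
import pytest

from ionlab.action_spec import ActionSpectrum
from ionlab.synthetic import carboxylate_template, phenolate_template
from ionlab.theory_spectra import (
    BroadenedSpectrum,
    StickSpectrum,
    boltzmann_weights,
    match_and_rank,
    scale_and_broaden,
    spectral_similarity,
)


def test_scale_factor_moves_line_center():
    stick = StickSpectrum("x", np.array([1000.0]), np.array([100.0]))
    spec = scale_and_broaden(stick, scale=0.978, fwhm=10.0,
                             grid_range=(900.0, 1100.0), grid_step=0.1)
    assert spec.grid[np.argmax(spec.profile)] == pytest.approx(978.0, abs=0.1)


def test_unit_scale_is_identity_on_center():
    stick = StickSpectrum("x", np.array([1000.0]), np.array([1.0]))
    spec = scale_and_broaden(stick, scale=1.0, fwhm=5.0,
                             grid_range=(950.0, 1050.0), grid_step=0.05)
    assert spec.grid[np.argmax(spec.profile)] == pytest.approx(1000.0, abs=0.05)


def test_two_equal_lines_give_equal_maxima():
    stick = StickSpectrum("x", np.array([1600.0, 1780.0]), np.array([1.0, 1.0]))
    spec = scale_and_broaden(stick, scale=1.0, fwhm=25.0,
                             grid_range=(1500.0, 1900.0), grid_step=0.1)
    near_a = spec.profile[np.abs(spec.grid - 1600.0) < 1.0].max()
    near_b = spec.profile[np.abs(spec.grid - 1780.0) < 1.0].max()
    assert near_a == pytest.approx(near_b, rel=0.01)
    peak_a = spec.grid[np.abs(spec.grid - 1600.0) < 20][
        np.argmax(spec.profile[np.abs(spec.grid - 1600.0) < 20])
    ]
    assert peak_a == pytest.approx(1600.0, abs=0.5)


def test_undersampling_warns():
    stick = StickSpectrum("x", np.array([1000.0]), np.array([1.0]))
    with pytest.warns(UserWarning, match="undersampled"):
        scale_and_broaden(stick, fwhm=2.0, grid_step=5.0, grid_range=(900.0, 1100.0))


def test_scale_out_of_range_rejected():
    stick = StickSpectrum("x", np.array([1000.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        scale_and_broaden(stick, scale=0.3)


def test_lorentzian_has_heavier_tails():
    stick = StickSpectrum("x", np.array([1000.0]), np.array([1.0]))
    g = scale_and_broaden(stick, scale=1.0, fwhm=20.0, lineshape="gaussian",
                          grid_range=(800.0, 1200.0), grid_step=0.5)
    l = scale_and_broaden(stick, scale=1.0, fwhm=20.0, lineshape="lorentzian",
                          grid_range=(800.0, 1200.0), grid_step=0.5)
    at_tail = np.abs(g.grid - 1100.0) < 0.25
    assert l.profile[at_tail] > g.profile[at_tail]


def test_boltzmann_equal_energies():
    w = boltzmann_weights([0.0, 0.0], 298.15)
    assert w == pytest.approx([0.5, 0.5])


@pytest.mark.parametrize("dg,expected", [(24.2, 5.7e-5), (26.2, 2.5e-5)])
def test_boltzmann_high_lying_isomer_weights(dg, expected):
    # closed form exp(-dG*1000/(R*T)) for the two-state case
    w = boltzmann_weights([0.0, dg], 298.15)
    ref = np.exp(-dg * 1000 / (8.314462618 * 298.15))
    assert w[1] == pytest.approx(ref / (1 + ref), rel=1e-9)
    assert w[1] == pytest.approx(expected, rel=0.05)


def test_boltzmann_offset_invariance_and_normalisation():
    a = boltzmann_weights([0.0, 5.0, 12.0])
    b = boltzmann_weights([100.0, 105.0, 112.0])
    assert a == pytest.approx(b, rel=1e-12)
    assert abs(a.sum() - 1.0) < 1e-12
    assert np.all(np.diff(a) <= 0)  # lower dG never gets lower weight


def test_boltzmann_rejects_bad_temperature():
    with pytest.raises(ValueError):
        boltzmann_weights([0.0], -10.0)


def _as_action(spec: BroadenedSpectrum) -> ActionSpectrum:
    return ActionSpectrum(spec.grid, spec.profile)


def test_identical_candidate_scores_one():
    cand = scale_and_broaden(carboxylate_template(), grid_range=(1000.0, 1900.0))
    ranked = match_and_rank(_as_action(cand), [cand])
    assert ranked[0] == ("carboxylate", pytest.approx(1.0, abs=1e-9))


def test_disjoint_bands_score_near_zero():
    a = scale_and_broaden(StickSpectrum("a", np.array([1600.0]), np.array([1.0])),
                          scale=1.0, fwhm=25.0, grid_range=(1400.0, 1900.0))
    b = scale_and_broaden(StickSpectrum("b", np.array([1780.0]), np.array([1.0])),
                          scale=1.0, fwhm=25.0, grid_range=(1400.0, 1900.0))
    ranked = match_and_rank(_as_action(a), [b])
    assert ranked[0][1] < 0.05


def test_similarity_invariant_to_intensity_rescaling():
    exp = scale_and_broaden(phenolate_template(), grid_range=(1000.0, 1900.0))
    cand_scaled = BroadenedSpectrum("phenolate", exp.grid, exp.profile * 37.0)
    ranked = match_and_rank(_as_action(exp), [cand_scaled])
    assert ranked[0][1] == pytest.approx(1.0, abs=1e-9)


def test_noisy_experiment_ranks_true_candidate_first():
    rng = np.random.default_rng(7)
    truth = scale_and_broaden(carboxylate_template(), grid_range=(1000.0, 1900.0))
    noisy = np.clip(truth.profile + 0.05 * truth.profile.max()
                    * rng.standard_normal(truth.profile.size), 0, None)
    exp = ActionSpectrum(truth.grid, noisy)
    cands = [scale_and_broaden(carboxylate_template(), grid_range=(1000.0, 1900.0)),
             scale_and_broaden(phenolate_template(), grid_range=(1000.0, 1900.0))]
    ranked = match_and_rank(exp, cands)
    assert ranked[0][0] == "carboxylate"


def test_composite_candidate_included():
    cands = [scale_and_broaden(carboxylate_template(), grid_range=(1000.0, 1900.0)),
             scale_and_broaden(phenolate_template(), grid_range=(1000.0, 1900.0))]
    exp = _as_action(cands[0])
    ranked = match_and_rank(exp, cands, weights=[0.9, 0.1], include_composite=True)
    labels = [l for l, _ in ranked]
    assert "composite" in labels


def test_empty_candidates_rejected():
    exp = _as_action(scale_and_broaden(carboxylate_template()))
    with pytest.raises(ValueError):
        match_and_rank(exp, [])
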