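# Methods

This note records the models implemented in ionlab, the defaults that
matter, the numerical choices, and what the synthetic benchmarks do and
do not demonstrate.

## Exact-mass bookkeeping

Monoisotopic atomic masses come from the NIST table shipped with
pyteomics. Ion m/z treats the supplied formula as the ion's full
elemental composition and adjusts only for electrons:
m/z = (Σ nᵢmᵢ − z·mₑ)/|z| with mₑ = 5.48580×10⁻⁴ Da. This is the right
convention for deprotomers written as [M−H]⁻ compositions; adduct
arithmetic beyond ±H is out of scope. Neutral-loss arithmetic assumes a
singly charged precursor that retains the charge. Computed fragment
values are reported as computed and rounded only at the formatting
layer; nominal instrument printouts can differ by ±0.1 at one decimal
(e.g. the ammonia-loss fragment computes to 632.756 → "632.8" while
unit-resolution instruments commonly report 632.7), and no attempt is
made to force agreement.

## IRMPD action spectra

Yield per scan: R = −log[I_p/(I_p + ΣI_f)] over configured precursor and
fragment m/z windows (default ±0.5, unit-resolution isolation). The log
base is a community convention with no physical content (it rescales R
globally); natural log is the default and the base is stored in the
spectrum provenance. R = 0 when no fragment signal is present; total
precursor depletion returns +inf with a warning since R is then
unbounded. Replicate energies are averaged; band centers are local
maxima above a prominence threshold (fraction of max R, default 0.1)
refined by 3-point parabolic interpolation, which is exact for a
parabola and recovers Gaussian centers to a small fraction of the grid
step when bands are resolved. No laser-power normalization is applied by
default (a per-energy power column can be supplied).

## Theory spectra and isomer ranking

Harmonic frequencies are scaled by a single factor (default 0.978,
appropriate for hybrid-DFT fingerprint frequencies of halogenated
aromatics) and convolved with Gaussian (default) or Lorentzian
lineshapes, FWHM default 25 cm⁻¹ — typical FEL action-spectroscopy
bandwidth. Similarity to experiment is the cosine of max-normalised
profiles after linear resampling onto the overlap of the experimental
grid; it is invariant to overall intensity scaling on either side
(action-spectroscopy intensities are only semi-quantitative). Pearson
correlation is available as an alternative. Whether a plotted theory
spectrum should be a single conformer or a Boltzmann-weighted composite
is experiment-dependent, so both are scored (the composite under the
label "composite"). Boltzmann weights use wᵢ ∝ exp(−ΔGᵢ/RT) and are
invariant to a constant shift of the free energies.

## TWIMS calibration

The standard power-law protocol for traveling-wave mobility: corrected
drift time t′ = t_d − EDC·√(m/z)/1000 (EDC delay coefficient, default
1.41, a required configuration value rather than a constant), reduced
CCS′ = CCS·√μ/|z| with μ the ion–gas reduced mass (drift gas N₂,
28.006 Da), then a least-squares line in ln CCS′ vs ln t′ gives
CCS′ = A·t′^B. Calibrant reference CCS values are user-supplied tables,
not bundled constants. On noiseless synthetic ladders the round trip is
exact to numerical precision; experimental CCS values from uncited
calibrant sets can only be compared as orderings, not re-derived.

Mixture mobilograms are fitted as 1- or 2-component Gaussian mixtures
(lmfit, moment-based seeds). For two components the widths are tied by
default: isomer peaks of the same m/z share the instrument resolution,
and the constraint removes the near-degeneracy between separation and
width that otherwise dominates strongly overlapped fits. The fit reports
both the fitted centers and the apparent maxima of the summed curve —
for overlapped pairs the apparent maxima are displaced inward/outward
from the true centers, which is why mixture drift times need not match
pure-compound ones.

## Projection-approximation CCS

CCS is the projected area of the union of hard spheres (atomic collision
radius + probe radius, editable YAML; N₂ probe 1.0 Å, halogen radii at
van-der-Waals scale), averaged over uniformly random orientations
(quaternion sampling via scipy Rotation). Within each orientation the
union area is estimated by Monte-Carlo rejection sampling of the
bounding box; the reported standard error is the per-orientation spread
over √N and folds in both orientation and sampling variance, scaling as
1/√(N_orient·N_samples). A deliberately independent brute-force path
(`grid_projection_ccs`) rasterises each projection on a fine fixed grid
(default 0.01 Å) and serves as the oracle in tests; for a two-sphere
system the estimators agree with the closed-form orientation-averaged
union area (37.566 Å² for r = 3 Å disks at separation 2 Å). The
projection approximation ignores multiple scattering and long-range
ion–quadrupole physics, so absolute values for real ions are systematic
underestimates; within the package it is used for orderings (extended
vs compact geometries) and method validation, not to reproduce
trajectory-method values.

## Kinetics

k′ is the negated slope of the unweighted least-squares line through
ln(parent fraction) vs time — the semilog-plot convention; a weighted
variant is available. Points with nonpositive parent fraction carry no
log information and are excluded with a warning. Number density is ideal
gas, n = P/(k_BT), with a gauge calibration factor anchorable to the
CH₄⁺• + CH₄ reference reaction (k = 1.1×10⁻⁹ cm³ s⁻¹) and per-neutral
response factors. k_exp = k′/n; with competitive channels, k_exp is
partitioned by product-abundance ratios (time-integrated abundances), so
channel rate constants sum to k_exp exactly.

Capture rates use the Su–Chesnavich parametrization of trajectory
theory: k_L = 2πq√(α/μ) in cgs, multiplied by an enhancement factor in
x = μ_D/√(2αk_BT) — quadratic branch (x + 0.509)²/10.526 + 0.9754 below
x = 2, linear branch 0.4767x + 0.62 above. The neutral's polarizability
and dipole are configuration inputs; for trifluoroacetic acid the
defaults α = 5.25 Å³, μ_D = 2.28 D give k_ADO = 1.24×10⁻⁹ cm³ s⁻¹ at
298 K, within 10% of the 1.14×10⁻⁹ benchmark for the same system — the
difference is within the spread of literature α/μ_D choices. Efficiency
ϕ = 100·k_exp/k_ADO is kept at full precision and rounded to integers
only at the report layer. Rate-constant uncertainty combines the ±30%
systematic typical of FT-ICR pressure calibration with the fit standard
error in quadrature. Because the tabulated k_exp convention for
multi-channel systems is ambiguous (channel-specific vs total), the
report layer exposes both the per-channel and the total efficiency.

## Thermochemistry

ΔG_acid = G(anion) + G(H⁺) − G(neutral) with hartree → kJ/mol conversion
2625.4996 and an explicit unit tag on every species. The proton's
standard Gibbs free energy is convention-dependent; the default
−26.28 kJ/mol at 298.15 K (Sackur–Tetrode translational entropy) is
configuration, not a constant. Proton-transfer prediction for
[X−H]⁻ + HA → X + [A]⁻ uses ΔG_rxn = ΔG_acid(HA) − ΔG_acid(X) with a
±5 kJ/mol band around zero called "~thermoneutral" — reactions in that
band (e.g. TFA with the phenolate isomer, +2 kJ/mol) are expected to be
slow but observable, which matches the low-but-nonzero efficiency seen
for such systems.

## Synthetic data

The generators produce exactly the structures the analysis stages
assume: band-shaped fragment fractions f(E) (summed Gaussians, rejected
if they reach 1) whose noiseless yield spectra invert to −ln(1−f)
exactly; exponential parent decay with unit-sum branching; calibrant
ladders and analyte mobilograms built through the inverse calibration so
noiseless round trips are exact; and deterministic toy geometries
(sphere pairs, chains, rings of identical composition) with known
projection orderings. Noise is multiplicative Gaussian, default 2% — the
scale of ion-count fluctuation in trapped-ion experiments — plus an
optional additive floor; all randomness flows through one integer seed
(numpy PCG64), so fixtures are bit-reproducible. Default study
magnitudes mirror the measured systems: k_exp ≈ 2.5×10⁻¹⁰ cm³ s⁻¹ at
n ≈ 2.4×10⁸ cm⁻³ (1×10⁻⁸ mbar, 300 K), reaction times to 20 s, 9-point
calibrant ladders over A = 350, B = 0.55, analyte CCS 209/215 Ų,
mobilogram FWHM 0.30 ms, two-band IR truths in the fingerprint region.

What passing synthetic benchmarks shows: the estimators are unbiased and
invert their own forward models at realistic noise, and the
discrimination logic is self-consistent. What it does not show:
robustness to structured experimental artifacts — multi-photon
saturation of IRMPD yields, drift of FEL power across a scan,
space-charge effects on kinetics, non-Gaussian mobilogram tails, or
calibrant-set bias in TWIMS CCS — none of which the noise model
emulates.

## Problem sizes

Defaults were chosen so every stage runs interactively on one core:
Monte-Carlo CCS at 300 orientations × 4000 samples (SE ≈ 0.5% for
~10-atom systems; 3000 orientations for the analytic benchmark), grid
oracle at 0.01 Å over ≤ 300 orientations, 100-seed calibration and
50-seed kinetics recovery ensembles, and 200-trial assignment
benchmarks. The whole test suite runs in well under a minute.
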