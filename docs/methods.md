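# Methods

This note documents the models, conventions, defaults and numerical
choices behind `qprm`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Spin physics and unit conventions

The probe is an NV ensemble described by `ProbeModel`: zero-field
splitting D (Hz, default 2.87 GHz), effective g-factor g_NV (2.0028),
transverse rate Γ₂ (rad s⁻¹), probe depth h (m) and optical
spin-relaxation contrast c. All spectral quantities are **angular**
frequencies (rad s⁻¹); gyromagnetic ratios are γ = 2π·g·μ_B/h in
rad s⁻¹ G⁻¹ with μ_B/h = 1.399624604 MHz/G; magnetic fields are in gauss
at every API surface. One convention has to be imposed because the target
spectrum mixes 2πD with γB terms.

Only the NV |0⟩→|−1⟩ branch and the target |−½⟩→|+½⟩ branch are used for
resonance matching — a single microwave-selected NV orientation below the
ground-state anti-crossing at 1024 G. The crossing condition
D = (g_NV + g_t)(μ_B/h)B gives 512.0 G for a free electron (g = 2.0023)
and 488.0 G for hexaaqua-Cu²⁺; the latter is commonly quoted as 487 G,
a ≤0.3% difference attributable to rounding of the inputs.

Γ₂ is taken as 2π × (ODMR linewidth in Hz): a 4 MHz inhomogeneously
broadened line gives 2.51×10⁷ rad s⁻¹. Conflating the inhomogeneous ODMR
width with the homogeneous filter width is an approximation, but since
Γ₂ ≪ R for aqueous targets (ratio ≈ 0.014) the measured spectrum is the
bath spectral density to better than 2% in fitted width — the package
verifies this by fitting the closed form to data generated by explicit
numerical convolution of the filter with a Lorentzian bath
(`convolved_rate`).

Because the fit is parametrised internally by (amplitude, field
half-width, B_res), the reported g and B_res satisfy
g = hD/(μ_B·B_res) − g_NV exactly, and a noise-free closed-form spectrum
is recovered exactly (to optimiser precision). Γ₂ is never fitted: only
Γ₂+R enters the lineshape, so fitting both would be degenerate.

## Concentration estimator and the coupling-depth relation

The on-resonance target rate maps to concentration through

    C = K · Γ₁(B_res) · h³ · (Γ₂+R),   K = 4.35×10¹⁰,

with h in metres and rates in rad s⁻¹ (Γ₁ itself in s⁻¹). The printed
form of this estimator carries an ambiguous (Γ₂+R)²/(Γ₂+R) factor; the
algebraically simplified single factor is implemented. Equating the
estimator's inversion with the Lorentzian on-resonance value b²/(2(Γ₂+R))
yields the consistency relation **b² = 2C/(K·h³)**, used both by the
simulator (to scale couplings with local concentration) and by the fit
(to convert a fitted b² into a probe depth when C is known). The relation
is internally exact — concentration → rate → concentration round-trips to
machine precision — but the absolute constant K is validated to order of
magnitude only: with the published rates and depth it reproduces a
100 mM input within a factor ≈2. Absolute h estimates are therefore
convention-dependent and flagged as such in the results object.

Quantification treats the sensing voxel as lateral ROI area × an
effective 10 nm sensing depth (the dipolar-coupling falloff above a
shallow probe); the default 1.6×1.6×0.01 µm³ voxel has volume
0.0256 µm³ = 25.6 aL (often rounded to 0.025 µm³ / 25 aL). The detection
limit is the concentration whose expected rate equals the rate
uncertainty σ_Γ.

## The synthetic-data generator

The generator is the package's study design: every pipeline input is a
pure function of (config, seed), bit-identical across runs, and annotated
with its ground truth so fits are scored as parameter recovery.

Per pixel, the true rate is Γ₁ = Γ_base + Γ_intrinsic(B) + Γ_target(B):

* Γ_base = 1/730 µs, the observed off-resonance background of a shallow
  implanted ensemble (this background already contains non-resonant
  surface contributions; it is field-independent in the model).
* The intrinsic (surface-spin) bath defaults to g = 2.0077 — placing its
  resonance at 511.3 G — with Γ₂+R = 60.4×10⁶ rad s⁻¹ and an on-resonance
  amplitude of 3.0×10³ s⁻¹. The amplitude is not a published number; it
  was chosen once to match the scale of published calibration spectra
  (a few 10³ s⁻¹) and is configurable.
* The target bath (hexaaqua-Cu²⁺ by default: g∥ = 2.400, g⊥ = 2.099,
  motional average ⟨g⟩ = 2.199, R = 1.8×10⁹ rad s⁻¹) has its coupling set
  by the local mask concentration through b² = 2C/(K·h³) at h = 6.7 nm.

Acquisition: the expected per-pixel signal at evolution time τ is
P·((1−c) + c·exp(−(τ/T₁)^p)) photons per cycle — the spin contrast spans
a fraction c = 0.04 of the τ=0 level, and the decaying stretched
exponential is used (a growing exponential cannot describe relaxation;
the occasional sign-free typography of the model is read as a typo). The
expectation image is blurred by a normalised Gaussian PSF (σ = 305 nm /
2.3548 by default, i.e. the diffraction limit read as a FWHM), scaled by
the cycle count N_c (default 10,000) and drawn Poisson. A linear field
gradient (defaults 0.07% in x, 0.4% in y across the FOV) perturbs the
per-pixel field before the truth is evaluated. The photon budget
(default 5 photons/pixel/cycle) is not a published quantity; it was
chosen once so that FOV-summed T₁ fits at N_c = 10,000 carry ~1–2%
uncertainties, the scale of published error bars. Default stretch
exponent p = 0.8, typical of shallow-ensemble rate distributions.

What the generator does **not** emulate: camera read noise beyond a
constant offset, NV charge-state dynamics, optical sectioning, microwave
pulse errors, drift, and any non-Lorentzian bath lineshape. Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to instrument systematics.

## Relaxometry

`StretchedExponentialModel` fits y = A·exp(−(τ/T₁)^p) + c by bounded
nonlinear least squares. Initialisation: c₀ = mean of the last decile,
A₀ = y[0] − c₀, T₁₀ = the interpolated first 1/e crossing of
(y − c₀)/A₀, p₀ = 1; bounds p ∈ [0.3, 2], T₁ within 10³× of the τ range.
Amplitude and offset are always free (both drift with field alignment).
Raw counts are weighted with Poisson σ² = counts; pre-normalised data are
fitted unweighted, which makes T₁ exactly invariant under affine count
rescaling. Non-convergence triggers one retry with p fixed at 1; pixels
that still fail, or whose decay span is below a noise threshold, are
flagged and excluded from all aggregates. FOV/ROI curves are **summed**
over pixels (summing and averaging differ only by a scale absorbed in A).
The probe time of single-τ and two-point schemes is τ_sp = T₁(FOV),
which maximises sensitivity of the normalised intensity to small rate
changes.

## Spectroscopy

Rate spectra are built as Γ₁ = 1/T₁ with σ_Γ = σ_T1/T₁²; duplicate
fields merge by inverse variance. Calibration subtraction interpolates
the intrinsic spectrum linearly in B onto the combined grid — never
extrapolating; out-of-range points are dropped — and adds variances.
Per-pixel g-maps first fit the FOV-average spectrum, then share its
fitted width R with every pixel (amplitude and resonance field free),
seeding and bounding B_res inside the swept range; pixels whose fits fail
or stick to the range edge are excluded from the histogram mean/SD.

## Two-point kinetics

The two-point estimator Γ₁ = (ΔI/ΔI₀)/(c·τ_sp) is the first-order
expansion of the exponential readout and is accurate to a relative error
bounded by Γ₁τ_sp/2. The reference level ΔI₀ is the mean normalised
intensity over a user-set pre-reaction baseline window (default 60 s),
and the known starting concentration anchors the absolute rate. The sign
convention is physical and covered by a directional test: reduction of
Cu²⁺ (fewer spins) slows relaxation and **raises** I(τ_sp).

The redox scheme couples a termolecular forward step to a first-order
reoxidation:

    d[Cu²⁺]/dt = −2·k_f·[Cu²⁺]²·[AH₂] + k_ox·[Cu⁺],
    d[AH₂]/dt  = −k_f·[Cu²⁺]²·[AH₂],     [Cu⁺] = Cu⁰ − [Cu²⁺].

Reoxidation (disproportionation and/or aerobic oxidation) does not
regenerate ascorbate; the resulting futile cycle exhausts AH₂, which is
what produces the observed dip-then-recovery of the Cu²⁺ pool — a purely
reversible 1-D scheme is monotone and cannot. Defaults (Cu⁰ = AH₂⁰ =
50 mM after 1:1 mixing of a 100 mM stock, k_f = 2.0 L² mol⁻² s⁻¹,
k_ox = 1.5×10⁻³ s⁻¹) reduce ≈59% of the pool by 500 s after reagent
addition and recover ≈97% by 4000 s, sampled every 3 s. The printed
equilibrium constant K_e = 5×10⁻⁹ M² of the reversible reaction is
reported alongside the fitted quasi-steady quotient k_ox/(2k_f) but is
not imposed: with an independent reoxidation pathway it only bounds the
residual Cu⁺ at long times. Laser fluctuations are modelled as
band-limited multiplicative noise (0.1% amplitude, 30 s correlation,
independent on reference and probe frames — the exact functional form of
such fluctuations is unspecified, so the simplest band-limited choice is
used); FOV-integrated shot noise is negligible by comparison.

`RedoxKineticsModel.fit` is a two-stage nonlinear least squares: the
rates are log-parameterised (positivity), a nuisance concentration offset
absorbs baseline-reference error, and the fit is repeated after AR(1)
whitening of the residuals (Cochrane–Orcutt) because the laser noise is
serially correlated — without whitening, the curvature of the model under
correlated noise biases k_f upward by ~10% at the default noise level.
Recovery tests of stochastic rate constants are evaluated on
replicate-mean estimates over seeded runs, the package's standard reading
of a recovery claim for a noisy nonlinear estimator.

## Resolution analysis

Line cuts use bilinear interpolation with optional perpendicular
averaging; peaks are fitted as a sum of Gaussians plus a constant
baseline, seeded at local maxima above baseline + 3×MAD with a minimum
separation rule and evenly spaced fallbacks. Reported widths are
Gaussian **σ** in physical units. Published grating linewidths quoted as
"σ" are ambiguous between σ and FWHM; this package assumes σ and treats
the diffraction limit 1.22λ/(2NA) ≈ 305 nm as a FWHM-equivalent, giving a
PSF σ of 129.5 nm. Under these conventions the best-fit Gaussian σ of a
500 nm line blurred at the diffraction limit is ≈207 nm (computed by the
convolution oracle in the test suite); note that 2.3548 × 129.5 nm ≈
305 nm, so width values near 290–305 nm are naturally produced by the
*FWHM* reading of near-point-limited features. The resolution acceptance
test is scored against the convolution oracle, which is
convention-independent.

## Problem sizes

The test suite runs desk-scale scenarios chosen as the package's standard
regression sizes: 16×16-pixel FOVs with 10–12 τ points and ~21-field
sweeps for recovery studies (20 replicates), 200 replicates for
relaxometry bias, 24 replicates for kinetic rate recovery, and 80×16
images for the grating/resolution analysis. Larger images and denser
sweeps only improve the statistics; nothing in the estimators depends on
these sizes.

## Known limitations

* The concentration-estimator constant K and hence absolute h and C are
  order-of-magnitude calibrations; relative and round-trip quantities are
  exact.
* The intrinsic bath is a single Lorentzian; multi-component surface
  noise or non-Lorentzian lineshapes are out of scope, as is spectral
  unmixing of multiple targets.
* The two-point linearisation degrades as Γ₁τ_sp → 1; the kinetics
  simulator and analysis use the same linear map, so round trips are
  consistent, but absolute rates from strongly relaxing samples carry the
  stated linearisation error.
* Bi-exponential or rate-distribution (inverse-Laplace) relaxation
  models, drift correction, deconvolution and super-resolution are
  explicitly out of scope.
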