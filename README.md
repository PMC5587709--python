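# qprm — quantum-probe relaxation microscopy

`qprm` is an analysis and simulation package for wide-field electron
paramagnetic resonance (EPR) microscopy with nitrogen-vacancy (NV) centres
in diamond. A shallow NV ensemble is imaged optically while an axial
magnetic field B₀ tunes its |0⟩→|−1⟩ spin transition; when that transition
crosses the Larmor frequency of an environmental spin-½ species — surface
electrons on the diamond, or a target such as hexaaqua-Cu²⁺ in solution —
resonant flip-flops enhance the NV spin-lattice relaxation rate Γ₁ = 1/T₁.
Sweeping B₀ and mapping T₁ per pixel therefore yields a spatially resolved
EPR spectrum at room temperature, with diffraction-limited (~300 nm)
resolution and zeptomole-scale spin sensitivity. The package is written
for experimentalists who want to fit such data end to end, and for anyone
who wants to study the estimators on fully specified synthetic data.

## The model

Relaxation of the probe in an environment with spectral density
S(ω_E; B₀) is the overlap with the probe's Lorentzian filter function

    Γ₁(B₀) = ∫ S(ω_E, B₀) · G(Γ₂, ω_E, B₀) dω_E,
    G = b²Γ₂ / (2(Γ₂² + (ω_NV − ω_E)²)),   ω_NV = 2π(D − γ_NV B₀),

with D the 2.87 GHz zero-field splitting, γ_NV the NV gyromagnetic ratio
and Γ₂ the transverse (filter) width. For a Lorentzian bath of width R
the convolution is closed form:

    Γ₁(B₀) = (b²/2)(Γ₂+R) / ((Γ₂+R)² + (2πD − (γ_NV+γ_t)B₀)²),

a Lorentzian in field peaking at the crossing B_res, from which the target
g-factor follows as g = hD/(μ_B B_res) − g_NV. The coupling b² scales
linearly with target concentration, giving the estimator
C = 4.35×10¹⁰ · Γ₁(B_res) · h³ · (Γ₂+R) mol/L at probe depth h.

Per-pixel relaxation is fitted with the stretched exponential
y = A·exp(−(τ/T₁)^p) + c that describes the rate distribution of a
shallow ensemble; a two-point scheme (reference time τ_ref ≈ 0, probe time
τ_sp = T₁) converts slow intensity changes into Γ₁(t) for kinetics, e.g.
the reversible reduction 2Cu²⁺ + AH₂ ⇌ 2Cu⁺ + A + 2H⁺ by ascorbate, where
the spin-½ Cu²⁺ is EPR-visible and the reduced Cu⁺ is silent.

## Worked example

Simulate a field-swept experiment on a uniform 100 mM Cu²⁺ droplet
(16×16 pixels, 21 fields, N_c = 10,000 cycles, Poisson shot noise), build
the calibration-subtracted rate spectrum and fit the closed-form model:

```python
import numpy as np
from qprm import (ProbeModel, SpinSpecies, AcquisitionConfig, make_mask,
                  simulate_field_sweep, fit_decay, roi_aggregate,
                  build_spectrum, subtract_calibration, fit_target_spectrum)

probe = ProbeModel()                    # D = 2.87 GHz, g_NV = 2.0028, 4 MHz ODMR
cu = SpinSpecies.hexaaqua_cu()          # g_par 2.400, g_perp 2.099, R = 1.8e9 rad/s
mask = make_mask("uniform", shape=(16, 16), C0=0.1)   # 100 mM
fields = list(np.linspace(420, 560, 21))

def fov(sweep):
    return build_spectrum([(B, fit_decay(s.tau, roi_aggregate(s, (0, 16, 0, 16))))
                           for B, s in sweep])

combined = fov(simulate_field_sweep(fields, mask, probe, cu,
                                    AcquisitionConfig(seed=1)))
calibration = fov(simulate_field_sweep(fields, mask, probe, None,
                                       AcquisitionConfig(seed=2)))
target = subtract_calibration(combined, calibration)
print(fit_target_spectrum(target, probe, known_concentration=0.1).summary())
```

prints

```
Target relaxation-spectrum fit (FOV)
====================================================
  B_res            488.18 G   (se 0.55)
  g-factor         2.1976     (se 0.0048)
  R             1.825e+09 rad/s (se 3.6e+07)
  b^2           1.547e+13 rad^2/s^2
  peak rate          4180 s^-1
  h_probe           6.674 nm  (from b^2 at C = 0.1 M; convention-dependent)
  converged    True
```

The spectrum peaks at the Cu²⁺↔NV level crossing (≈488 G for the motional
average g = 2.199 of the axial tensor), the fitted bath fluctuation rate R
recovers the 1.8×10⁹ rad/s linewidth the sweep was generated with, and
the coupling amplitude converts to the 6.7 nm probe depth because the
concentration is known. `quantification` then converts on-resonance rates
to spins per sensing voxel (a 1.6×1.6×0.01 µm³ voxel at 100 mM holds
~1.5×10⁶ spins ≈ 2.5 amol) and to detection limits.

A `qprm` command-line tool wraps the same stages
(`simulate`, `fit-t1`, `spectrum`, `quantify`, `kinetics`, `resolution`,
`pipeline`); `qprm pipeline --config scenario.yaml --out run/` executes the
whole workflow from one YAML file and writes a JSON report plus a hash
manifest for reproducibility.

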