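"""Seeded generators for every input the analysis pipeline consumes.

A simulated experiment is assembled in layers that mirror the instrument:

1. a patterned 2-D concentration mask (the lithographed template that
   confines the target solution),
2. per-pixel ground-truth relaxation from the closed-form spin physics,
   including the intrinsic surface-spin bath and a linear field gradient
   across the field of view,
3. fluorescence decay stacks: stretched-exponential contrast on a photon
   budget, diffraction-limited Gaussian blur, Poisson shot noise
   accumulated over N_c cycles,
4. field sweeps of such stacks, and two-point intensity traces driven by
   the redox ODE for kinetics experiments.

Every generator is a pure function of (config, seed): identical seeds give
bit-identical outputs.  Generated objects carry their ground truth in
``meta`` so downstream fits can be scored as parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .containers import DecayStack, KineticsTrace
from .kinetics import integrate_redox
from .physics import ProbeModel, SpinSpecies, resonance_field, target_spectrum
from .quantification import QuantParams, b2_from_concentration, rate_from_concentration

__all__ = [
    "MaskPattern",
    "AcquisitionConfig",
    "SimTruth",
    "RedoxConfig",
    "make_mask",
    "apply_field_gradient",
    "truth_from_mask",
    "simulate_decay_stack",
    "simulate_field_sweep",
    "simulate_kinetics",
    "BASE_RATE_OFF_RESONANCE",
]

#: Default background relaxation rate far from any resonance, s^-1
#: (the 730 us off-resonance T1 scale of a shallow implanted ensemble).
BASE_RATE_OFF_RESONANCE = 1.0 / 730e-6

# 5x7 block font for the lithographed letter masks.
_FONT = {
    "C": ["01110", "10001", "10000", "10000", "10000", "10001", "01110"],
    "U": ["10001", "10001", "10001", "10001", "10001", "10001", "01110"],
    "Q": ["01110", "10001", "10001", "10001", "10101", "10010", "01101"],
    "P": ["11110", "10001", "10001", "11110", "10000", "10000", "10000"],
    "R": ["11110", "10001", "10001", "11110", "10100", "10010", "10001"],
    "M": ["10001", "11011", "10101", "10101", "10001", "10001", "10001"],
    "N": ["10001", "11001", "10101", "10011", "10001", "10001", "10001"],
    "V": ["10001", "10001", "10001", "10001", "10001", "01010", "00100"],
    " ": ["00000"] * 7,
}


@dataclass
class MaskPattern:
    """2-D target concentration map (mol/L) on a square pixel grid.

    Row-major, 0-based, (0, 0) top-left; physical position is
    index × ``pixel_size_um``.
    """

    concentration_map: np.ndarray
    pixel_size_um: float = 0.1

    def __post_init__(self):
        self.concentration_map = np.asarray(self.concentration_map, dtype=float)
        if self.concentration_map.ndim != 2 or min(self.concentration_map.shape) < 8:
            raise ValueError("mask must be a 2-D grid of at least 8x8 pixels")
        if np.any(self.concentration_map < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self):
        return self.concentration_map.shape


def make_mask(kind: str, *, shape=(32, 32), C0: float = 0.1,
              pixel_size_um: float = 0.1, width_um: float = 0.5,
              pitch_um: float = 1.0, text: str = "CU",
              scale: int = 3, margin: int = 2) -> MaskPattern:
    """Build a binary concentration mask.

    ``uniform`` fills the FOV with C0; ``grating`` makes vertical lines of
    ``width_um`` on a ``pitch_um`` period (the resolution test pattern);
    ``letters`` renders block text (the image-template pattern).
    """
    if C0 < 0:
        raise ValueError("C0 must be nonnegative")
    if kind == "uniform":
        cmap = np.full(shape, float(C0))
    elif kind == "grating":
        if pitch_um <= width_um:
            raise ValueError("grating pitch must exceed line width")
        ny, nx = shape
        x_um = np.arange(nx) * pixel_size_um
        on = (x_um % pitch_um) < width_um
        cmap = np.where(on[None, :], float(C0), 0.0) * np.ones((ny, 1))
    elif kind == "letters":
        glyphs = []
        for ch in text.upper():
            if ch not in _FONT:
                raise ValueError(f"no glyph for {ch!r}")
            glyphs.append(np.array([[int(c) for c in row] for row in _FONT[ch]]))
        bitmap = np.hstack(
            [np.pad(g, ((0, 0), (0, 1))) for g in glyphs])[:, :-1]
        bitmap = np.kron(bitmap, np.ones((scale, scale)))
        cmap = np.pad(bitmap, margin) * float(C0)
        if min(cmap.shape) < 8:
            cmap = np.pad(cmap, (0, 8 - min(cmap.shape)))
    else:
        raise ValueError(f"unknown mask kind {kind!r}")
    return MaskPattern(cmap, pixel_size_um)


@dataclass
class AcquisitionConfig:
    """Camera/sequence settings of a simulated T1 acquisition."""

    tau_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-6, 3e-3, 12))
    N_c: int = 10_000
    photons_per_pixel_per_cycle: float = 5.0
    camera_offset: float = 0.0
    psf_sigma_um: float = 305e-3 / 2.3548  # diffraction limit as FWHM
    field_gradient: tuple = (0.0007, 0.004)  # fractional (x, y) across FOV
    seed: int = 0

    def __post_init__(self):
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        if self.tau_grid.size < 5 or np.any(np.diff(self.tau_grid) <= 0):
            raise ValueError("tau_grid must be strictly increasing with >= 5 points")
        if self.N_c < 1:
            raise ValueError("N_c must be >= 1")
        if self.photons_per_pixel_per_cycle <= 0:
            raise ValueError("photon budget must be positive")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma must be nonnegative")


@dataclass
class SimTruth:
    """Per-pixel ground truth behind a simulated stack."""

    T1: np.ndarray  # s
    p: np.ndarray  # stretch exponent
    gamma_base: float  # s^-1, field-independent background
    gamma_intrinsic: np.ndarray  # s^-1
    gamma_target: np.ndarray  # s^-1
    contrast_c: float
    B0: float  # nominal field, G
    B_map: np.ndarray  # per-pixel field, G
    pixel_size_um: float = 0.1

    def __post_init__(self):
        if np.any(self.T1 <= 0):
            raise ValueError("T1 must be positive")
        if np.any((self.p < 0.3) | (self.p > 2.0)):
            raise ValueError("stretch exponent must lie in [0.3, 2]")

    @property
    def Gamma1(self) -> np.ndarray:
        return 1.0 / self.T1

    def summary(self) -> dict:
        return {
            "B0_G": self.B0,
            "gamma_base_per_s": self.gamma_base,
            "T1_mean_s": float(np.mean(self.T1)),
            "T1_min_s": float(np.min(self.T1)),
            "T1_max_s": float(np.max(self.T1)),
            "p_mean": float(np.mean(self.p)),
        }


def apply_field_gradient(B0: float, shape, gradient_xy) -> np.ndarray:
    """Per-pixel field map with a linear fractional gradient across the FOV."""
    ny, nx = shape
    gx, gy = gradient_xy
    xn = np.linspace(-0.5, 0.5, nx) if nx > 1 else np.zeros(1)
    yn = np.linspace(-0.5, 0.5, ny) if ny > 1 else np.zeros(1)
    return B0 * (1.0 + gx * xn[None, :] + gy * yn[:, None])


def truth_from_mask(mask: MaskPattern, probe: ProbeModel, target: Optional[SpinSpecies],
                    intrinsic: SpinSpecies, B0, *,
                    base_rate: float = BASE_RATE_OFF_RESONANCE,
                    stretch_p: float = 0.8) -> SimTruth:
    """Ground-truth rate decomposition for a mask at field ``B0``.

    Per pixel, Γ₁ = Γ_base + Γ_intrinsic(B) + Γ_target(B) where the target
    coupling scales linearly with the local concentration through
    b² = 2C/(K·h³) at the probe depth.  ``B0`` may be a scalar (uniform
    field) or a per-pixel map (e.g. from :func:`apply_field_gradient`).
    """
    shape = mask.shape
    B_map = np.broadcast_to(np.asarray(B0, dtype=float), shape).copy()
    B_nominal = float(np.mean(B_map))
    gamma_i = np.asarray(target_spectrum(B_map, intrinsic, probe))
    if target is not None:
        unit = target.with_coupling(1.0)
        shape_fn = np.asarray(target_spectrum(B_map, unit, probe))
        b2 = b2_from_concentration(1.0, probe.h_probe) * mask.concentration_map
        gamma_t = b2 * shape_fn
    else:
        gamma_t = np.zeros(shape)
    gamma1 = base_rate + gamma_i + gamma_t
    return SimTruth(
        T1=1.0 / gamma1, p=np.full(shape, float(stretch_p)),
        gamma_base=base_rate, gamma_intrinsic=gamma_i, gamma_target=gamma_t,
        contrast_c=probe.contrast_c, B0=B_nominal, B_map=B_map,
        pixel_size_um=mask.pixel_size_um,
    )


def simulate_decay_stack(truth: SimTruth, acq: AcquisitionConfig,
                         rng: Optional[np.random.Generator] = None) -> DecayStack:
    """Poisson-noisy fluorescence stack for a given ground truth.

    The expected per-pixel signal at evolution time τ is
    P·((1−c) + c·exp(−(τ/T1)^p)) photons per cycle — the optical contrast
    spans a fraction c of the τ=0 level.  The expectation image is blurred
    by the Gaussian PSF (normalised kernel, reflective boundary, so total
    expected intensity is conserved), scaled by N_c and drawn Poisson.
    """
    if acq.tau_grid.size == 0:
        raise ValueError("tau_grid is empty")
    if rng is None:
        rng = np.random.default_rng(acq.seed)
    c = truth.contrast_c
    tau = acq.tau_grid[:, None, None]
    decay = (1.0 - c) + c * np.exp(-((tau / truth.T1) ** truth.p))
    expected = acq.photons_per_pixel_per_cycle * decay
    sigma_px = acq.psf_sigma_um / truth.pixel_size_um
    if sigma_px > 0:
        for k in range(expected.shape[0]):
            expected[k] = gaussian_filter(expected[k], sigma_px, mode="reflect")
    counts = rng.poisson(acq.N_c * expected).astype(float) + acq.camera_offset
    return DecayStack(
        tau=acq.tau_grid, frames=counts, N_c=acq.N_c, B0=truth.B0,
        pixel_size_um=truth.pixel_size_um,
        meta={"truth": truth, "seed": acq.seed,
              "truth_summary": truth.summary()},
    )


def simulate_field_sweep(B_list: Sequence[float], mask: MaskPattern,
                         probe: ProbeModel, target: Optional[SpinSpecies],
                         acq: AcquisitionConfig, *,
                         intrinsic: Optional[SpinSpecies] = None,
                         base_rate: float = BASE_RATE_OFF_RESONANCE,
                         stretch_p: float = 0.8):
    """One decay stack per applied field; reproducible child RNG per field.

    The root generator is seeded from ``acq.seed`` and spawned once per
    field in list order, so a sweep is reproducible as a whole and any
    single field can be regenerated independently.
    """
    if len(B_list) == 0:
        raise ValueError("B_list must be nonempty")
    intrinsic = intrinsic or SpinSpecies.surface_bath()
    streams = np.random.default_rng(acq.seed).spawn(len(B_list))
    out = []
    for B0, stream in zip(B_list, streams):
        B_map = apply_field_gradient(float(B0), mask.shape, acq.field_gradient)
        truth = truth_from_mask(mask, probe, target, intrinsic, B_map,
                                base_rate=base_rate, stretch_p=stretch_p)
        truth.B0 = float(B0)  # nominal sweep value, not the gradient mean
        out.append((float(B0), simulate_decay_stack(truth, acq, rng=stream)))
    return out


@dataclass
class RedoxConfig:
    """Scenario for a two-point redox-kinetics run.

    Defaults emulate 1:1 mixing of a 100 mM Cu²⁺ stock with ascorbate
    (both 50 mM after mixing): ~60% of the Cu²⁺ is reduced within 500 s
    and the pool recovers by ~4000 s as the ascorbate is exhausted.
    """

    cu0_M: float = 0.05
    ah2_0_M: float = 0.05
    k_f: float = 2.0  # L^2 mol^-2 s^-1
    k_ox: float = 1.5e-3  # s^-1
    K_e: float = 5e-9  # M^2
    sample_interval_s: float = 3.0
    duration_s: float = 4000.0
    laser_amp: float = 1e-3  # fractional, band-limited
    laser_corr_s: float = 30.0
    reaction_start_s: float = 60.0

    def __post_init__(self):
        if min(self.cu0_M, self.ah2_0_M, self.k_f, self.k_ox, self.laser_amp) < 0:
            raise ValueError("rates and concentrations must be nonnegative")
        if self.K_e <= 0:
            raise ValueError("K_e must be positive")
        if self.sample_interval_s <= 0 or self.duration_s <= 0:
            raise ValueError("sampling parameters must be positive")


def _band_limited_noise(n: int, amp: float, corr_samples: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Zero-mean multiplicative noise with ~Gaussian autocorrelation."""
    if amp == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if corr_samples > 0:
        smooth = gaussian_filter1d(white, corr_samples, mode="reflect")
    else:
        smooth = white
    sd = smooth.std()
    return amp * smooth / sd if sd > 0 else np.zeros(n)


def simulate_kinetics(redox: RedoxConfig, probe: ProbeModel, quant: QuantParams,
                      acq: AcquisitionConfig, *, fov_pixels: int = 256 * 256,
                      intrinsic: Optional[SpinSpecies] = None,
                      base_rate: float = BASE_RATE_OFF_RESONANCE,
                      rng: Optional[np.random.Generator] = None) -> KineticsTrace:
    """Two-point intensity trace of a redox reaction at the target resonance.

    The redox ODE gives [Cu²⁺](t); the concentration estimator maps it to
    the on-resonance target rate Γ₁(t); the probe time τ_sp is set to the
    FOV T1 at the start of the run; and the probe-point intensity follows
    the linear two-point relation ΔI/ΔI₀ = c·τ_sp·ΔΓ₁ around the baseline.
    Band-limited multiplicative laser fluctuations (independent on the
    reference and probe frames) and Poisson shot noise are added on top.
    """
    if rng is None:
        rng = np.random.default_rng(acq.seed)
    intrinsic = intrinsic or SpinSpecies.surface_bath()
    t = np.arange(0.0, redox.duration_s + 0.5 * redox.sample_interval_s,
                  redox.sample_interval_s)
    cu2, ah2 = integrate_redox(redox.cu0_M, redox.ah2_0_M, redox.k_f,
                               redox.k_ox, t, redox.reaction_start_s)
    # On-resonance Cu rate series and static background at the Cu resonance.
    gamma_cu = rate_from_concentration(1.0, quant.h_probe, quant.Gamma2,
                                       quant.R_relax) * cu2
    B_res = resonance_field(SpinSpecies.hexaaqua_cu().g_iso, probe)
    gamma_bg = base_rate + float(target_spectrum(B_res, intrinsic, probe))
    gamma_tot0 = gamma_bg + gamma_cu[0]
    tau_sp = 1.0 / gamma_tot0
    c = probe.contrast_c
    ratio0 = (1.0 - c) + c * math.exp(-tau_sp * gamma_tot0)
    ratio = ratio0 * (1.0 - c * tau_sp * (gamma_cu - gamma_cu[0]))

    n_ref = acq.photons_per_pixel_per_cycle * acq.N_c * fov_pixels
    corr = redox.laser_corr_s / redox.sample_interval_s
    eps_ref = _band_limited_noise(t.size, redox.laser_amp, corr, rng)
    eps_sp = _band_limited_noise(t.size, redox.laser_amp, corr, rng)
    I_ref = rng.poisson(n_ref * (1.0 + eps_ref)).astype(float)
    I_sp = rng.poisson(n_ref * ratio * (1.0 + eps_sp)).astype(float)
    return KineticsTrace(
        t=t, I_ref=I_ref, I_sp=I_sp, tau_sp=tau_sp,
        meta={"cu2_M": cu2, "ah2_M": ah2, "gamma_cu_per_s": gamma_cu,
              "gamma_background_per_s": gamma_bg, "B_res_G": B_res,
              "redox": redox, "quant": quant, "seed": acq.seed},
    )
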