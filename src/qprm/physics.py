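"""Closed-form spin physics for NV-diamond relaxometry.

The nitrogen-vacancy (NV) centre is a spin-1 defect whose |0>-|−1>
transition frequency is tuned with an axial magnetic field B0.  When that
transition crosses the Larmor frequency of an environmental spin-1/2
species (free electrons on the diamond surface, or a target such as
hexaaqua-Cu2+ in solution), resonant flip-flops enhance the NV
spin-lattice relaxation rate Γ₁.  This module provides:

* Zeeman/level arithmetic: transition frequencies, resonance fields and
  g-factor conversions,
* the Lorentzian NV filter function and the environment spectral density,
* the closed-form target relaxation-rate spectrum Γ₁(B0) obtained by
  convolving the two Lorentzians.

Unit conventions (imposed consistently):

* magnetic fields in gauss at every API surface;
* all spectral quantities (Γ₂, R, b², detunings) in angular frequency,
  rad s⁻¹;
* gyromagnetic ratios internally in rad s⁻¹ G⁻¹, γ = 2π·g·μB/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import DEFAULT_CONSTANTS, G_FREE_ELECTRON, PhysConstants

__all__ = [
    "ProbeModel",
    "SpinSpecies",
    "motional_average_g",
    "nv_transition_freq",
    "resonance_field",
    "g_from_resonance_field",
    "filter_function",
    "spectral_density",
    "target_spectrum",
    "convolved_rate",
    "gamma_rad_per_s_G",
]

#: Field (G) of the ground-state level anti-crossing; the |0>-|−1> branch
#: arithmetic used here is only valid below it.
B_GSLAC = 1024.0


def gamma_rad_per_s_G(g: float, constants: PhysConstants = DEFAULT_CONSTANTS) -> float:
    """Gyromagnetic ratio in rad s⁻¹ G⁻¹ for a dimensionless g-factor."""
    return 2.0 * math.pi * g * constants.mu_B_over_h


@dataclass
class ProbeModel:
    """NV ensemble parameters.

    Parameters
    ----------
    D : float
        Zero-field splitting in Hz (2.87 GHz for NV in diamond).
    g_NV : float
        Effective g-factor of the NV spin.
    Gamma2 : float
        Transverse relaxation rate of the probe in rad s⁻¹.  Taken as
        2π × (ODMR linewidth in Hz); the default corresponds to a 4 MHz
        inhomogeneously broadened line.
    h_probe : float
        Mean probe depth below the diamond surface, metres.
    contrast_c : float
        Optical spin-relaxation contrast (fractional fluorescence span
        between the polarised |0> state and the thermally mixed state).
    """

    D: float = 2.87e9
    g_NV: float = 2.0028
    Gamma2: float = 2.0 * math.pi * 4.0e6
    h_probe: float = 6.7e-9
    contrast_c: float = 0.04
    constants: PhysConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("zero-field splitting D must be positive")
        if self.Gamma2 <= 0:
            raise ValueError("transverse rate Gamma2 must be positive")
        if self.h_probe <= 0:
            raise ValueError("probe depth h_probe must be positive")
        if not 0.0 < self.contrast_c < 1.0:
            raise ValueError("optical contrast must lie in (0, 1)")

    @property
    def gamma_NV_Hz_per_G(self) -> float:
        """NV gyromagnetic ratio in Hz G⁻¹ (≈ 2.8 MHz G⁻¹)."""
        return self.g_NV * self.constants.mu_B_over_h

    @property
    def gamma_NV_rad(self) -> float:
        """NV gyromagnetic ratio in rad s⁻¹ G⁻¹."""
        return 2.0 * math.pi * self.gamma_NV_Hz_per_G

    def omega_NV(self, B0):
        """|0>→|−1> transition of the probe in rad s⁻¹ at field ``B0`` (G)."""
        return 2.0 * math.pi * nv_transition_freq(B0, -1, self)


@dataclass
class SpinSpecies:
    """An electronic spin bath coupled to the probe.

    Either the axial tensor components ``(g_par, g_perp)`` or the
    isotropic ``g_iso`` must be supplied; when both axial components are
    given, ``g_iso`` is their motional average (the value observed for a
    tumbling complex in solution).

    ``R_relax`` is the intrinsic fluctuation rate of the bath (rad s⁻¹),
    dominating the width of its spectral density; ``coupling_b2`` is the
    squared probe-bath coupling b² (rad² s⁻²) setting the on-resonance
    relaxation-rate amplitude b²/(2(Γ₂+R)).
    """

    label: str = "spins"
    g_par: Optional[float] = None
    g_perp: Optional[float] = None
    g_iso: Optional[float] = None
    R_relax: float = 0.0
    coupling_b2: float = 0.0

    def __post_init__(self):
        if self.g_iso is None:
            if self.g_par is None or self.g_perp is None:
                raise ValueError(
                    "supply g_iso or both axial components g_par, g_perp"
                )
            self.g_iso = motional_average_g(self.g_par, self.g_perp)
        elif self.g_par is not None and self.g_perp is not None:
            avg = motional_average_g(self.g_par, self.g_perp)
            if not math.isclose(self.g_iso, avg, rel_tol=1e-9):
                raise ValueError(
                    f"g_iso={self.g_iso} inconsistent with motional average "
                    f"{avg} of (g_par, g_perp)"
                )
        for name in ("g_par", "g_perp", "g_iso"):
            val = getattr(self, name)
            if val is not None and not 1.0 < val < 10.0:
                raise ValueError(f"{name}={val} outside the plausible (1, 10) range")
        if self.R_relax < 0:
            raise ValueError("R_relax must be nonnegative")
        if self.coupling_b2 < 0:
            raise ValueError("coupling_b2 must be nonnegative")

    def with_coupling(self, b2: float) -> "SpinSpecies":
        """Copy of this species with a different coupling amplitude."""
        return SpinSpecies(
            label=self.label,
            g_par=self.g_par,
            g_perp=self.g_perp,
            g_iso=self.g_iso if self.g_par is None else None,
            R_relax=self.R_relax,
            coupling_b2=b2,
        )

    @classmethod
    def free_electron(cls, R_relax: float = 0.0, coupling_b2: float = 0.0):
        return cls(label="free-electron", g_iso=G_FREE_ELECTRON,
                   R_relax=R_relax, coupling_b2=coupling_b2)

    @classmethod
    def hexaaqua_cu(cls, R_relax: float = 1.8e9, coupling_b2: float = 0.0):
        """[Cu(OH2)6]2+ with the axial g-tensor of the tumbling complex."""
        return cls(label="Cu2+", g_par=2.400, g_perp=2.099,
                   R_relax=R_relax, coupling_b2=coupling_b2)

    @classmethod
    def surface_bath(cls, g_iso: float = 2.0077, R_relax: float = 35.27e6,
                     coupling_b2: float = 3.624e11):
        """Diamond surface electronic spins (the intrinsic calibration bath).

        Defaults put the resonance at 511.3 G and the total spectrum
        half-width (Γ₂ + R) at 60.4e6 rad s⁻¹ for the default probe; the
        coupling sets an on-resonance rate of 3.0e3 s⁻¹ (the printed
        spectra give only the scale, a few 10³ s⁻¹).
        """
        return cls(label="surface", g_iso=g_iso, R_relax=R_relax,
                   coupling_b2=coupling_b2)


def motional_average_g(g_par: float, g_perp: float) -> float:
    """Isotropic g-factor of a fast-tumbling axial species.

    Orientation averaging of an axial Zeeman tensor gives
    <g> = (g_par + 2 g_perp) / 3.
    """
    if g_par <= 0 or g_perp <= 0:
        raise ValueError("g-tensor components must be positive")
    return (g_par + 2.0 * g_perp) / 3.0


def nv_transition_freq(B0, branch: int, probe: Optional[ProbeModel] = None):
    """NV ground-state transition frequency in Hz.

    ``branch=-1`` selects |0>→|−1> (D − γ_NV·B0), ``branch=+1`` selects
    |0>→|+1> (D + γ_NV·B0).  Valid for fields aligned with the NV axis
    below the ground-state level anti-crossing (1024 G).
    """
    probe = probe or ProbeModel()
    B0 = np.asarray(B0, dtype=float)
    if np.any(B0 < 0) or np.any(B0 >= B_GSLAC):
        raise ValueError(f"B0 must satisfy 0 <= B0 < {B_GSLAC} G")
    if branch not in (-1, +1):
        raise ValueError("branch must be -1 or +1")
    out = probe.D + branch * probe.gamma_NV_Hz_per_G * B0
    return float(out) if out.ndim == 0 else out


def resonance_field(g_target: float, probe: Optional[ProbeModel] = None) -> float:
    """Field (G) where the NV |0>→|−1> branch crosses the target spin flip.

    Solves D − γ_NV·B = γ_t·B, i.e. D = (g_NV + g_t)·(μB/h)·B: the probe
    transition comes down in energy with field while the spin-1/2 target
    transition goes up, and they cross once below the anti-crossing.
    """
    probe = probe or ProbeModel()
    if g_target <= 0:
        raise ValueError("g_target must be positive")
    return probe.D / ((probe.g_NV + g_target) * probe.constants.mu_B_over_h)


def g_from_resonance_field(B_res: float, probe: Optional[ProbeModel] = None) -> float:
    """Target g-factor from the observed resonance field (G).

    Inverts the crossing condition: g = hD/(μB·B_res) − g_NV.
    """
    probe = probe or ProbeModel()
    if B_res <= 0:
        raise ValueError("B_res must be positive")
    return probe.D / (probe.constants.mu_B_over_h * B_res) - probe.g_NV


def filter_function(omega_E, B0: float, b2: float, Gamma2: float,
                    probe: Optional[ProbeModel] = None):
    """Lorentzian NV filter function G(Γ₂, ω_E, B0), rad⁻¹ spectral weight.

    b²Γ₂ / (2(Γ₂² + (ω_NV − ω_E)²)) with ω_NV = 2π(D − γ_NV·B0).  Its
    quadrature over ω_E is πb²/2 independent of Γ₂, so a narrow filter
    samples the environment spectral density pointwise.
    """
    if Gamma2 <= 0:
        raise ValueError("Gamma2 must be positive")
    if b2 < 0:
        raise ValueError("b2 must be nonnegative")
    probe = probe or ProbeModel()
    omega_NV = probe.omega_NV(B0)
    omega_E = np.asarray(omega_E, dtype=float)
    out = b2 * Gamma2 / (2.0 * (Gamma2**2 + (omega_NV - omega_E) ** 2))
    return float(out) if out.ndim == 0 else out


def spectral_density(omega_E, B0: float, species: SpinSpecies,
                     constants: PhysConstants = DEFAULT_CONSTANTS):
    """Normalised spectral density of a spin bath at field ``B0``.

    Unit-area Lorentzian centred on the bath Larmor frequency γ_t·B0 with
    half-width R_relax; the probe-bath coupling b² lives in the filter
    function, so ∫S dω = 1.
    """
    omega_t = gamma_rad_per_s_G(species.g_iso, constants) * B0
    R = species.R_relax
    omega_E = np.asarray(omega_E, dtype=float)
    out = (R / math.pi) / (R**2 + (omega_E - omega_t) ** 2)
    return float(out) if out.ndim == 0 else out


def target_spectrum(B0, species: SpinSpecies, probe: Optional[ProbeModel] = None):
    """Closed-form relaxation-rate spectrum Γ₁(B0) of a target bath, s⁻¹.

    The convolution of the Lorentzian filter (width Γ₂) with a Lorentzian
    bath spectral density (width R) is itself Lorentzian with width Γ₂+R:

        Γ₁(B0) = (b²/2)(Γ₂+R) / ((Γ₂+R)² + (2πD − (γ_NV+γ_t)B0)²)

    peaking exactly at ``resonance_field(species.g_iso)`` with value
    b²/(2(Γ₂+R)).
    """
    probe = probe or ProbeModel()
    width = probe.Gamma2 + species.R_relax
    detune = (2.0 * math.pi * probe.D
              - (probe.gamma_NV_rad + gamma_rad_per_s_G(species.g_iso,
                                                        probe.constants))
              * np.asarray(B0, dtype=float))
    out = 0.5 * species.coupling_b2 * width / (width**2 + detune**2)
    return float(out) if out.ndim == 0 else out


def convolved_rate(B0: float, species: SpinSpecies,
                   probe: Optional[ProbeModel] = None,
                   n_width: float = 60.0, n_points: int = 20001) -> float:
    """Relaxation rate by explicit numerical convolution of filter x density.

    Integrates S(ω_E)·G(Γ₂, ω_E, B0) over ω_E on a grid spanning
    ``n_width`` half-widths around both Lorentzian centres.  Serves as the
    independent numerical route to the closed form in
    :func:`target_spectrum` (they agree because the convolution of two
    Lorentzians is Lorentzian).
    """
    probe = probe or ProbeModel()
    omega_NV = probe.omega_NV(B0)
    omega_t = gamma_rad_per_s_G(species.g_iso, probe.constants) * B0
    width = probe.Gamma2 + species.R_relax
    lo = min(omega_NV, omega_t) - n_width * width
    hi = max(omega_NV, omega_t) + n_width * width
    omega = np.linspace(lo, hi, n_points)
    integrand = (spectral_density(omega, B0, species, probe.constants)
                 * filter_function(omega, B0, species.coupling_b2,
                                   probe.Gamma2, probe))
    return float(np.trapezoid(integrand, omega))
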