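"""Shared data containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np


@dataclass
class DecayStack:
    """Fluorescence image stack over spin evolution times τ.

    ``frames`` has shape (len(tau), ny, nx) and holds accumulated camera
    counts over ``N_c`` measurement cycles per τ point.  Coordinates are
    0-based and row-major with (0, 0) the top-left pixel; physical
    position = index × ``pixel_size_um``.
    """

    tau: np.ndarray  # s, strictly increasing
    frames: np.ndarray  # (ntau, ny, nx) counts
    N_c: int = 1
    B0: float = 0.0  # nominal applied field, G
    pixel_size_um: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.frames = np.asarray(self.frames)
        if self.tau.ndim != 1 or np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be a strictly increasing vector")
        if self.frames.ndim != 3 or self.frames.shape[0] != self.tau.size:
            raise ValueError("frames must be (len(tau), ny, nx)")
        if np.any(self.frames < 0):
            raise ValueError("counts must be nonnegative")
        if self.N_c < 1:
            raise ValueError("N_c must be >= 1")

    @property
    def shape(self):
        return self.frames.shape[1:]


@dataclass
class RateSpectrum:
    """Relaxation rate Γ₁ ± σ versus applied field B0.

    ``provenance`` records whether the spectrum came from the full field
    of view ("FOV"), a region of interest ("ROI") or a single pixel
    ("pixel(i,j)").
    """

    B0: np.ndarray  # G, strictly increasing
    Gamma1: np.ndarray  # s^-1
    sigma_Gamma1: np.ndarray  # s^-1
    provenance: str = "FOV"

    def __post_init__(self):
        self.B0 = np.asarray(self.B0, dtype=float)
        self.Gamma1 = np.asarray(self.Gamma1, dtype=float)
        self.sigma_Gamma1 = np.asarray(self.sigma_Gamma1, dtype=float)
        if self.B0.ndim != 1 or np.any(np.diff(self.B0) <= 0):
            raise ValueError("B0 must be strictly increasing")
        if self.Gamma1.shape != self.B0.shape or self.sigma_Gamma1.shape != self.B0.shape:
            raise ValueError("Gamma1/sigma arrays must match B0")
        if np.any(self.sigma_Gamma1 <= 0):
            raise ValueError("sigma_Gamma1 must be positive")

    def __len__(self):
        return self.B0.size


@dataclass
class KineticsTrace:
    """Two-point relaxometry time series.

    ``I_ref`` and ``I_sp`` are the fluorescence levels at the reference
    (τ≈0) and probe (τ_sp) evolution times; their ratio carries the
    relaxation-rate dynamics.
    """

    t: np.ndarray  # s, strictly increasing
    I_ref: np.ndarray
    I_sp: np.ndarray
    tau_sp: float = 0.0  # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.I_ref = np.asarray(self.I_ref, dtype=float)
        self.I_sp = np.asarray(self.I_sp, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.I_ref.shape != self.t.shape or self.I_sp.shape != self.t.shape:
            raise ValueError("intensity arrays must match t")
        if np.any(self.I_ref <= 0) or np.any(self.I_sp <= 0):
            raise ValueError("intensities must be positive")

    @property
    def normalized(self) -> np.ndarray:
        """I(τ_sp)/I(τ_ref), the quantity the two-point scheme monitors."""
        return self.I_sp / self.I_ref
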