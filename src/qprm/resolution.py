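"""Spatial-resolution analysis of contrast images.

Line profiles are cut through relaxation-contrast images with bilinear
interpolation and optional perpendicular averaging; grating peaks are
fitted with a sum of Gaussians plus baseline.  The widths are reported as
Gaussian σ in physical units and compared against the optical diffraction
limit 1.22 λ / (2 NA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

__all__ = [
    "LineProfile",
    "line_profile",
    "fit_gaussian_peaks",
    "diffraction_limit",
    "default_psf_sigma_um",
]


@dataclass
class LineProfile:
    """Samples along a straight cut through an image."""

    position_um: np.ndarray  # increasing, along the cut
    value: np.ndarray
    p0: tuple  # (row, col) endpoints in pixels
    p1: tuple
    averaging_width: int = 1

    def __post_init__(self):
        if np.any(np.diff(self.position_um) <= 0):
            raise ValueError("positions must be increasing")


def line_profile(image: np.ndarray, p0, p1, width: int = 1,
                 pixel_size_um: float = 0.1,
                 n_samples: Optional[int] = None) -> LineProfile:
    """Bilinear line cut from pixel ``p0`` to ``p1`` ((row, col) pairs).

    Averaged over ``width`` parallel lines offset along the perpendicular
    direction (centred on the cut).  Sample spacing never exceeds one
    pixel.  NaN pixels (e.g. masked contrast values) are ignored in the
    average.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    r0, c0 = map(float, p0)
    r1, c1 = map(float, p1)
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= ny - 1 and 0 <= c <= nx - 1):
            raise ValueError(f"endpoint ({r}, {c}) outside the {ny}x{nx} image")
    length_px = math.hypot(r1 - r0, c1 - c0)
    if length_px == 0:
        raise ValueError("endpoints must be distinct")
    if width < 1:
        raise ValueError("averaging width must be >= 1")
    n = n_samples or max(int(math.ceil(length_px)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    # unit perpendicular in pixel space
    ur, uc = (c1 - c0) / length_px, -(r1 - r0) / length_px
    offsets = np.arange(width) - (width - 1) / 2.0
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for off in offsets:
        vals = map_coordinates(image, [rows + off * ur, cols + off * uc],
                               order=1, mode="nearest", cval=np.nan)
        good = np.isfinite(vals)
        acc[good] += vals[good]
        cnt[good] += 1
    profile = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return LineProfile(position_um=t * length_px * pixel_size_um,
                       value=profile, p0=tuple(p0), p1=tuple(p1),
                       averaging_width=width)


def _sum_of_gaussians(x, *theta):
    base = theta[-1]
    out = np.full_like(x, base, dtype=float)
    for k in range((len(theta) - 1) // 3):
        a, mu, s = theta[3 * k: 3 * k + 3]
        out += a * np.exp(-((x - mu) ** 2) / (2.0 * s**2))
    return out


def _seed_peaks(x, y, n_peaks):
    """Local maxima above baseline + 3*MAD, strongest first."""
    base = float(np.median(y))
    mad = float(np.median(np.abs(y - base))) or 1e-12
    interior = np.arange(1, x.size - 1)
    is_max = (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1])
    cand = interior[is_max & (y[interior] > base + 3 * mad)]
    cand = cand[np.argsort(y[cand])[::-1]]
    # enforce a minimum separation so one broad peak is not seeded twice
    chosen = []
    min_sep = (x[-1] - x[0]) / (3 * n_peaks) if n_peaks else 0
    for i in cand:
        if all(abs(x[i] - x[j]) > min_sep for j in chosen):
            chosen.append(i)
        if len(chosen) == n_peaks:
            break
    # fall back to evenly spaced seeds if detection came up short
    while len(chosen) < n_peaks:
        k = len(chosen)
        pos = x[0] + (k + 0.5) * (x[-1] - x[0]) / n_peaks
        chosen.append(int(np.argmin(np.abs(x - pos))))
    return chosen, base


def fit_gaussian_peaks(profile: LineProfile, n_peaks: int) -> list:
    """Sum-of-Gaussians + constant-baseline fit of a line profile.

    Returns one dict per peak, ordered by centre, with ``center_um``,
    ``sigma_um``, ``amplitude`` and standard errors; peaks whose fit did
    not converge carry ``converged=False``.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    x = profile.position_um
    y = np.asarray(profile.value, dtype=float)
    good = np.isfinite(y)
    x, y = x[good], y[good]
    if x.size < 3 * n_peaks + 1:
        raise ValueError("profile too short for the requested number of peaks")
    idx, base = _seed_peaks(x, y, n_peaks)
    span = x[-1] - x[0]
    theta0 = []
    for i in idx:
        theta0 += [max(y[i] - base, 1e-12), float(x[i]), span / (6 * n_peaks)]
    theta0.append(base)
    lo = ([0.0, x[0], span / x.size / 4] * n_peaks) + [-np.inf]
    hi = ([np.inf, x[-1], span] * n_peaks) + [np.inf]
    try:
        popt, pcov = curve_fit(_sum_of_gaussians, x, y, p0=theta0,
                               bounds=(lo, hi), max_nfev=20000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
        converged = True
    except (RuntimeError, ValueError):
        popt, perr = np.array(theta0), np.full(len(theta0), np.nan)
        converged = False
    peaks = []
    for k in range(n_peaks):
        a, mu, s = popt[3 * k: 3 * k + 3]
        ea, emu, es = perr[3 * k: 3 * k + 3]
        peaks.append({"amplitude": float(a), "center_um": float(mu),
                      "sigma_um": float(abs(s)), "bse": {
                          "amplitude": float(ea), "center_um": float(emu),
                          "sigma_um": float(es)},
                      "converged": converged})
    peaks.sort(key=lambda d: d["center_um"])
    return peaks


def diffraction_limit(lambda_nm: float, NA: float) -> float:
    """Optical resolution 1.22 λ / (2 NA) in nm."""
    if lambda_nm <= 0 or NA <= 0:
        raise ValueError("wavelength and NA must be positive")
    if NA >= 2:
        raise ValueError("numerical aperture must be below 2")
    return 1.22 * lambda_nm / (2.0 * NA)


def default_psf_sigma_um(lambda_nm: float = 700.0, NA: float = 1.4) -> float:
    """Gaussian PSF σ (µm): diffraction limit treated as FWHM-equivalent."""
    return diffraction_limit(lambda_nm, NA) / 2.3548 * 1e-3
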