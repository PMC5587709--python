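"""Relaxation-rate spectra versus field: assembly, calibration, model fits.

A field sweep of T1 fits becomes a rate spectrum Γ₁(B0).  The intrinsic
(surface-spin) contribution measured in a calibration run is subtracted on
a common field grid to isolate the target spectrum, which is then fitted
with the closed-form Lorentzian

    Γ₁(B0) = (b²/2)(Γ₂+R) / ((Γ₂+R)² + (2πD − (γ_NV+γ_t)B0)²).

Internally the fit is parametrised by the well-scaled triple
(on-resonance amplitude, field half-width ΔB, resonance field B_res),
which is algebraically identical to (b², R, g): at the resonance field the
detuning vanishes by definition, so ΔB = (Γ₂+R)/(γ_NV+γ_t) and
amp = b²/(2(Γ₂+R)).  This guarantees the reported B_res and g always
satisfy the resonance-inversion relation exactly.  Γ₂ is fixed from the
ODMR linewidth rather than fitted — only the sum Γ₂+R enters the shape,
and Γ₂ ≪ R for aqueous targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .containers import RateSpectrum
from .physics import (ProbeModel, g_from_resonance_field, gamma_rad_per_s_G,
                      resonance_field)
from .quantification import h_probe_from_b2
from .relaxometry import T1Map

__all__ = [
    "build_spectrum",
    "subtract_calibration",
    "fit_intrinsic",
    "TargetSpectrumModel",
    "SpectrumFitResults",
    "fit_target_spectrum",
    "per_pixel_g_map",
]


def build_spectrum(sweep_results: Sequence[Tuple[float, object]],
                   provenance: str = "FOV") -> RateSpectrum:
    """Rate spectrum from (B0, T1-fit) pairs.

    Γ₁ = 1/T1 with σ_Γ = σ_T1/T1² propagated from the fit covariance.
    Unconverged fits are dropped; duplicate fields are merged by
    inverse-variance weighting.
    """
    pts = []
    for B0, res in sweep_results:
        if not getattr(res, "converged", True):
            continue
        T1 = res["T1"] if not np.isscalar(res) else float(res)
        sig = getattr(res, "sigma_T1", float("nan"))
        if not np.isfinite(sig) or sig <= 0:
            sig = 0.05 * T1  # conservative placeholder when cov unavailable
        pts.append((float(B0), 1.0 / T1, sig / T1**2))
    if len({b for b, *_ in pts}) < 3:
        raise ValueError("need converged fits at >= 3 distinct fields")
    merged = {}
    for B0, g1, sg in pts:
        merged.setdefault(B0, []).append((g1, sg))
    B = np.array(sorted(merged))
    gamma = np.empty_like(B)
    sigma = np.empty_like(B)
    for i, b in enumerate(B):
        vals = np.array(merged[b])
        w = 1.0 / vals[:, 1] ** 2
        gamma[i] = np.sum(w * vals[:, 0]) / np.sum(w)
        sigma[i] = 1.0 / math.sqrt(np.sum(w))
    return RateSpectrum(B, gamma, sigma, provenance=provenance)


def subtract_calibration(combined: RateSpectrum,
                         calibration: RateSpectrum) -> RateSpectrum:
    """Target spectrum Γ₁^(T) = Γ₁^(I+T) − Γ₁^(I) on the combined grid.

    The calibration is linearly interpolated in B (no extrapolation:
    combined points outside the calibration range are dropped) and the
    variances added.
    """
    lo = max(combined.B0[0], calibration.B0[0])
    hi = min(combined.B0[-1], calibration.B0[-1])
    keep = (combined.B0 >= lo) & (combined.B0 <= hi)
    if not np.any(keep):
        raise ValueError("field ranges of the two spectra do not overlap")
    B = combined.B0[keep]
    cal_g = np.interp(B, calibration.B0, calibration.Gamma1)
    cal_var = np.interp(B, calibration.B0, calibration.sigma_Gamma1**2)
    return RateSpectrum(
        B, combined.Gamma1[keep] - cal_g,
        np.sqrt(combined.sigma_Gamma1[keep] ** 2 + cal_var),
        provenance=combined.provenance)


def _lorentzian_B(B, amp, center, hw, base):
    return base + amp * hw**2 / (hw**2 + (B - center) ** 2)


def fit_intrinsic(calibration: RateSpectrum,
                  probe: Optional[ProbeModel] = None) -> dict:
    """Single-Lorentzian fit of the calibration (intrinsic) spectrum.

    Returns the centre field (G), the half-width converted to angular
    frequency via ΔB·(γ_NV + γ_surface), the amplitude and baseline, plus
    the g-factor implied by the centre.  ``converged`` is False (with NaN
    estimates) if the optimiser fails.
    """
    probe = probe or ProbeModel()
    if len(calibration) < 5:
        raise ValueError("need at least 5 spectrum points")
    B, y, s = calibration.B0, calibration.Gamma1, calibration.sigma_Gamma1
    base0 = float(np.min(y))
    amp0 = float(np.max(y) - base0)
    c0 = float(B[np.argmax(y)])
    above = B[y > base0 + amp0 / 2.0]
    hw0 = max(float(above[-1] - above[0]) / 2.0, float(np.mean(np.diff(B))) / 2) \
        if above.size > 1 else float(np.mean(np.diff(B)))
    try:
        popt, pcov = curve_fit(
            _lorentzian_B, B, y, p0=[amp0, c0, hw0, base0], sigma=s,
            absolute_sigma=True,
            bounds=([0, B[0], 1e-6, -np.inf], [np.inf, B[-1], B[-1] - B[0], np.inf]),
            max_nfev=10000)
    except (RuntimeError, ValueError):
        nan = float("nan")
        return {"amplitude": nan, "center_G": nan, "halfwidth_G": nan,
                "halfwidth_rad_s": nan, "baseline": nan, "g_center": nan,
                "converged": False}
    amp, center, hw, base = popt
    g_c = g_from_resonance_field(center, probe)
    gamma_sum = probe.gamma_NV_rad + gamma_rad_per_s_G(g_c, probe.constants)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return {
        "amplitude": float(amp), "center_G": float(center),
        "halfwidth_G": float(hw), "halfwidth_rad_s": float(hw * gamma_sum),
        "baseline": float(base), "g_center": float(g_c),
        "bse": {"amplitude": perr[0], "center_G": perr[1],
                "halfwidth_G": perr[2], "halfwidth_rad_s": perr[2] * gamma_sum,
                "baseline": perr[3]},
        "converged": True,
    }


@dataclass
class SpectrumFitResults:
    """Fitted target-spectrum parameters and their uncertainties."""

    g_fit: float
    R_fit: float  # rad/s
    b2_fit: float  # rad^2/s^2
    B_res: float  # G
    amp: float  # on-resonance rate, s^-1
    halfwidth_G: float
    bse: dict
    cov: Optional[np.ndarray]  # covariance of (amp, halfwidth_G, B_res)
    converged: bool
    h_probe: Optional[float] = None  # m, when concentration known
    known_concentration: Optional[float] = None
    provenance: str = "FOV"

    def summary(self) -> str:
        rows = [
            f"Target relaxation-spectrum fit ({self.provenance})",
            "=" * 52,
            f"  B_res        {self.B_res:10.2f} G"
            f"   (se {self.bse.get('B_res', float('nan')):.2g})",
            f"  g-factor     {self.g_fit:10.4f}"
            f"     (se {self.bse.get('g_fit', float('nan')):.2g})",
            f"  R            {self.R_fit:10.4g} rad/s"
            f" (se {self.bse.get('R_fit', float('nan')):.2g})",
            f"  b^2          {self.b2_fit:10.4g} rad^2/s^2",
            f"  peak rate    {self.amp:10.4g} s^-1",
        ]
        if self.h_probe is not None:
            rows.append(
                f"  h_probe      {self.h_probe * 1e9:10.3f} nm"
                f"  (from b^2 at C = {self.known_concentration} M;"
                " convention-dependent)")
        rows.append(f"  converged    {self.converged}")
        return "\n".join(rows)


class TargetSpectrumModel:
    """Closed-form Lorentzian model of a target rate spectrum.

    Construct from a :class:`RateSpectrum` (usually calibration-
    subtracted) and ``fit()`` for estimates of the coupling b², the bath
    fluctuation rate R and the g-factor; with a known concentration the
    probe depth follows from b² = 2C/(K·h³).
    """

    def __init__(self, spectrum: RateSpectrum, probe: Optional[ProbeModel] = None,
                 known_concentration: Optional[float] = None):
        if len(spectrum) < 7:
            raise ValueError("need >= 7 spectrum points spanning the peak")
        self.spectrum = spectrum
        self.probe = probe or ProbeModel()
        self.known_concentration = known_concentration

    def _shape(self, B, amp, hw, B_res):
        return amp * hw**2 / (hw**2 + (B - B_res) ** 2)

    def fit(self, R_fixed: Optional[float] = None,
            B_res_bounds: Optional[Tuple[float, float]] = None,
            B_res0: Optional[float] = None) -> SpectrumFitResults:
        """Weighted least squares in (amplitude, half-width, B_res).

        ``R_fixed`` pins the bath rate (hence the half-width up to the
        weak B_res dependence of γ_t), the stabiliser used for per-pixel
        fits; ``B_res_bounds``/``B_res0`` constrain and seed the resonance
        field (per-pixel fits restrict it to the swept range).
        """
        sp, probe = self.spectrum, self.probe
        B, y, s = sp.B0, sp.Gamma1, sp.sigma_Gamma1
        i_pk = int(np.argmax(y))
        B0_guess = float(B_res0) if B_res0 is not None else float(B[i_pk])
        B_lo, B_hi = B_res_bounds if B_res_bounds is not None else (1.0, 1023.0)
        B0_guess = min(max(B0_guess, B_lo), B_hi)
        amp0 = max(float(y[i_pk]), 1e-12)
        if i_pk in (0, len(sp) - 1):
            warnings.warn("spectrum peak lies at the edge of the field range; "
                          "fit may extrapolate", stacklevel=2)

        def hw_of(B_res, R):
            g = g_from_resonance_field(B_res, probe)
            gsum = probe.gamma_NV_rad + gamma_rad_per_s_G(g, probe.constants)
            return (probe.Gamma2 + R) / gsum

        if R_fixed is None:
            above = B[y > amp0 / 2.0]
            hw0 = max(float(above[-1] - above[0]) / 2.0,
                      float(np.mean(np.diff(B)))) if above.size > 1 \
                else float(np.mean(np.diff(B)))
            popt, pcov = curve_fit(
                self._shape, B, y, p0=[amp0, hw0, B0_guess], sigma=s,
                absolute_sigma=True,
                bounds=([0, 1e-3, B_lo], [np.inf, 5 * (B[-1] - B[0]), B_hi]),
                max_nfev=10000)
            amp, hw, B_res = popt
        else:
            def shape_fixed(Bv, amp, B_res):
                return self._shape(Bv, amp, hw_of(B_res, R_fixed), B_res)
            popt, pcov = curve_fit(
                shape_fixed, B, y, p0=[amp0, B0_guess], sigma=s,
                absolute_sigma=True, bounds=([0, B_lo], [np.inf, B_hi]),
                max_nfev=10000)
            amp, B_res = popt
            hw = hw_of(B_res, R_fixed)
            pcov = np.array([[pcov[0, 0], 0.0, pcov[0, 1]],
                             [0.0, 0.0, 0.0],
                             [pcov[1, 0], 0.0, pcov[1, 1]]])

        g = g_from_resonance_field(B_res, probe)
        gamma_sum = probe.gamma_NV_rad + gamma_rad_per_s_G(g, probe.constants)
        width_rad = hw * gamma_sum
        R = width_rad - probe.Gamma2 if R_fixed is None else R_fixed
        b2 = 2.0 * amp * width_rad

        perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
        dg_dB = -probe.D / (probe.constants.mu_B_over_h * B_res**2)
        bse = {
            "amp": perr[0], "halfwidth_G": perr[1], "B_res": perr[2],
            "g_fit": abs(dg_dB) * perr[2],
            "R_fit": gamma_sum * perr[1],
            "b2_fit": 2.0 * math.hypot(width_rad * perr[0],
                                       amp * gamma_sum * perr[1]),
        }
        h = None
        if self.known_concentration is not None and b2 > 0:
            h = h_probe_from_b2(b2, self.known_concentration)
            bse["h_probe"] = h * bse["b2_fit"] / (3.0 * b2)
        return SpectrumFitResults(
            g_fit=float(g), R_fit=float(R), b2_fit=float(b2),
            B_res=float(B_res), amp=float(amp), halfwidth_G=float(hw),
            bse=bse, cov=pcov, converged=True, h_probe=h,
            known_concentration=self.known_concentration,
            provenance=sp.provenance)


def fit_target_spectrum(target: RateSpectrum, probe: Optional[ProbeModel] = None,
                        known_concentration: Optional[float] = None,
                        R_fixed: Optional[float] = None) -> SpectrumFitResults:
    """Convenience wrapper around :class:`TargetSpectrumModel`."""
    return TargetSpectrumModel(target, probe, known_concentration).fit(R_fixed=R_fixed)


def per_pixel_g_map(sweep_maps: Sequence[Tuple[float, T1Map]],
                    probe: Optional[ProbeModel] = None,
                    calibration: Optional[RateSpectrum] = None) -> dict:
    """g-factor image and histogram from a sweep of per-pixel T1 maps.

    The FOV-average spectrum is fitted first; its bath rate R is then
    shared by every pixel (stabilising low-SNR pixels), leaving amplitude
    and resonance field free per pixel.  Pixels without converged T1 fits
    at >= 7 fields, or whose spectrum fit fails, are flagged (NaN) and
    excluded from the mean/SD.
    """
    probe = probe or ProbeModel()
    if len(sweep_maps) < 7:
        raise ValueError("need >= 7 fields for per-pixel spectroscopy")
    shape = sweep_maps[0][1].shape
    B_all = np.array([b for b, _ in sweep_maps])
    order = np.argsort(B_all)
    maps = [sweep_maps[k][1] for k in order]
    B_all = B_all[order]

    gamma = np.stack([1.0 / m.T1 for m in maps])  # (nB, ny, nx), NaN if flagged
    sig = np.stack([m.sigma_T1 / m.T1**2 for m in maps])

    def pixel_spectrum(vals, errs):
        ok = np.isfinite(vals) & np.isfinite(errs) & (errs > 0)
        if ok.sum() < 7:
            return None
        sp = RateSpectrum(B_all[ok], vals[ok], errs[ok], provenance="pixel")
        return subtract_calibration(sp, calibration) if calibration is not None else sp

    # FOV spectrum: inverse-variance mean over converged pixels per field
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        w = 1.0 / sig**2
        w[~np.isfinite(w)] = 0.0
        g_masked = np.where(np.isfinite(gamma), gamma, 0.0)
        fov_gamma = (w * g_masked).sum(axis=(1, 2)) / w.sum(axis=(1, 2))
        fov_sigma = 1.0 / np.sqrt(w.sum(axis=(1, 2)))
    fov_sp = RateSpectrum(B_all, fov_gamma, fov_sigma, provenance="FOV")
    if calibration is not None:
        fov_sp = subtract_calibration(fov_sp, calibration)
    fov_fit = TargetSpectrumModel(fov_sp, probe).fit()

    g_img = np.full(shape, np.nan)
    bounds = (float(B_all[0]), float(B_all[-1]))
    margin = 0.02 * (bounds[1] - bounds[0])
    for i in range(shape[0]):
        for j in range(shape[1]):
            sp = pixel_spectrum(gamma[:, i, j], sig[:, i, j])
            if sp is None:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = TargetSpectrumModel(sp, probe).fit(
                        R_fixed=fov_fit.R_fit, B_res_bounds=bounds,
                        B_res0=fov_fit.B_res)
            except (RuntimeError, ValueError):
                continue
            # flag pixels whose resonance stuck to the swept-range edge
            if res.converged and bounds[0] + margin < res.B_res < bounds[1] - margin:
                g_img[i, j] = res.g_fit
    vals = g_img[np.isfinite(g_img)]
    return {
        "g_image": g_img,
        "g_values": vals,
        "g_mean": float(np.mean(vals)) if vals.size else float("nan"),
        "g_sd": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
        "n_pixels": int(vals.size),
        "fov_fit": fov_fit,
    }
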