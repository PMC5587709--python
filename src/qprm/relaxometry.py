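"""Spin-lattice relaxation fitting: decay curves, T1 maps, contrast images.

An NV ensemble pixel does not relax mono-exponentially: the depth and
local-environment distribution of the probes produces a distribution of
rates, described compactly by the stretched exponential

    y(τ) = A · exp(−(τ/T1)^p) + c,

with amplitude A, spin-lattice time T1, stretch exponent p (p = 1 is a
single exponential) and offset c.  Amplitude and offset are always free
parameters because both drift with field alignment.  The fit is exposed
statsmodels-style: :class:`StretchedExponentialModel` wraps one decay
curve and ``fit()`` returns a results object with estimates, standard
errors and a ``summary()`` table; ``fit_t1_map`` runs it per pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .containers import DecayStack

__all__ = [
    "FitConfig",
    "StretchedExponentialModel",
    "StretchedExponentialResults",
    "T1Map",
    "fit_decay",
    "fit_t1_map",
    "roi_aggregate",
    "single_tau_contrast",
    "choose_tau_sp",
]


def stretched_exp(tau, A, T1, p, c):
    return A * np.exp(-((tau / T1) ** p)) + c


@dataclass
class FitConfig:
    """Knobs of the per-curve and per-map fitting."""

    binning: int = 1
    p_bounds: tuple = (0.3, 2.0)
    max_nfev: int = 5000
    min_snr: float = 3.0  # skip map pixels whose decay span is below this x noise
    poisson_weights: bool = True  # sigma^2 = counts for raw count data

    def __post_init__(self):
        if self.binning < 1:
            raise ValueError("binning factor must be >= 1")
        if not 0 < self.p_bounds[0] < self.p_bounds[1]:
            raise ValueError("invalid stretch-exponent bounds")


@dataclass
class StretchedExponentialResults:
    """Estimates and diagnostics of one stretched-exponential fit."""

    params: dict  # A, T1, p, c_offset
    bse: dict
    cov: Optional[np.ndarray]
    rms: float
    converged: bool
    p_fixed: bool = False
    nobs: int = 0

    def __getitem__(self, key):
        return self.params[key]

    @property
    def T1(self):
        return self.params["T1"]

    @property
    def sigma_T1(self):
        return self.bse.get("T1", float("nan"))

    def summary(self) -> str:
        rows = [
            "Stretched-exponential relaxation fit",
            "=" * 52,
            f"  model: A exp(-(tau/T1)^p) + c    n = {self.nobs}",
            f"  {'param':<9}{'estimate':>14}{'std err':>12}",
        ]
        for name in ("A", "T1", "p", "c_offset"):
            rows.append(f"  {name:<9}{self.params[name]:>14.6g}"
                        f"{self.bse.get(name, float('nan')):>12.3g}")
        rows.append(f"  rms residual {self.rms:.4g}"
                    + ("   [p fixed at 1]" if self.p_fixed else ""))
        rows.append(f"  converged    {self.converged}")
        return "\n".join(rows)


class StretchedExponentialModel:
    """One fluorescence decay curve, ready to fit.

    Poisson weighting (sigma² = counts) is used for raw count data;
    disable it for pre-normalised curves.
    """

    def __init__(self, tau, y, config: Optional[FitConfig] = None):
        self.tau = np.asarray(tau, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.config = config or FitConfig()
        if self.tau.size < 5:
            raise ValueError("need at least 5 evolution-time points")
        if self.tau.shape != self.y.shape:
            raise ValueError("tau and y must have equal length")
        if np.ptp(self.y) == 0:
            raise ValueError("constant decay curve: nothing to fit")

    def _initial_guess(self):
        y, tau = self.y, self.tau
        n_tail = max(1, y.size // 10)
        c0 = float(np.mean(y[-n_tail:]))
        A0 = float(y[0] - c0)
        if A0 <= 0:
            A0 = max(float(np.max(y) - c0), np.ptp(y))
        # first tau where the normalised decay crosses 1/e, by interpolation
        norm = (y - c0) / A0
        below = np.nonzero(norm < 1.0 / math.e)[0]
        if below.size and below[0] > 0:
            i = below[0]
            f = (1.0 / math.e - norm[i - 1]) / (norm[i] - norm[i - 1])
            T10 = float(tau[i - 1] + f * (tau[i] - tau[i - 1]))
        elif below.size:
            T10 = float(tau[0])
        else:
            T10 = float(tau[-1] / 2.0)
        T10 = min(max(T10, tau[0] / 10.0), tau[-1] * 10.0)
        return A0, T10, 1.0, c0

    def fit(self, fix_p: Optional[float] = None) -> StretchedExponentialResults:
        cfg = self.config
        A0, T10, p0, c0 = self._initial_guess()
        sigma = np.sqrt(np.clip(self.y, 1.0, None)) if cfg.poisson_weights else None
        lo_T1, hi_T1 = self.tau[0] / 1e3, self.tau[-1] * 1e3
        ymax = float(np.max(np.abs(self.y))) or 1.0

        def attempt(p_fix):
            if p_fix is None:
                f = stretched_exp
                p_init = [A0, T10, p0, c0]
                bounds = ([0.0, lo_T1, cfg.p_bounds[0], -10 * ymax],
                          [np.inf, hi_T1, cfg.p_bounds[1], 10 * ymax])
            else:
                def f(tau, A, T1, c):
                    return stretched_exp(tau, A, T1, p_fix, c)
                p_init = [A0, T10, c0]
                bounds = ([0.0, lo_T1, -10 * ymax], [np.inf, hi_T1, 10 * ymax])
            popt, pcov = curve_fit(
                f, self.tau, self.y, p0=p_init, sigma=sigma,
                absolute_sigma=cfg.poisson_weights, bounds=bounds,
                max_nfev=cfg.max_nfev)
            return popt, pcov

        p_fixed = fix_p is not None
        try:
            popt, pcov = attempt(fix_p)
        except (RuntimeError, ValueError):
            if fix_p is None:
                # tie-break: one retry as a plain exponential
                try:
                    popt, pcov = attempt(1.0)
                    p_fixed = True
                    fix_p = 1.0
                except (RuntimeError, ValueError):
                    nan = float("nan")
                    return StretchedExponentialResults(
                        params={"A": nan, "T1": nan, "p": nan, "c_offset": nan},
                        bse={}, cov=None, rms=nan, converged=False,
                        nobs=self.tau.size)
            else:
                nan = float("nan")
                return StretchedExponentialResults(
                    params={"A": nan, "T1": nan, "p": fix_p, "c_offset": nan},
                    bse={}, cov=None, rms=nan, converged=False, p_fixed=True,
                    nobs=self.tau.size)

        if p_fixed:
            params = {"A": popt[0], "T1": popt[1], "p": float(fix_p),
                      "c_offset": popt[2]}
            names = ("A", "T1", "c_offset")
        else:
            params = {"A": popt[0], "T1": popt[1], "p": popt[2],
                      "c_offset": popt[3]}
            names = ("A", "T1", "p", "c_offset")
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        bse = dict(zip(names, perr))
        resid = self.y - stretched_exp(self.tau, params["A"], params["T1"],
                                       params["p"], params["c_offset"])
        return StretchedExponentialResults(
            params=params, bse=bse, cov=pcov,
            rms=float(np.sqrt(np.mean(resid**2))), converged=True,
            p_fixed=p_fixed, nobs=self.tau.size)


def fit_decay(tau, y, cfg: Optional[FitConfig] = None,
              fix_p: Optional[float] = None) -> StretchedExponentialResults:
    """Fit one decay curve; see :class:`StretchedExponentialModel`."""
    return StretchedExponentialModel(tau, y, cfg).fit(fix_p=fix_p)


@dataclass
class T1Map:
    """Per-pixel stretched-exponential fit results over an image."""

    A: np.ndarray
    T1: np.ndarray
    p: np.ndarray
    c_offset: np.ndarray
    rms: np.ndarray
    sigma_T1: np.ndarray
    converged: np.ndarray  # bool mask
    B0: float = 0.0
    binning: int = 1
    pixel_size_um: float = 0.1
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.T1.shape

    def fov_T1(self) -> float:
        """Mean T1 over converged pixels (flagged pixels excluded)."""
        return float(np.nanmean(np.where(self.converged, self.T1, np.nan)))


def _bin_frames(frames: np.ndarray, b: int) -> np.ndarray:
    nt, ny, nx = frames.shape
    ny2, nx2 = ny // b, nx // b
    trimmed = frames[:, : ny2 * b, : nx2 * b]
    return trimmed.reshape(nt, ny2, b, nx2, b).sum(axis=(2, 4))


def fit_t1_map(stack: DecayStack, cfg: Optional[FitConfig] = None) -> T1Map:
    """Stretched-exponential fit at every (binned) pixel of a stack.

    Pixels whose decay span is below ``min_snr`` times the shot-noise
    level, or whose fit fails even after the p=1 retry, are flagged and
    excluded from aggregates.
    """
    cfg = cfg or FitConfig()
    frames = _bin_frames(stack.frames, cfg.binning) if cfg.binning > 1 \
        else stack.frames
    _, ny, nx = frames.shape
    out = {k: np.full((ny, nx), np.nan) for k in
           ("A", "T1", "p", "c_offset", "rms", "sigma_T1")}
    converged = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            y = frames[:, i, j]
            span = float(np.ptp(y))
            noise = math.sqrt(max(float(np.mean(y)), 1.0))
            if span == 0 or span < cfg.min_snr * noise:
                continue
            res = StretchedExponentialModel(stack.tau, y, cfg).fit()
            if not res.converged:
                continue
            converged[i, j] = True
            out["A"][i, j] = res.params["A"]
            out["T1"][i, j] = res.params["T1"]
            out["p"][i, j] = res.params["p"]
            out["c_offset"][i, j] = res.params["c_offset"]
            out["rms"][i, j] = res.rms
            out["sigma_T1"][i, j] = res.sigma_T1
    return T1Map(A=out["A"], T1=out["T1"], p=out["p"], c_offset=out["c_offset"],
                 rms=out["rms"], sigma_T1=out["sigma_T1"], converged=converged,
                 B0=stack.B0, binning=cfg.binning,
                 pixel_size_um=stack.pixel_size_um * cfg.binning,
                 meta=dict(stack.meta))


def roi_aggregate(stack: DecayStack, roi) -> np.ndarray:
    """Sum counts over a pixel rectangle per τ point.

    ``roi`` is (row0, row1, col0, col1), half-open, 0-based.  The whole
    image as ROI reproduces the FOV decay curve.
    """
    r0, r1, c0, c1 = roi
    ny, nx = stack.shape
    if not (0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nx):
        raise ValueError(f"ROI {roi} empty or outside the {ny}x{nx} image")
    return stack.frames[:, r0:r1, c0:c1].sum(axis=(1, 2))


def single_tau_contrast(stack: DecayStack, tau_sp: float,
                        reference: np.ndarray) -> np.ndarray:
    """Normalised single-evolution-time image I(τ_sp)/I_ref.

    Lower values mean faster relaxation.  ``tau_sp`` must be one of the
    stack's evolution times (matched within 1e-9 relative); pixels with a
    zero reference are masked as NaN.
    """
    idx = np.nonzero(np.isclose(stack.tau, tau_sp, rtol=1e-9))[0]
    if idx.size == 0:
        raise ValueError(f"tau_sp={tau_sp} is not an evolution time of the stack")
    reference = np.asarray(reference, dtype=float)
    frame = stack.frames[int(idx[0])].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(reference > 0, frame / reference, np.nan)
    return out


def choose_tau_sp(T1_fov: float) -> float:
    """Probe time of the single-τ/two-point schemes: the FOV T1 itself.

    Probing at τ = T1 maximises the sensitivity of the normalised
    intensity to small changes in the relaxation rate.
    """
    if not T1_fov > 0:
        raise ValueError("T1 must be positive")
    return float(T1_fov)
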