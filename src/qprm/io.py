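"""File interchange: TIFF stacks with JSON sidecars, CSV tables, YAML config.

Decay stacks travel as multi-page TIFF (one page per evolution time) plus
a JSON sidecar carrying the τ grid, field, cycle count, seed and a
ground-truth summary when the stack was simulated.  Spectra, traces and
profiles are CSV with unit-suffixed headers.  Run configuration is YAML,
validated against a closed schema: unknown keys are rejected with the path
to the offending entry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import DecayStack, KineticsTrace, RateSpectrum
from .resolution import LineProfile

__all__ = [
    "write_decay_stack", "read_decay_stack",
    "spectrum_to_csv", "spectrum_from_csv",
    "trace_to_csv", "trace_from_csv",
    "profile_to_csv",
    "t1map_to_tiff",
    "ConfigError", "load_config", "save_config", "CONFIG_SCHEMA",
]


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def write_decay_stack(stack: DecayStack, path) -> Path:
    """Multi-page TIFF (one page per τ) + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "tau_s": stack.tau.tolist(),
        "B0_G": stack.B0,
        "N_c": stack.N_c,
        "pixel_size_um": stack.pixel_size_um,
        "seed": stack.meta.get("seed"),
        "truth_summary": stack.meta.get("truth_summary"),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_decay_stack(path) -> DecayStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar(path).read_text())
    return DecayStack(
        tau=np.asarray(meta["tau_s"], dtype=float), frames=frames,
        N_c=int(meta.get("N_c", 1)), B0=float(meta.get("B0_G", 0.0)),
        pixel_size_um=float(meta.get("pixel_size_um", 0.1)),
        meta={k: meta.get(k) for k in ("seed", "truth_summary")},
    )


def spectrum_to_csv(spectrum: RateSpectrum, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "B0_G": spectrum.B0,
        "Gamma1_per_s": spectrum.Gamma1,
        "sigma_Gamma1_per_s": spectrum.sigma_Gamma1,
    }).to_csv(path, index=False)
    return path


def spectrum_from_csv(path, provenance: str = "FOV") -> RateSpectrum:
    df = pd.read_csv(path)
    return RateSpectrum(df["B0_G"].to_numpy(), df["Gamma1_per_s"].to_numpy(),
                        df["sigma_Gamma1_per_s"].to_numpy(), provenance=provenance)


def trace_to_csv(trace: KineticsTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": trace.t, "I_ref": trace.I_ref,
                  "I_sp": trace.I_sp}).to_csv(path, index=False)
    side = {"tau_sp_s": trace.tau_sp}
    for key in ("B_res_G", "gamma_background_per_s", "seed"):
        if key in trace.meta:
            side[key] = trace.meta[key]
    _sidecar(path).write_text(json.dumps(side, indent=1))
    return path


def trace_from_csv(path, tau_sp: float = None) -> KineticsTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if tau_sp is None:
        tau_sp = meta.get("tau_sp_s", 0.0)
    return KineticsTrace(df["t_s"].to_numpy(), df["I_ref"].to_numpy(),
                         df["I_sp"].to_numpy(), tau_sp=float(tau_sp), meta=meta)


def profile_to_csv(profile: LineProfile, path) -> Path:
    path = Path(path)
    pd.DataFrame({"pos_um": profile.position_um,
                  "value": profile.value}).to_csv(path, index=False)
    return path


def t1map_to_tiff(t1map, path) -> Path:
    """T1 map as a 3-channel TIFF (T1 s, stretch p, rms) + CSV summary."""
    path = Path(path)
    channels = np.stack([t1map.T1, t1map.p, t1map.rms]).astype(np.float32)
    tifffile.imwrite(path, channels, photometric="minisblack")
    ok = t1map.converged
    pd.DataFrame({
        "statistic": ["T1_mean_s", "T1_sd_s", "p_mean", "n_converged", "n_pixels"],
        "value": [float(np.nanmean(np.where(ok, t1map.T1, np.nan))),
                  float(np.nanstd(np.where(ok, t1map.T1, np.nan))),
                  float(np.nanmean(np.where(ok, t1map.p, np.nan))),
                  int(ok.sum()), int(ok.size)],
    }).to_csv(path.with_suffix(".csv"), index=False)
    return path


# --- configuration ---------------------------------------------------------

class ConfigError(ValueError):
    """Raised for schema violations, with the path to the offending key."""


#: Closed schema: section -> allowed keys (None = scalar leaf section).
CONFIG_SCHEMA = {
    "physics": {"D_Hz", "g_NV", "Gamma2_rad_s", "h_probe_nm", "contrast_c",
                "mu_B_over_h_MHz_per_G"},
    "mask": {"kind", "shape", "C0_M", "pixel_size_um", "width_um",
             "pitch_um", "text"},
    "acquisition": {"tau_min_s", "tau_max_s", "n_tau", "N_c",
                    "photons_per_pixel_per_cycle", "camera_offset",
                    "psf_sigma_um", "field_gradient"},
    "sweep": {"fields_G", "B_start_G", "B_stop_G", "n_fields"},
    "target": {"g_par", "g_perp", "g_iso", "R_relax_rad_s"},
    "quantification": {"h_probe_nm", "voxel_um"},
    "kinetics": {"enabled", "cu0_M", "ah2_0_M", "k_f", "k_ox", "K_e_M2",
                 "sample_interval_s", "duration_s", "laser_amp",
                 "reaction_start_s"},
    "output_dir": None,
    "seed": None,
    "log_level": None,
}


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")
    for key, val in cfg.items():
        if key not in CONFIG_SCHEMA:
            raise ConfigError(f"unknown configuration key: {key!r}")
        allowed = CONFIG_SCHEMA[key]
        if allowed is None:
            continue
        if not isinstance(val, dict):
            raise ConfigError(f"section {key!r} must be a mapping")
        for sub in val:
            if sub not in allowed:
                raise ConfigError(f"unknown configuration key: {key}.{sub}")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path
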