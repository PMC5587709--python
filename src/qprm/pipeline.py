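"""Seeded end-to-end workflows tying the pipeline stages together.

``run_pipeline`` executes simulate -> fit-t1 -> spectrum -> quantify
(-> kinetics when a trace is present) from one YAML-derived configuration
dict, writing every artifact plus a manifest of SHA-256 hashes so a run is
reproducible from (config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as qio
from .containers import RateSpectrum
from .kinetics import fit_redox_model, trace_to_concentration
from .physics import ProbeModel, SpinSpecies
from .quantification import (QuantParams, Voxel, concentration_from_rate,
                             detection_limit, rate_from_concentration,
                             spins_per_voxel, spins_to_moles)
from .relaxometry import fit_decay, roi_aggregate
from .spectroscopy import (build_spectrum, fit_intrinsic, fit_target_spectrum,
                           subtract_calibration)
from .synth import (AcquisitionConfig, MaskPattern, RedoxConfig, make_mask,
                    simulate_field_sweep, simulate_kinetics)

log = logging.getLogger("qprm")

__all__ = ["run_simulation", "run_pipeline", "probe_from_config"]


def probe_from_config(cfg: dict) -> ProbeModel:
    phys = cfg.get("physics") or {}
    kw = {}
    if "D_Hz" in phys:
        kw["D"] = phys["D_Hz"]
    if "g_NV" in phys:
        kw["g_NV"] = phys["g_NV"]
    if "Gamma2_rad_s" in phys:
        kw["Gamma2"] = phys["Gamma2_rad_s"]
    if "h_probe_nm" in phys:
        kw["h_probe"] = phys["h_probe_nm"] * 1e-9
    if "contrast_c" in phys:
        kw["contrast_c"] = phys["contrast_c"]
    if "mu_B_over_h_MHz_per_G" in phys:
        from .constants import PhysConstants
        kw["constants"] = PhysConstants(mu_B_over_h=phys["mu_B_over_h_MHz_per_G"] * 1e6)
    return ProbeModel(**kw)


def _mask_from_config(cfg: dict) -> MaskPattern:
    m = dict(cfg.get("mask") or {})
    kind = m.pop("kind", "uniform")
    kw = {}
    if "shape" in m:
        kw["shape"] = tuple(m["shape"])
    for src, dst in (("C0_M", "C0"), ("pixel_size_um", "pixel_size_um"),
                     ("width_um", "width_um"), ("pitch_um", "pitch_um"),
                     ("text", "text")):
        if src in m:
            kw[dst] = m[src]
    return make_mask(kind, **kw)


def _acq_from_config(cfg: dict, seed: int) -> AcquisitionConfig:
    a = cfg.get("acquisition") or {}
    tau = np.geomspace(a.get("tau_min_s", 1e-6), a.get("tau_max_s", 3e-3),
                       int(a.get("n_tau", 12)))
    return AcquisitionConfig(
        tau_grid=tau, N_c=int(a.get("N_c", 10_000)),
        photons_per_pixel_per_cycle=a.get("photons_per_pixel_per_cycle", 5.0),
        camera_offset=a.get("camera_offset", 0.0),
        psf_sigma_um=a.get("psf_sigma_um", 305e-3 / 2.3548),
        field_gradient=tuple(a.get("field_gradient", (0.0007, 0.004))),
        seed=seed)


def _target_from_config(cfg: dict) -> SpinSpecies:
    t = cfg.get("target") or {}
    if "g_iso" in t:
        return SpinSpecies(label="target", g_iso=t["g_iso"],
                           R_relax=t.get("R_relax_rad_s", 1.8e9))
    return SpinSpecies(label="target", g_par=t.get("g_par", 2.400),
                       g_perp=t.get("g_perp", 2.099),
                       R_relax=t.get("R_relax_rad_s", 1.8e9))


def _sweep_fields(cfg: dict) -> list:
    s = cfg.get("sweep") or {}
    if "fields_G" in s:
        return [float(b) for b in s["fields_G"]]
    return list(np.linspace(s.get("B_start_G", 420.0), s.get("B_stop_G", 560.0),
                            int(s.get("n_fields", 18))))


def run_simulation(cfg: dict, outdir: Path, seed: int) -> dict:
    """Simulate calibration + target sweeps (and a kinetics trace) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = probe_from_config(cfg)
    mask = _mask_from_config(cfg)
    acq = _acq_from_config(cfg, seed)
    target = _target_from_config(cfg)
    fields = _sweep_fields(cfg)
    if not fields:
        raise ValueError("sweep field list is empty")

    files = {"calibration": [], "combined": []}
    cal_acq = AcquisitionConfig(**{**acq.__dict__, "seed": seed + 1})
    for name, tgt, a in (("calibration", None, cal_acq), ("combined", target, acq)):
        sweep = simulate_field_sweep(fields, mask, probe, tgt, a)
        for k, (B0, stack) in enumerate(sweep):
            path = outdir / f"{name}_{k:03d}.tif"
            qio.write_decay_stack(stack, path)
            files[name].append(str(path))
    log.info("simulated %d fields x 2 sweeps", len(fields))

    kin = cfg.get("kinetics") or {}
    if kin.get("enabled", False):
        redox_kw = {k: kin[k] for k in
                    ("cu0_M", "ah2_0_M", "k_f", "k_ox", "sample_interval_s",
                     "duration_s", "laser_amp", "reaction_start_s") if k in kin}
        if "K_e_M2" in kin:
            redox_kw["K_e"] = kin["K_e_M2"]
        redox = RedoxConfig(**redox_kw)
        quant = QuantParams(h_probe=probe.h_probe, Gamma2=probe.Gamma2,
                            R_relax=target.R_relax)
        trace = simulate_kinetics(
            redox, probe, quant,
            AcquisitionConfig(**{**acq.__dict__, "seed": seed + 2}))
        qio.trace_to_csv(trace, outdir / "trace.csv")
        files["trace"] = str(outdir / "trace.csv")
        (outdir / "trace_truth.json").write_text(json.dumps({
            "cu2_M": trace.meta["cu2_M"].tolist(),
            "gamma_background_per_s": trace.meta["gamma_background_per_s"],
            "tau_sp_s": trace.tau_sp}, indent=1))
    qio.save_config({**cfg, "seed": seed}, outdir / "resolved_config.yaml")
    (outdir / "sim_files.json").write_text(json.dumps(files, indent=1))
    return files


def _fov_spectrum(paths, provenance="FOV") -> RateSpectrum:
    results = []
    for p in paths:
        stack = qio.read_decay_stack(p)
        ny, nx = stack.shape
        curve = roi_aggregate(stack, (0, ny, 0, nx))
        results.append((stack.B0, fit_decay(stack.tau, curve)))
    return build_spectrum(results, provenance=provenance)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: dict, outdir, seed: int = 0, resume: bool = False,
                 make_plots: bool = True) -> dict:
    """Full workflow; returns the report dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = probe_from_config(cfg)

    sim_index = outdir / "sim_files.json"
    if resume and sim_index.exists():
        files = json.loads(sim_index.read_text())
        log.info("resume: reusing simulated inputs")
    else:
        files = run_simulation(cfg, outdir, seed)

    spec_path = outdir / "target_spectrum.csv"
    if resume and spec_path.exists():
        target_sp = qio.spectrum_from_csv(spec_path)
        cal_sp = qio.spectrum_from_csv(outdir / "calibration_spectrum.csv")
    else:
        if not files.get("calibration") or not files.get("combined"):
            raise FileNotFoundError("pipeline needs simulated or user-supplied "
                                    "calibration and combined sweeps")
        cal_sp = _fov_spectrum(files["calibration"])
        comb_sp = _fov_spectrum(files["combined"])
        target_sp = subtract_calibration(comb_sp, cal_sp)
        qio.spectrum_to_csv(cal_sp, outdir / "calibration_spectrum.csv")
        qio.spectrum_to_csv(comb_sp, outdir / "combined_spectrum.csv")
        qio.spectrum_to_csv(target_sp, spec_path)

    qcfg = cfg.get("quantification") or {}
    C_known = (cfg.get("mask") or {}).get("C0_M", 0.1)
    intr = fit_intrinsic(cal_sp, probe)
    fit = fit_target_spectrum(target_sp, probe, known_concentration=C_known)

    h_m = fit.h_probe if fit.h_probe else qcfg.get("h_probe_nm", 6.7) * 1e-9
    vox = Voxel(*(qcfg.get("voxel_um", (1.6, 1.6, 0.01))))
    i_res = int(np.argmin(np.abs(target_sp.B0 - fit.B_res)))
    gamma_res = float(target_sp.Gamma1[i_res])
    sigma_res = float(target_sp.sigma_Gamma1[i_res])
    C_est = concentration_from_rate(gamma_res, h_m, probe.Gamma2, fit.R_fit)
    limit = detection_limit(sigma_res, h_m, probe.Gamma2, fit.R_fit, vox)

    report = {
        "g": fit.g_fit, "g_se": fit.bse.get("g_fit"),
        "B_res_G": fit.B_res,
        "R_rad_s": fit.R_fit, "R_se_rad_s": fit.bse.get("R_fit"),
        "h_probe_nm": h_m * 1e9,
        "intrinsic": {"center_G": intr["center_G"], "g": intr["g_center"],
                      "halfwidth_rad_s": intr["halfwidth_rad_s"]},
        "concentration_M": C_est,
        "spins_per_voxel": spins_per_voxel(max(C_est, 0.0), vox),
        "mol_per_voxel": spins_to_moles(spins_per_voxel(max(C_est, 0.0), vox)),
        "detection_limit": limit,
        "seed": seed,
    }

    trace_csv = files.get("trace")
    if trace_csv and Path(trace_csv).exists():
        trace = qio.trace_from_csv(trace_csv)
        kin = cfg.get("kinetics") or {}
        quant = QuantParams(h_probe=h_m, Gamma2=probe.Gamma2, R_relax=fit.R_fit)
        cu0 = kin.get("cu0_M", 0.05)
        baseline_rate = rate_from_concentration(
            cu0, quant.h_probe, quant.Gamma2, quant.R_relax)
        C_t = trace_to_concentration(
            trace, quant, contrast_c=probe.contrast_c,
            baseline_window_s=kin.get("reaction_start_s", 60.0),
            baseline_rate=baseline_rate)
        kin_fit = fit_redox_model(trace.t, C_t, kin.get("ah2_0_M", 0.05),
                                  K_e=kin.get("K_e_M2", 5e-9),
                                  reaction_start=kin.get("reaction_start_s", 60.0))
        report["kinetics"] = {
            "k_f": kin_fit.k_f, "k_ox": kin_fit.k_ox, "rms_M": kin_fit.rms,
            "min_cu_fraction": float(np.min(C_t) / max(C_t[0], 1e-30)),
        }
        np.savetxt(outdir / "concentration_series.csv",
                   np.column_stack([trace.t, C_t]), delimiter=",",
                   header="t_s,C_M", comments="")

    (outdir / "report.json").write_text(json.dumps(report, indent=1))

    if make_plots:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.errorbar(target_sp.B0, target_sp.Gamma1, target_sp.sigma_Gamma1,
                        fmt="o", ms=3, label="target spectrum")
            Bf = np.linspace(target_sp.B0[0], target_sp.B0[-1], 300)
            ax.plot(Bf, fit.amp * fit.halfwidth_G**2
                    / (fit.halfwidth_G**2 + (Bf - fit.B_res) ** 2), label="fit")
            ax.set_xlabel("B0 (G)")
            ax.set_ylabel(r"$\Gamma_1$ (s$^{-1}$)")
            ax.legend()
            fig.tight_layout()
            fig.savefig(outdir / "spectrum.png", dpi=120)
            plt.close(fig)
        except Exception as exc:  # plotting must never sink the pipeline
            log.warning("plotting failed: %s", exc)

    manifest = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                if p.is_file() and p.name != "manifest.json"}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
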