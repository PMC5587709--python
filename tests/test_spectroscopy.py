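"""Rate spectra: assembly, calibration subtraction, Lorentzian model fits."""

import numpy as np
import pytest

from conftest import fov_spectrum
from qprm import (AcquisitionConfig, RateSpectrum,
                  build_spectrum, fit_intrinsic, fit_t1_map,
                  fit_target_spectrum, make_mask, per_pixel_g_map,
                  resonance_field, simulate_field_sweep, subtract_calibration,
                  target_spectrum, g_from_resonance_field)
from qprm.physics import gamma_rad_per_s_G
from qprm.relaxometry import StretchedExponentialResults


def _fake_fit(T1, sigma):
    return StretchedExponentialResults(
        params={"A": 1.0, "T1": T1, "p": 1.0, "c_offset": 0.0},
        bse={"T1": sigma}, cov=None, rms=0.0, converged=True, nobs=10)


class TestBuildSpectrum:
    def test_rate_conversion_and_propagation(self):
        sweep = [(250.0, _fake_fit(730e-6, 60e-6)),
                 (460.0, _fake_fit(96e-6, 1e-6)),
                 (520.0, _fake_fit(200e-6, 5e-6))]
        sp = build_spectrum(sweep)
        assert sp.Gamma1[0] == pytest.approx(1369.9, rel=1e-4)
        assert sp.Gamma1[1] == pytest.approx(10416.7, rel=1e-4)
        assert sp.sigma_Gamma1[0] == pytest.approx(60e-6 / 730e-6**2, rel=1e-9)

    def test_flat_for_constant_t1(self):
        sp = build_spectrum([(b, _fake_fit(1e-4, 1e-6)) for b in (400., 450., 500.)])
        assert np.ptp(sp.Gamma1) == 0

    def test_duplicates_merged_inverse_variance(self):
        sp = build_spectrum([(450.0, _fake_fit(1e-4, 1e-6)),
                             (450.0, _fake_fit(2e-4, 1e-6)),
                             (460.0, _fake_fit(1e-4, 1e-6)),
                             (470.0, _fake_fit(1e-4, 1e-6))])
        g1, s1 = 1e4, 1e-6 / 1e-8
        g2, s2 = 5e3, 1e-6 / 4e-8
        w1, w2 = 1 / s1**2, 1 / s2**2
        assert sp.B0[0] == 450.0 and len(sp) == 3
        assert sp.Gamma1[0] == pytest.approx((w1 * g1 + w2 * g2) / (w1 + w2))
        assert sp.sigma_Gamma1[0] == pytest.approx((w1 + w2) ** -0.5)

    def test_needs_three_fields(self):
        with pytest.raises(ValueError):
            build_spectrum([(450.0, _fake_fit(1e-4, 1e-6)),
                            (460.0, _fake_fit(1e-4, 1e-6))])


class TestSubtraction:
    def test_self_subtraction_is_zero(self):
        B = np.linspace(400, 560, 17)
        sp = RateSpectrum(B, 1000 + 50 * np.sin(B / 10), np.full(17, 10.0))
        diff = subtract_calibration(sp, sp)
        assert np.all(diff.Gamma1 == 0)
        assert np.allclose(diff.sigma_Gamma1, np.sqrt(2) * 10.0)

    def test_no_overlap_raises(self):
        a = RateSpectrum([400, 410, 420], [1, 1, 1], [0.1] * 3)
        b = RateSpectrum([500, 510, 520], [1, 1, 1], [0.1] * 3)
        with pytest.raises(ValueError):
            subtract_calibration(a, b)

    def test_out_of_range_points_dropped(self):
        a = RateSpectrum(np.arange(400, 480, 10.0), np.ones(8), np.full(8, .1))
        b = RateSpectrum(np.arange(430, 520, 10.0), np.ones(9), np.full(9, .1))
        diff = subtract_calibration(a, b)
        assert diff.B0[0] == 430.0 and diff.B0[-1] == 470.0

    def test_recovers_generator_target_spectrum(self, probe, cu, surface):
        """(intrinsic+Cu) minus intrinsic reproduces the Cu-only truth."""
        mask = make_mask("uniform", shape=(10, 10), C0=0.1)
        fields = list(np.linspace(420, 560, 15))
        acq = AcquisitionConfig(seed=41)
        acq_cal = AcquisitionConfig(seed=42)
        comb = fov_spectrum(simulate_field_sweep(fields, mask, probe, cu, acq))
        cal = fov_spectrum(simulate_field_sweep(fields, mask, probe, None, acq_cal))
        diff = subtract_calibration(comb, cal)
        truth = target_spectrum(diff.B0, cu.with_coupling(
            0.1 * 2 / (4.35e10 * probe.h_probe**3)), probe)
        pulls = (diff.Gamma1 - truth) / diff.sigma_Gamma1
        assert np.mean(np.abs(pulls)) < 3.0


class TestIntrinsicFit:
    def test_noiseless_lorentzian_recovery(self, probe):
        B = np.linspace(504, 518, 40)
        center, hw_G, amp, base = 511.3, 1.715, 3000.0, 1370.0
        y = base + amp * hw_G**2 / (hw_G**2 + (B - center) ** 2)
        fit = fit_intrinsic(RateSpectrum(B, y, np.full(B.size, 5.0)), probe)
        assert fit["center_G"] == pytest.approx(center, abs=1e-3)
        assert fit["halfwidth_G"] == pytest.approx(hw_G, rel=1e-4)
        assert fit["g_center"] == pytest.approx(2.0077, abs=1e-3)
        gamma_sum = probe.gamma_NV_rad + gamma_rad_per_s_G(fit["g_center"])
        assert fit["halfwidth_rad_s"] == pytest.approx(hw_G * gamma_sum, rel=1e-4)

    def test_synthetic_calibration_sweep(self, probe, surface):
        """Simulated calibration peaks at the surface-spin field, 511.3 G."""
        mask = make_mask("uniform", shape=(10, 10), C0=0.0)
        fields = list(np.linspace(505, 517.5, 26))
        acq = AcquisitionConfig(tau_grid=np.geomspace(1e-6, 5e-3, 12),
                                field_gradient=(0, 0), seed=43)
        cal = fov_spectrum(simulate_field_sweep(fields, mask, probe, None, acq))
        fit = fit_intrinsic(cal, probe)
        assert fit["converged"]
        assert fit["center_G"] == pytest.approx(511.3, abs=0.3)
        assert fit["halfwidth_rad_s"] == pytest.approx(60.4e6, rel=0.15)
        assert fit["g_center"] == pytest.approx(2.01, abs=0.02)

    def test_flat_zero_input(self, probe):
        B = np.linspace(480, 540, 13)
        fit = fit_intrinsic(RateSpectrum(B, np.zeros(13), np.full(13, 1.0)), probe)
        assert abs(fit["amplitude"]) < 1.0


class TestTargetFit:
    def test_noiseless_round_trip(self, probe, cu):
        """Exact parameter recovery from a noise-free closed-form spectrum."""
        cu = cu.with_coupling(1.5e13)
        B = np.linspace(400, 575, 36)
        y = target_spectrum(B, cu, probe)
        sp = RateSpectrum(B, y, np.full(B.size, 1e-3))
        fit = fit_target_spectrum(sp, probe)
        assert fit.g_fit == pytest.approx(cu.g_iso, rel=1e-6)
        assert fit.R_fit == pytest.approx(cu.R_relax, rel=1e-6)
        assert fit.b2_fit == pytest.approx(cu.coupling_b2, rel=1e-6)
        assert fit.B_res == pytest.approx(resonance_field(cu.g_iso, probe), rel=1e-9)

    def test_b_res_g_relation_exact(self, probe, cu):
        cu = cu.with_coupling(1e13)
        B = np.linspace(420, 560, 20)
        sp = RateSpectrum(B, target_spectrum(B, cu, probe) + 5.0,
                          np.full(B.size, 20.0))
        fit = fit_target_spectrum(sp, probe)
        assert fit.g_fit == g_from_resonance_field(fit.B_res, probe)

    def test_depth_from_known_concentration(self, probe, cu):
        C = 0.1
        b2 = 2 * C / (4.35e10 * (6.7e-9) ** 3)
        cu = cu.with_coupling(b2)
        B = np.linspace(400, 575, 30)
        sp = RateSpectrum(B, target_spectrum(B, cu, probe),
                          np.full(B.size, 1e-3))
        fit = fit_target_spectrum(sp, probe, known_concentration=C)
        assert fit.h_probe == pytest.approx(6.7e-9, rel=1e-6)

    def test_deconvolution_neglect_small(self, probe, cu):
        """Fitting the closed form to numerically convolved data shifts R < 2%."""
        from qprm import convolved_rate
        cu = cu.with_coupling(1e13)
        B = np.linspace(400, 575, 25)
        y = np.array([convolved_rate(b, cu, probe) for b in B])
        fit = fit_target_spectrum(
            RateSpectrum(B, y, np.full(B.size, 1.0)), probe)
        assert probe.Gamma2 / cu.R_relax < 0.02
        assert fit.R_fit == pytest.approx(cu.R_relax, rel=0.02)

    def test_requires_seven_points(self, probe):
        B = np.linspace(450, 500, 5)
        with pytest.raises(ValueError):
            fit_target_spectrum(RateSpectrum(B, np.ones(5), np.ones(5)), probe)

    def test_edge_peak_warns(self, probe, cu):
        cu = cu.with_coupling(1e13)
        B = np.linspace(500, 600, 11)  # peak at 488 G lies outside
        sp = RateSpectrum(B, target_spectrum(B, cu, probe), np.full(11, 1.0))
        with pytest.warns(UserWarning, match="edge"):
            fit_target_spectrum(sp, probe)


class TestPerPixel:
    def _sweep_maps(self, probe, species, mask, fields, seed, photons=40.0):
        acq = AcquisitionConfig(tau_grid=np.geomspace(1e-6, 3e-3, 10),
                                photons_per_pixel_per_cycle=photons, seed=seed)
        sweep = simulate_field_sweep(fields, mask, probe, species, acq)
        return [(B0, fit_t1_map(st)) for B0, st in sweep]

    def test_cu_histogram_centres_on_truth(self, probe, cu):
        mask = make_mask("uniform", shape=(8, 8), C0=0.1)
        fields = list(np.linspace(420, 560, 15))
        maps = self._sweep_maps(probe, cu, mask, fields, seed=44)
        out = per_pixel_g_map(maps, probe)
        assert out["n_pixels"] >= 50
        assert out["g_mean"] == pytest.approx(2.1993, abs=0.03)
        assert out["g_sd"] < 0.1  # the printed histograms are the 0.03 scale

    def test_calibration_histogram_centres_on_surface_g(self, probe):
        mask = make_mask("uniform", shape=(8, 8), C0=0.0)
        fields = list(np.linspace(506, 517, 15))
        maps = self._sweep_maps(probe, None, mask, fields, seed=45)
        out = per_pixel_g_map(maps, probe)
        assert out["n_pixels"] >= 40
        assert out["g_mean"] == pytest.approx(2.0077, abs=0.01)
        assert out["g_sd"] < 0.02
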