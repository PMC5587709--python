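"""Synthetic-data generator: masks, ground truth, noise model, kinetics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from qprm import (AcquisitionConfig, QuantParams, RedoxConfig,
                  integrate_redox, make_mask, simulate_decay_stack,
                  simulate_field_sweep, simulate_kinetics, truth_from_mask)
from qprm.synth import MaskPattern, apply_field_gradient


class TestMasks:
    def test_grating_geometry(self):
        mask = make_mask("grating", shape=(16, 40), C0=0.1,
                         width_um=0.5, pitch_um=1.0, pixel_size_um=0.1)
        col = mask.concentration_map[0]
        # columns alternate 5 pixels on / 5 off
        assert np.array_equal(col[:10] > 0,
                              [True] * 5 + [False] * 5)
        frac = np.mean(mask.concentration_map > 0)
        assert frac == pytest.approx(0.5, abs=1.0 / 40)  # width/pitch +- 1 px

    def test_grating_rejects_bad_pitch(self):
        with pytest.raises(ValueError):
            make_mask("grating", width_um=1.0, pitch_um=0.5)

    def test_uniform_zero(self):
        mask = make_mask("uniform", shape=(8, 8), C0=0.0)
        assert np.all(mask.concentration_map == 0)

    def test_letters_renders_pattern(self):
        mask = make_mask("letters", text="CU", C0=0.1)
        assert mask.concentration_map.max() == 0.1
        assert 0 < np.mean(mask.concentration_map > 0) < 1
        assert min(mask.shape) >= 8

    def test_mask_validation(self):
        with pytest.raises(ValueError):
            MaskPattern(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            MaskPattern(-np.ones((8, 8)))


class TestTruth:
    def test_zero_mask_is_intrinsic_only(self, probe, cu, surface):
        mask = make_mask("uniform", shape=(8, 8), C0=0.0)
        truth = truth_from_mask(mask, probe, cu, surface, 488.0)
        assert np.all(truth.gamma_target == 0)
        assert np.allclose(truth.Gamma1,
                           truth.gamma_base + truth.gamma_intrinsic)

    def test_off_resonance_t1_scale(self, probe, cu, surface):
        """Far from every resonance the T1 sits at the 730 us background
        scale (the Lorentzian tail of the target still contributes a little
        at a 240 G detuning, so the match is to scale, not exact)."""
        mask = make_mask("uniform", shape=(8, 8), C0=0.1)
        truth = truth_from_mask(mask, probe, cu, surface, 250.0)
        assert np.all(np.abs(truth.T1 - 730e-6) / 730e-6 < 0.15)
        # without the target the background is reproduced to high accuracy
        truth0 = truth_from_mask(mask, probe, None, surface, 250.0)
        assert np.all(np.abs(truth0.T1 - 730e-6) / 730e-6 < 0.01)

    def test_target_term_linear_in_concentration(self, probe, cu, surface):
        m1 = make_mask("uniform", shape=(8, 8), C0=0.05)
        m2 = make_mask("uniform", shape=(8, 8), C0=0.10)
        t1 = truth_from_mask(m1, probe, cu, surface, 470.0)
        t2 = truth_from_mask(m2, probe, cu, surface, 470.0)
        assert np.allclose(t2.gamma_target, 2.0 * t1.gamma_target, rtol=1e-12)

    def test_gradient_map(self):
        B = apply_field_gradient(500.0, (9, 5), (0.001, 0.004))
        assert B.shape == (9, 5)
        assert B[4, 2] == pytest.approx(500.0)
        assert np.ptp(B[4, :]) == pytest.approx(0.5, rel=1e-9)   # 0.1% of 500
        assert np.ptp(B[:, 2]) == pytest.approx(2.0, rel=1e-9)   # 0.4% of 500


class TestDecayStacks:
    def test_noiseless_limit_matches_model(self, probe, cu, surface):
        """At huge N_c the per-pixel counts converge on the stretched exponential."""
        mask = make_mask("uniform", shape=(8, 8), C0=0.1)
        truth = truth_from_mask(mask, probe, cu, surface, 460.0)
        acq = AcquisitionConfig(tau_grid=np.geomspace(1e-6, 2e-3, 8),
                                N_c=10_000_000, photons_per_pixel_per_cycle=5.0,
                                psf_sigma_um=0.0, field_gradient=(0, 0), seed=1)
        stack = simulate_decay_stack(truth, acq)
        c = probe.contrast_c
        tau = acq.tau_grid[:, None, None]
        expected = acq.N_c * 5.0 * ((1 - c) + c * np.exp(-((tau / truth.T1) ** truth.p)))
        assert np.all(np.abs(stack.frames / expected - 1) < 1e-3)

    def test_poisson_variance_over_mean(self, probe, cu, surface):
        """Shot noise: variance/mean ~ 1 per accumulated count (iid pixels)."""
        mask = make_mask("uniform", shape=(40, 50), C0=0.1)
        truth = truth_from_mask(mask, probe, cu, surface, 460.0)
        acq = AcquisitionConfig(tau_grid=np.geomspace(1e-6, 2e-3, 5), N_c=10,
                                psf_sigma_um=0.0, field_gradient=(0, 0), seed=2)
        stack = simulate_decay_stack(truth, acq)
        frame = stack.frames[2]  # fixed tau, 2000 iid replicates
        assert frame.var() / frame.mean() == pytest.approx(1.0, abs=0.1)

    def test_psf_conserves_total_intensity(self, probe, cu, surface):
        mask = make_mask("grating", shape=(16, 40), C0=0.1,
                         width_um=0.5, pitch_um=1.0)
        truth = truth_from_mask(mask, probe, cu, surface, 460.0)
        kw = dict(tau_grid=np.geomspace(1e-6, 2e-3, 6), N_c=10_000_000,
                  field_gradient=(0, 0), seed=3)
        sharp = simulate_decay_stack(truth, AcquisitionConfig(psf_sigma_um=0.0, **kw))
        blurred = simulate_decay_stack(truth, AcquisitionConfig(psf_sigma_um=0.13, **kw))
        assert blurred.frames.sum() == pytest.approx(sharp.frames.sum(), rel=1e-4)

    def test_sharp_edges_without_psf(self, probe, cu, surface):
        mask = make_mask("grating", shape=(8, 20), C0=0.1,
                         width_um=0.5, pitch_um=1.0)
        truth = truth_from_mask(mask, probe, cu, surface, 460.0)
        acq = AcquisitionConfig(tau_grid=np.geomspace(1e-5, 2e-3, 6),
                                N_c=50_000_000, psf_sigma_um=0.0,
                                field_gradient=(0, 0), seed=4)
        stack = simulate_decay_stack(truth, acq)
        late = stack.frames[-2, 0]
        on, off = late[mask.concentration_map[0] > 0], late[mask.concentration_map[0] == 0]
        # binary truth -> exactly two intensity levels, pixel-sharp
        assert on.std() / on.mean() < 1e-3 and off.std() / off.mean() < 1e-3
        assert off.mean() > on.mean()  # target pixels relax faster

    def test_seed_determinism(self, probe, cu, surface, small_acq):
        mask = make_mask("uniform", shape=(8, 8), C0=0.1)
        truth = truth_from_mask(mask, probe, cu, surface, 470.0)
        s1 = simulate_decay_stack(truth, small_acq)
        s2 = simulate_decay_stack(truth, small_acq)
        assert np.array_equal(s1.frames, s2.frames)
        sw1 = simulate_field_sweep([450.0, 490.0], mask, probe, cu, small_acq)
        sw2 = simulate_field_sweep([450.0, 490.0], mask, probe, cu, small_acq)
        for (_, a), (_, b) in zip(sw1, sw2):
            assert np.array_equal(a.frames, b.frames)

    def test_sweep_rejects_empty_fields(self, probe, cu, small_acq):
        mask = make_mask("uniform", shape=(8, 8), C0=0.1)
        with pytest.raises(ValueError):
            simulate_field_sweep([], mask, probe, cu, small_acq)


class TestRedox:
    def test_mass_conservation_against_full_system(self):
        """Cross-check the mass-balance closure with a 3-species integration."""
        cu0, ah2_0, kf, kox = 0.05, 0.05, 2.0, 1.5e-3
        t = np.linspace(0, 3000, 301)
        cu2, ah2 = integrate_redox(cu0, ah2_0, kf, kox, t)

        def rhs(_t, y):
            c2, c1, a = y
            v = kf * c2**2 * a
            return [-2 * v + kox * c1, 2 * v - kox * c1, -v]

        sol = solve_ivp(rhs, (0, 3000), [cu0, 0.0, ah2_0], t_eval=t,
                        rtol=1e-10, atol=1e-13)
        assert np.allclose(cu2, sol.y[0], atol=1e-7)
        assert np.allclose(ah2, sol.y[2], atol=1e-7)
        total = sol.y[0] + sol.y[1]
        assert np.all(np.abs(total - cu0) < 1e-9)

    def test_default_scenario_time_course(self):
        """~60% of the Cu2+ reduced by ~500 s, recovery by 4000 s."""
        r = RedoxConfig()
        t = np.arange(0, 4001, 5.0)
        cu2, _ = integrate_redox(r.cu0_M, r.ah2_0_M, r.k_f, r.k_ox, t,
                                 r.reaction_start_s)
        i500 = np.searchsorted(t, 500 + r.reaction_start_s)
        assert 1 - cu2[i500] / r.cu0_M == pytest.approx(0.6, abs=0.1)
        assert cu2[-1] / r.cu0_M > 0.9

    def test_kf_zero_trace_constant(self, probe):
        redox = RedoxConfig(k_f=0.0, k_ox=0.0, duration_s=600.0, laser_amp=0.0)
        acq = AcquisitionConfig(seed=5)
        trace = simulate_kinetics(redox, probe, QuantParams(), acq)
        y = trace.normalized
        assert np.std(y) / np.mean(y) < 1e-4  # shot noise only

    def test_trace_determinism_and_truth_annotation(self, probe):
        redox = RedoxConfig(duration_s=300.0)
        a = simulate_kinetics(redox, probe, QuantParams(), AcquisitionConfig(seed=6))
        b = simulate_kinetics(redox, probe, QuantParams(), AcquisitionConfig(seed=6))
        assert np.array_equal(a.I_sp, b.I_sp)
        assert "cu2_M" in a.meta and a.meta["cu2_M"].shape == a.t.shape

    def test_reduction_raises_intensity(self, probe):
        """Fewer spins -> slower relaxation -> brighter probe-time image."""
        redox = RedoxConfig(laser_amp=0.0)
        trace = simulate_kinetics(redox, probe, QuantParams(),
                                  AcquisitionConfig(seed=7))
        cu2 = trace.meta["cu2_M"]
        y = trace.normalized
        r = np.corrcoef(cu2, y)[0, 1]
        assert r < -0.99
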