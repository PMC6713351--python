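"""Decay inference: mono-exponential fit, Birge ratio, extended GP model."""

import numpy as np
import pytest
from scipy.optimize import least_squares

import stromalight as sl
from stromalight.errors import PreconditionError


def _flat_noise(sd=1.0):
    return sl.NoiseModel(sigma0=sd, sigma_rate=0.0, sigma_floor=0.0)


class TestMonoExponential:
    def test_noiseless_profile_recovered_sharply(self, noiseless_profile, light_sampler):
        profile, spec = noiseless_profile
        fit = sl.fit_mono_exponential(profile, _flat_noise(1.0), sampler=light_sampler)
        assert abs(fit.l_s - spec.l_s) / spec.l_s < 0.005
        assert fit.birge_ratio < 0.1

    def test_ls_equals_inverse_rate(self, fitted_homogeneous):
        mono = fitted_homogeneous["mono"]
        assert mono.l_s == pytest.approx(1.0 / mono.B)

    def test_recovery_at_snr8(self, fitted_homogeneous):
        mono = fitted_homogeneous["mono"]
        spec = fitted_homogeneous["spec"]
        assert abs(mono.l_s - spec.l_s) / spec.l_s < 0.08
        # homogeneous truth: the mono model is adequate
        assert mono.birge_ratio < 2.0

    def test_posterior_mode_matches_weighted_least_squares(self, noiseless_profile):
        """Low-noise oracle equivalence: MAP vs an independent weighted
        nonlinear least-squares optimizer, within 0.1% per parameter."""
        profile, spec = noiseless_profile
        rng = np.random.default_rng(12)
        a = np.clip(profile.a + rng.normal(0, 0.01, len(profile.a)), 0, None)
        noisy = sl.DepthProfile(z=profile.z, a=a, z_max=profile.z_max)
        noise = _flat_noise(0.01)
        A0, B, C = sl.mono_posterior_mode(noisy, noise)

        def resid(theta):
            return (noisy.a - (theta[0] * np.exp(-theta[1] * noisy.z) + theta[2])) / 0.01

        ref = least_squares(resid, x0=[90.0, 1 / 120.0, 3.0], method="lm").x
        assert abs(A0 - ref[0]) / ref[0] < 1e-3
        assert abs(B - ref[1]) / ref[1] < 1e-3
        assert abs(C - ref[2]) / ref[2] < 1e-3


class TestBirgeRatio:
    def test_unit_weighted_residuals(self):
        resid = np.full(103, 2.0)
        sigma = np.full(103, 2.0)
        assert sl.compute_birge_ratio(resid, sigma, 3) == pytest.approx(103 / 100)

    def test_zero_residuals(self):
        assert sl.compute_birge_ratio(np.zeros(50), np.ones(50), 3) == 0.0

    def test_dof_guard(self):
        with pytest.raises(PreconditionError):
            sl.compute_birge_ratio(np.ones(3), np.ones(3), 3)

    def test_calibration_under_true_model(self):
        """Monte-Carlo oracle: with matched sigma the mean Birge ratio over
        1000 replicates of N=500 sits in [0.95, 1.05]."""
        rng = np.random.default_rng(2024)
        sigma = np.linspace(3.0, 0.5, 500)
        brs = [sl.compute_birge_ratio(rng.normal(0, sigma), sigma, 3)
               for _ in range(1000)]
        assert 0.95 <= np.mean(brs) <= 1.05

    def test_birge_ratio_grows_with_heterogeneity(self, light_sampler):
        """Injecting a mean-free-path deviation of increasing amplitude
        degrades the mono-exponential fit monotonically."""
        medians = []
        for amp in [0.0, 0.4, 0.9, 1.5]:
            brs = []
            for seed in range(3):
                bumps = () if amp == 0 else (
                    sl.DeltaBump(amplitude=amp, z_start=0, z_end=150, taper_um=12),)
                spec = sl.sigma0_for_snr(
                    sl.SimulationSpec(l_s=108.0, z_max=500.0, z_step=2.0,
                                      bumps=bumps, seed=seed), 8.0)
                profile, _ = sl.simulate_profile(spec)
                _, resid = sl.fit_smoothing_spline(profile)
                noise = sl.fit_noise_sd_decay(resid, profile.z,
                                              sampler=light_sampler.with_seed(seed))
                fit = sl.fit_mono_exponential(profile, noise,
                                              sampler=light_sampler.with_seed(seed + 50))
                brs.append(fit.birge_ratio)
            medians.append(np.median(brs))
        assert np.all(np.diff(medians) >= 0)


class TestExtendedDecay:
    def test_control_grid_minimum(self, fitted_homogeneous, hmc_sampler):
        with pytest.raises(PreconditionError):
            sl.fit_extended_decay(
                fitted_homogeneous["profile"], fitted_homogeneous["noise"],
                n_control_points=1, sampler=hmc_sampler)

    def test_homogeneous_consistency_with_mono_fit(self, fitted_homogeneous, hmc_sampler):
        """On mono-exponential truth, the extended fit's deviation field
        concentrates near zero and its l_s agrees with the mono fit."""
        ext = sl.fit_extended_decay(
            fitted_homogeneous["profile"], fitted_homogeneous["noise"],
            sampler=hmc_sampler, mono_fit=fitted_homogeneous["mono"])
        mono = fitted_homogeneous["mono"]
        sd = ext.summaries["l_s"]["sd"]
        assert abs(ext.l_s - mono.l_s) < 4 * max(sd, mono.l_s_sd)
        assert ext.max_abs_delta < 0.15
        q = np.percentile(ext.delta_control_draws, [2.5, 97.5], axis=0)
        assert np.all((q[0] <= 0.0) & (q[1] >= 0.0))

    def test_scar_localized_at_anterior_controls(self, scar_spec, light_sampler, hmc_sampler):
        """A +1.5 deviation below 150 um is flagged by the control points in
        that region and only marginally elsewhere."""
        profile, _ = sl.simulate_profile(scar_spec)
        _, resid = sl.fit_smoothing_spline(profile)
        noise = sl.fit_noise_sd_decay(resid, profile.z,
                                      sampler=light_sampler.with_seed(21))
        mono = sl.fit_mono_exponential(profile, noise,
                                       sampler=light_sampler.with_seed(22))
        assert mono.birge_ratio > 2.0
        ext = sl.fit_extended_decay(profile, noise, sampler=hmc_sampler.with_seed(23),
                                    mono_fit=mono)
        intervals = sl.localize_heterogeneity(ext)
        spacing = ext.grid_spacing
        assert any(lo <= 150.0 and abs(hi - 150.0) <= spacing
                   for lo, hi in intervals)
        # the deviation peaks inside the scar band
        med = ext.delta_median_curve()
        assert ext.curve_z[np.argmax(np.abs(med))] <= 150.0 + spacing
        assert ext.max_abs_delta > 0.5
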