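"""Shared fixtures: light sampler settings and canonical synthetic inputs."""

import numpy as np
import pytest

import stromalight as sl


@pytest.fixture(scope="session")
def light_sampler():
    """Ensemble-sampler settings sized for test-suite turnaround."""
    return sl.SamplerConfig(nwalkers=24, burn=400, draws=400, seed=7)


@pytest.fixture(scope="session")
def hmc_sampler():
    return sl.HMCConfig(seed=7)


@pytest.fixture(scope="session")
def eyebank_spec():
    """Homogeneous profile at the healthy-cornea scale (l_s=108, z_max=480)."""
    return sl.sigma0_for_snr(
        sl.SimulationSpec(l_s=108.0, z_max=480.0, z_step=1.0, seed=42), 8.0)


@pytest.fixture(scope="session")
def noiseless_profile():
    spec = sl.SimulationSpec(l_s=108.0, z_max=480.0, z_step=1.0,
                             sigma0=0.0, sigma_floor=0.0, seed=0)
    profile, truth = sl.simulate_profile(spec)
    return profile, spec


@pytest.fixture(scope="session")
def fitted_homogeneous(eyebank_spec, light_sampler):
    """Profile + spline + noise + mono fit for the homogeneous case, shared
    across tests to avoid refitting."""
    profile, _ = sl.simulate_profile(eyebank_spec)
    smooth, resid = sl.fit_smoothing_spline(profile)
    noise = sl.fit_noise_sd_decay(resid, profile.z, sampler=light_sampler.with_seed(1))
    mono = sl.fit_mono_exponential(profile, noise, sampler=light_sampler.with_seed(2))
    return {"spec": eyebank_spec, "profile": profile, "smooth": smooth,
            "residuals": resid, "noise": noise, "mono": mono}


@pytest.fixture(scope="session")
def scar_spec():
    """Anterior scar: mean-free-path deviation +1.5 for z < 150 um."""
    return sl.sigma0_for_snr(
        sl.SimulationSpec(
            l_s=108.0, z_max=500.0, z_step=2.0, seed=11,
            bumps=(sl.DeltaBump(amplitude=1.5, z_start=0.0, z_end=150.0,
                                taper_um=12.0),),
        ), 8.0)


@pytest.fixture(scope="session")
def flat_stack_spec():
    """Flat-surface, speckle-free stack whose profile is exactly closed-form."""
    return sl.SimulationSpec(
        mode="stack", l_s=108.0, z_max=300.0, z_step=1.0,
        sigma0=0.0, sigma_floor=0.0, lateral_size=48,
        surface_base_slices=30, speckle=None, seed=3)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
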