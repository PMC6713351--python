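"""End-to-end orchestration: stack or profile in, transparency report out.

``run_pipeline`` executes the full decision flow — load, surface detection,
flattening, stroma extraction, depth-profile averaging, spline noise
estimation, SNR gate, mono-exponential fit, Birge-ratio gate, extended fit —
and assembles a :class:`~stromalight.report.TransparencyReport`. Every
stochastic stage draws its seed deterministically from the config seed, so a
fixed config + input reproduces the report exactly.
"""

from __future__ import annotations

import logging
import math
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .decay import (DecayPriors, fit_extended_decay, fit_mono_exponential)
from .mcmc import HMCConfig, SamplerConfig
from .noise import NoisePriors, compute_snr, fit_noise_sd_decay, fit_smoothing_spline
from .report import (Thresholds, TransparencyReport, classify,
                     compute_transparency_metrics, config_hash,
                     localize_heterogeneity)
from .stack import (DepthProfile, compute_depth_profile, detect_surface,
                    extract_stroma, flatten_stack, load_stack)

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_on_profile"]

log = logging.getLogger("stromalight")


class PreprocessingConfig(BaseModel):
    voxel_size_xy: float = Field(1.6, gt=0)
    voxel_size_z: float = Field(1.0, gt=0)
    threshold_quantile: float = Field(0.85, gt=0, lt=1)
    detect_mode: str = "crossing"
    smooth_mode: str = "2d"
    median_window: int = Field(11, ge=1)
    savgol_window: int = Field(31, ge=3)
    savgol_order: int = Field(3, ge=1)
    anterior_offset_um: float = Field(60.0, ge=0)
    posterior_offset_um: float = Field(0.0, ge=0)
    subvoxel: bool = False


class SamplerSettings(BaseModel):
    """Ensemble-sampler settings (noise and mono-exponential stages)."""

    nwalkers: int = Field(32, ge=8)
    burn: int = Field(1000, ge=10)
    draws: int = Field(1000, ge=10)
    rhat_max: float = 1.05
    ess_min: float = 400.0

    def to_config(self, seed: int) -> SamplerConfig:
        return SamplerConfig(
            nwalkers=self.nwalkers, burn=self.burn, draws=self.draws,
            seed=int(seed), rhat_max=self.rhat_max, ess_min=self.ess_min,
        )


class HMCSettings(BaseModel):
    """Gradient-based sampler settings (extended decay stage)."""

    n_chains: int = Field(4, ge=2)
    warmup: int = Field(500, ge=50)
    draws: int = Field(1000, ge=50)
    rhat_max: float = 1.05
    ess_min: float = 400.0

    def to_config(self, seed: int) -> HMCConfig:
        return HMCConfig(
            n_chains=self.n_chains, warmup=self.warmup, draws=self.draws,
            seed=int(seed), rhat_max=self.rhat_max, ess_min=self.ess_min,
        )


class PipelineConfig(BaseModel):
    """Validated configuration of the full analysis flow."""

    input_path: str | None = None
    input_type: str = "auto"  # auto | stack | profile
    preprocessing: PreprocessingConfig = PreprocessingConfig()
    baseline_frac: float = Field(0.1, gt=0, lt=1)
    snr_threshold: float = Field(3.0, ge=0)
    birge_threshold: float = Field(2.0, gt=0)
    delta_threshold: float = Field(0.1, gt=0)
    n_control_points: int = Field(10, ge=4)
    sampler: SamplerSettings = SamplerSettings()
    extended_sampler: HMCSettings = HMCSettings()
    seed: int = 0
    force_extended: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data or {})

    def thresholds(self) -> Thresholds:
        return Thresholds(snr=self.snr_threshold, birge=self.birge_threshold,
                          delta=self.delta_threshold)


def _load_profile(config: PipelineConfig) -> DepthProfile:
    path = Path(config.input_path)
    kind = config.input_type
    if kind == "auto":
        kind = "profile" if path.suffix.lower() == ".csv" else "stack"
    if kind == "profile":
        return DepthProfile.from_csv(path)
    pp = config.preprocessing
    stack = load_stack(path, pp.voxel_size_xy, pp.voxel_size_z)
    return preprocess_stack(stack, pp)


def preprocess_stack(stack, pp: PreprocessingConfig) -> DepthProfile:
    """Surface detection, flattening and stroma extraction down to a profile."""
    t0 = time.perf_counter()
    surface = detect_surface(
        stack,
        threshold_quantile=pp.threshold_quantile,
        median_window=pp.median_window,
        savgol_window=pp.savgol_window,
        savgol_order=pp.savgol_order,
        mode=pp.detect_mode,
        smooth_mode=pp.smooth_mode,
    )
    flat = flatten_stack(stack, surface, subvoxel=pp.subvoxel)
    stroma = extract_stroma(flat, pp.anterior_offset_um, pp.posterior_offset_um)
    profile = compute_depth_profile(stroma)
    log.info("preprocessing done in %.2fs (%d stromal slices)",
             time.perf_counter() - t0, len(profile.z))
    return profile


def run_pipeline_on_profile(profile: DepthProfile, config: PipelineConfig) -> TransparencyReport:
    """Statistical stages only (noise model onward) on an existing profile."""
    thresholds = config.thresholds()
    provenance = {
        "config_hash": config_hash(config.model_dump()),
        "seed": config.seed,
        "version": __version__,
        "thresholds": {"snr": thresholds.snr, "birge": thresholds.birge,
                       "delta": thresholds.delta},
        "gates": {},
    }
    seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)

    smooth, residuals = fit_smoothing_spline(profile)
    snr = compute_snr(profile, residuals, smooth, baseline_frac=config.baseline_frac)
    provenance["gates"]["snr"] = snr
    if snr < thresholds.snr:
        log.info("SNR %.2f below gate %.2f: insufficient signal", snr, thresholds.snr)
        return TransparencyReport(
            l_s=None, l_s_sd=None, z_max=profile.z_max, depth_ratio=None,
            transmitted_fraction=None, snr=snr, birge_ratio=None,
            classification="insufficient_signal", provenance=provenance,
        )

    noise = fit_noise_sd_decay(residuals, profile.z,
                               sampler=SamplerConfig(
                                   nwalkers=config.sampler.nwalkers,
                                   burn=config.sampler.burn,
                                   draws=config.sampler.draws,
                                   seed=int(seeds[0]),
                                   rhat_max=config.sampler.rhat_max,
                                   ess_min=config.sampler.ess_min))
    noise.snr = snr
    mono = fit_mono_exponential(profile, noise,
                                sampler=config.sampler.to_config(seeds[1]))
    provenance["gates"]["birge_ratio"] = mono.birge_ratio
    log.info("mono-exponential fit: l_s=%.1f um, b_r=%.2f", mono.l_s, mono.birge_ratio)

    extended = None
    intervals: list = []
    max_abs_delta = None
    if mono.birge_ratio >= thresholds.birge or config.force_extended:
        extended = fit_extended_decay(
            profile, noise, n_control_points=config.n_control_points,
            sampler=config.extended_sampler.to_config(seeds[2]), mono_fit=mono)
        max_abs_delta = extended.max_abs_delta
        log.info("extended fit: max|dls|=%.3f", max_abs_delta)

    classification = classify(
        snr, mono.birge_ratio,
        max_abs_delta if max_abs_delta is not None else 0.0,
        thresholds,
    )
    l_s = mono.l_s if extended is None or classification == "homogeneous" else extended.l_s
    l_s_sd = mono.l_s_sd if extended is None or classification == "homogeneous" \
        else extended.summaries["l_s"]["sd"]
    if classification == "heterogeneous":
        intervals = localize_heterogeneity(extended, min_effect=thresholds.delta)

    ratio, T = compute_transparency_metrics(l_s, profile.z_max)
    assert T == math.exp(-ratio)
    return TransparencyReport(
        l_s=l_s, l_s_sd=l_s_sd, z_max=profile.z_max,
        depth_ratio=ratio, transmitted_fraction=T,
        snr=snr, birge_ratio=mono.birge_ratio,
        classification=classification,
        heterogeneity_intervals=intervals,
        max_abs_delta=max_abs_delta,
        provenance=provenance,
    )


def run_pipeline(config: PipelineConfig) -> TransparencyReport:
    """Full flow from the configured input file (TIFF stack or profile CSV)."""
    if not config.input_path:
        raise ValueError("config.input_path is required")
    if not Path(config.input_path).exists():
        raise IOError(f"input not found: {config.input_path}")
    profile = _load_profile(config)
    return run_pipeline_on_profile(profile, config)
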