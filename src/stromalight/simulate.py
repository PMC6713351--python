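"""Synthetic depth profiles and image stacks with known ground truth.

The generator emulates what the analysis consumes: a mean-amplitude depth
profile following the (optionally depth-corrected) exponential decay

    A(z) = A0 * exp(-z / (l_s (1 + dls(z)))) + C

with additive zero-mean Gaussian noise whose SD decays exponentially with
depth, sigma(z) = sigma0 exp(-sigma_rate z) + sigma_floor. In stack mode it
builds a full 3-D volume: a tilted/curved bright epithelial band sits on
top of the stroma, per-voxel multiplicative speckle (unit-mean gamma) is
applied, and optional hyperreflective scar layers multiply the stromal
amplitude over a depth band. Everything is deterministic given the seed and
the ground truth is returned alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import PreconditionError
from .stack import CorneaStack, DepthProfile

__all__ = [
    "DeltaBump",
    "ScarLayer",
    "SimulationSpec",
    "simulate_profile",
    "simulate_stack",
    "sigma0_for_snr",
]


@dataclass
class DeltaBump:
    """One smooth window of mean-free-path deviation: dls = amplitude inside
    [z_start, z_end], tapering to 0 over ``taper_um`` at each edge."""

    amplitude: float
    z_start: float
    z_end: float
    taper_um: float = 15.0

    def __call__(self, z: np.ndarray) -> np.ndarray:
        t = max(self.taper_um, 1e-6)
        rise = 1.0 / (1.0 + np.exp(-(z - self.z_start) / t))
        fall = 1.0 / (1.0 + np.exp((z - self.z_end) / t))
        if self.z_start <= 0:
            rise = np.ones_like(z)
        return self.amplitude * rise * fall


@dataclass
class ScarLayer:
    """Hyperreflective stromal band: amplitude multiplied by ``factor`` in
    [z_start, z_end] (logistic taper at the edges)."""

    z_start: float
    z_end: float
    factor: float = 3.0
    taper_um: float = 10.0

    def gain(self, z: np.ndarray) -> np.ndarray:
        t = max(self.taper_um, 1e-6)
        rise = 1.0 / (1.0 + np.exp(-(z - self.z_start) / t))
        fall = 1.0 / (1.0 + np.exp((z - self.z_end) / t))
        return 1.0 + (self.factor - 1.0) * rise * fall


@dataclass
class SimulationSpec:
    """Ground-truth parameters for a synthetic profile or stack."""

    mode: str = "profile"            # "profile" | "stack"
    A0: float = 100.0
    C: float = 5.0
    l_s: float = 108.0               # um
    z_max: float = 480.0             # um (stromal thickness)
    z_step: float = 1.0              # um per slice
    bumps: tuple = ()                # DeltaBump ground-truth dls(z)
    sigma0: float = 8.0
    sigma_rate: float = 1.0 / 200.0  # 1/um
    sigma_floor: float = 0.2
    seed: int = 0
    # stack-only geometry
    lateral_size: int = 64
    voxel_size_xy: float = 12.2      # um/px (desk-scale field of view)
    surface_base_slices: int = 30
    tilt_x_slices: float = 0.0
    tilt_y_slices: float = 0.0
    curvature_slices: float = 0.0
    quantize_surface: bool = True
    epithelium_um: float = 50.0
    epithelium_factor: float = 2.0
    speckle: str | None = None       # None | "gamma"
    speckle_shape: float = 25.0      # mean/SD^2 of unit-mean gamma; SNR=sqrt(shape)
    slice_noise_cv: float = 0.0      # per-slice common gain fluctuation (CV)
    background: float = 0.0
    scar_layers: tuple = ()

    def __post_init__(self):
        if self.mode not in ("profile", "stack"):
            raise PreconditionError("mode must be 'profile' or 'stack'")
        if min(self.A0, self.l_s, self.z_max, self.z_step) <= 0 or self.C < 0:
            raise PreconditionError("amplitudes and scales must be positive")
        if self.sigma0 < 0 or self.sigma_rate < 0 or self.sigma_floor < 0:
            raise PreconditionError("noise parameters must be non-negative")
        if self.mode == "stack" and self.lateral_size < 16:
            raise PreconditionError("stack lateral size must be >= 16")
        z = self.z_grid()
        if np.min(1.0 + self.delta_ls(z)) <= 0:
            raise PreconditionError("1 + dls(z) must stay positive")

    def z_grid(self) -> np.ndarray:
        n = int(round(self.z_max / self.z_step))
        return np.arange(n) * self.z_step

    def delta_ls(self, z: np.ndarray) -> np.ndarray:
        d = np.zeros_like(np.asarray(z, float))
        for bump in self.bumps:
            d = d + bump(z)
        return d

    def signal(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        gain = np.ones_like(z)
        for scar in self.scar_layers:
            gain = gain * scar.gain(z)
        return gain * self.A0 * np.exp(-z / (self.l_s * (1.0 + self.delta_ls(z)))) + self.C

    def sigma(self, z: np.ndarray) -> np.ndarray:
        return self.sigma0 * np.exp(-self.sigma_rate * np.asarray(z, float)) + self.sigma_floor

    def ground_truth(self) -> dict:
        z = self.z_grid()
        d = dataclasses.asdict(self)
        d["bumps"] = [dataclasses.asdict(b) for b in self.bumps]
        d["scar_layers"] = [dataclasses.asdict(s) for s in self.scar_layers]
        d["n_points"] = len(z)
        return d


def sigma0_for_snr(spec: SimulationSpec, snr_target: float,
                   baseline_frac: float = 0.1) -> SimulationSpec:
    """Return a copy of ``spec`` with sigma0 set so the generated profile has
    the requested SNR under the pipeline's definition (mean signal above the
    terminal plateau over mean absolute residual)."""
    if snr_target <= 0:
        raise PreconditionError("snr_target must be positive")
    z = spec.z_grid()
    s = spec.signal(z)
    k = max(1, int(round(baseline_frac * len(z))))
    signal_mean = float(np.mean(s - np.mean(s[-k:])))
    target_mean_abs = signal_mean / snr_target
    mean_sigma = target_mean_abs / np.sqrt(2.0 / np.pi)
    decay_mean = float(np.mean(np.exp(-spec.sigma_rate * z)))
    sigma0 = (mean_sigma - spec.sigma_floor) / decay_mean
    if sigma0 <= 0:
        raise PreconditionError("sigma_floor alone already exceeds the target noise")
    return dataclasses.replace(spec, sigma0=float(sigma0))


def simulate_profile(spec: SimulationSpec) -> tuple[DepthProfile, dict]:
    """Draw one noisy depth profile; deterministic given ``spec.seed``."""
    if spec.mode != "profile":
        raise PreconditionError("spec.mode must be 'profile'")
    rng = np.random.default_rng(spec.seed)
    z = spec.z_grid()
    a = spec.signal(z) + rng.normal(0.0, spec.sigma(z))
    a = np.clip(a, 0.0, None)
    profile = DepthProfile(z=z, a=a, z_max=len(z) * spec.z_step)
    return profile, spec.ground_truth()


def _surface_positions(spec: SimulationSpec) -> np.ndarray:
    n = spec.lateral_size
    gx = np.arange(n) / max(n - 1, 1)
    gy = np.arange(n) / max(n - 1, 1)
    X, Y = np.meshgrid(gx, gy)
    r2 = (X - 0.5) ** 2 + (Y - 0.5) ** 2
    pos = (spec.surface_base_slices
           + spec.tilt_x_slices * X
           + spec.tilt_y_slices * Y
           + spec.curvature_slices * r2 / 0.5)
    if spec.quantize_surface:
        pos = np.rint(pos)
    return pos


def simulate_stack(spec: SimulationSpec) -> tuple[CorneaStack, dict]:
    """Build a full synthetic volume with surface geometry, epithelium band,
    speckle, and the stromal decay signal; also returns the ground truth
    (including the true surface map under key ``"surface_positions"``)."""
    if spec.mode != "stack":
        raise PreconditionError("spec.mode must be 'stack'")
    rng = np.random.default_rng(spec.seed)
    vz = spec.z_step
    epi_slices = int(round(spec.epithelium_um / vz))
    z = spec.z_grid()
    stromal = spec.signal(z)
    epi_amp = spec.epithelium_factor * float(stromal[0])

    surface = _surface_positions(spec)
    n_stroma = len(z)
    nz = int(np.ceil(surface.max())) + epi_slices + n_stroma
    # template profile indexed by depth relative to the surface
    template = np.full(nz + 1, spec.background)
    template[:epi_slices] = epi_amp
    template[epi_slices:epi_slices + n_stroma] = stromal
    template[epi_slices + n_stroma:] = spec.background

    rel = np.arange(nz)[:, None, None] - surface[None, :, :]
    rel_idx = np.clip(np.rint(rel).astype(int), -1, nz)
    vol = np.where(rel_idx < 0, spec.background,
                   template[np.clip(rel_idx, 0, nz)])

    if spec.speckle == "gamma":
        shape = spec.speckle_shape
        tissue = rel_idx >= 0
        gain = rng.gamma(shape, 1.0 / shape, size=vol.shape)
        vol = np.where(tissue, vol * gain, vol)
    elif spec.speckle is not None:
        raise PreconditionError(f"unknown speckle model {spec.speckle!r}")

    if spec.slice_noise_cv > 0:
        # common per-slice gain fluctuation (illumination / interferometric
        # drift and laterally correlated speckle); unlike per-voxel speckle
        # it does not average away over the field of view
        gains = 1.0 + spec.slice_noise_cv * rng.standard_normal(nz)
        vol = vol * np.clip(gains, 0.05, None)[:, None, None]

    stack = CorneaStack(vol.astype(np.float32), spec.voxel_size_xy, vz)
    truth = spec.ground_truth()
    truth["surface_positions"] = surface.tolist()
    truth["epithelium_slices"] = epi_slices
    return stack, truth


def save_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=float)
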