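"""Stack preprocessing: load, surface detection, flattening, stroma extraction.

A depth-resolved amplitude volume (e.g. from full-field OCT) is reduced to a
one-dimensional mean-amplitude depth profile in four steps:

1. :func:`load_stack` reads a multi-page TIFF into a :class:`CorneaStack`.
2. :func:`detect_surface` finds the bright epithelial surface in every
   lateral column and smooths the resulting height map (median +
   Savitzky-Golay filters).
3. :func:`flatten_stack` shifts each column so the surface sits at slice 0.
4. :func:`extract_stroma` + :func:`compute_depth_profile` cut the stromal
   sub-volume and average each en-face slice into the depth profile that all
   downstream statistics operate on.

Axis convention: ``volume[z, y, x]`` with z increasing from anterior (toward
the light source) to posterior. Out-of-range voxels created by flattening are
marked NaN and excluded from averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .errors import DetectionError, FormatError, PreconditionError, RangeError

__all__ = [
    "CorneaStack",
    "SurfaceMap",
    "DepthProfile",
    "load_stack",
    "save_stack",
    "detect_surface",
    "flatten_stack",
    "extract_stroma",
    "compute_depth_profile",
]

log = logging.getLogger("stromalight")

MIN_SLICES = 16
MIN_LATERAL = 16


@dataclass
class CorneaStack:
    """3-D amplitude volume with voxel geometry.

    ``volume`` is float, shape (n_slices, ny, nx), values >= 0 (NaN marks
    voxels excluded by flattening). ``voxel_size_xy`` is um/pixel laterally,
    ``voxel_size_z`` um/slice axially.
    """

    volume: np.ndarray
    voxel_size_xy: float
    voxel_size_z: float

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got {self.volume.ndim}-D")
        nz, ny, nx = self.volume.shape
        if nz < MIN_SLICES or ny < MIN_LATERAL or nx < MIN_LATERAL:
            raise FormatError(
                f"volume too small ({nz}x{ny}x{nx}); need >= {MIN_SLICES} slices "
                f"and {MIN_LATERAL}x{MIN_LATERAL} pixels"
            )
        if self.voxel_size_xy <= 0 or self.voxel_size_z <= 0:
            raise FormatError("voxel sizes must be positive")
        if np.nanmin(self.volume) < 0:
            raise FormatError("negative amplitude values; refusing to clamp silently")

    @property
    def n_slices(self) -> int:
        return self.volume.shape[0]

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return self.volume.shape[1:]


@dataclass
class SurfaceMap:
    """Per-column z-position of the corneal surface (possibly fractional)."""

    positions: np.ndarray  # (ny, nx), NaN = undetected column
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2:
            raise FormatError("surface map must be 2-D")


@dataclass
class DepthProfile:
    """Mean amplitude vs stromal depth.

    ``z`` in um, 0 at the anterior stromal boundary, strictly increasing and
    uniformly spaced; ``z_max`` is the total thickness spanned, defined as
    ``n_slices * z_step`` (half-open slice bins, so z_max = z[-1] + z_step).
    """

    z: np.ndarray
    a: np.ndarray
    z_max: float
    n_pixels_averaged: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.a.shape:
            raise FormatError("z and a must be 1-D arrays of equal length")
        if len(self.z) < 2:
            raise FormatError("profile needs at least 2 points")
        dz = np.diff(self.z)
        if np.any(dz <= 0) or not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-9):
            raise FormatError("z must be strictly increasing and uniformly spaced")
        if not np.all(np.isfinite(self.a)) or np.any(self.a < 0):
            raise FormatError("amplitudes must be finite and non-negative")

    @property
    def z_step(self) -> float:
        return float(self.z[1] - self.z[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"z_um": self.z, "amplitude": self.a}).to_csv(
            path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "DepthProfile":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"z_um", "amplitude"} <= set(df.columns):
            raise FormatError("profile CSV needs columns z_um, amplitude")
        z = df["z_um"].to_numpy(float)
        a = df["amplitude"].to_numpy(float)
        z_max = float(z[-1] - z[0] + (z[1] - z[0]))
        return cls(z=z - z[0], a=a, z_max=z_max)


def load_stack(path, voxel_size_xy: float, voxel_size_z: float) -> CorneaStack:
    """Read a multi-page TIFF into a :class:`CorneaStack` (no rescaling)."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        volume = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise IOError(f"could not decode {path}: {exc}") from exc
    return CorneaStack(np.asarray(volume), voxel_size_xy, voxel_size_z)


def save_stack(stack: CorneaStack, path) -> None:
    import tifffile

    tifffile.imwrite(path, stack.volume.astype(np.float32))


def detect_surface(
    stack: CorneaStack,
    threshold_quantile: float = 0.85,
    median_window: int = 11,
    savgol_window: int = 31,
    savgol_order: int = 3,
    mode: str = "crossing",
    smooth_mode: str = "2d",
    min_valid_fraction: float = 0.5,
    max_jump: float = 10.0,
) -> SurfaceMap:
    """Locate the bright corneal surface in every lateral column.

    Each column is thresholded at its own amplitude quantile; the surface is
    the first upward threshold crossing (``mode="crossing"``, default) or the
    first supra-threshold local maximum (``mode="local_max"``). The raw
    height map is then median-filtered and Savitzky-Golay smoothed, either
    over the full 2-D lateral field (default) or per cross-sectional row
    (``smooth_mode="per_row"``).
    """
    if not 0 < threshold_quantile < 1:
        raise PreconditionError("threshold_quantile must be in (0, 1)")
    if savgol_window % 2 == 0 or savgol_window <= savgol_order:
        raise PreconditionError("savgol_window must be odd and > savgol_order")
    ny, nx = stack.lateral_shape
    if savgol_window > min(ny, nx):
        raise PreconditionError("savgol_window larger than the lateral field")

    vol = stack.volume
    thr = np.nanquantile(vol, threshold_quantile, axis=0)  # (ny, nx)
    above = vol > thr[None, :, :]
    if mode == "local_max":
        interior = np.zeros_like(above)
        interior[1:-1] = (vol[1:-1] >= vol[:-2]) & (vol[1:-1] >= vol[2:])
        interior[0] = vol[0] >= vol[1]
        interior[-1] = vol[-1] >= vol[-2]
        candidate = above & interior
    elif mode == "crossing":
        candidate = above
    else:
        raise PreconditionError(f"unknown detection mode {mode!r}")

    found = candidate.any(axis=0)
    raw = np.argmax(candidate, axis=0).astype(float)
    raw[~found] = np.nan

    valid_frac = found.mean()
    if valid_frac < min_valid_fraction:
        raise DetectionError(
            f"surface detected in only {100 * valid_frac:.0f}% of columns "
            f"(need >= {100 * min_valid_fraction:.0f}%)"
        )
    if not found.all():
        raw[~found] = np.nanmedian(raw)

    med = min(median_window, min(ny, nx))
    smoothed = median_filter(raw, size=med, mode="nearest")
    if smooth_mode == "2d":
        smoothed = savgol_filter(smoothed, savgol_window, savgol_order,
                                 axis=0, mode="interp")
        smoothed = savgol_filter(smoothed, savgol_window, savgol_order,
                                 axis=1, mode="interp")
    elif smooth_mode == "per_row":
        smoothed = savgol_filter(smoothed, savgol_window, savgol_order,
                                 axis=1, mode="interp")
    else:
        raise PreconditionError(f"unknown smooth_mode {smooth_mode!r}")
    smoothed = np.clip(smoothed, 0, stack.n_slices - 1)

    jump = max(
        np.nanmax(np.abs(np.diff(smoothed, axis=0)), initial=0.0),
        np.nanmax(np.abs(np.diff(smoothed, axis=1)), initial=0.0),
    )
    if jump > max_jump:
        warnings.warn(
            f"smoothed surface has neighbor jumps up to {jump:.1f} slices",
            stacklevel=2,
        )
    meta = {
        "threshold_quantile": threshold_quantile,
        "median_window": median_window,
        "savgol_window": savgol_window,
        "savgol_order": savgol_order,
        "mode": mode,
        "smooth_mode": smooth_mode,
        "valid_fraction": float(valid_frac),
    }
    return SurfaceMap(positions=smoothed, metadata=meta)


def flatten_stack(
    stack: CorneaStack, surface: SurfaceMap, subvoxel: bool = False
) -> CorneaStack:
    """Shift each lateral column so the detected surface lies at slice 0.

    Integer shifts by default (sub-voxel linear interpolation behind the
    ``subvoxel`` flag); vacated voxels become NaN and are excluded from all
    later averages. Columns with NaN surface positions are fully excluded.
    """
    pos = surface.positions
    if pos.shape != stack.lateral_shape:
        raise PreconditionError("surface map does not match stack lateral shape")
    nz = stack.n_slices
    with np.errstate(invalid="ignore"):
        if np.nanmin(pos) < 0 or np.nanmax(pos) > nz - 1:
            raise PreconditionError("surface positions outside stack depth range")

    out = np.full_like(stack.volume, np.nan)
    nan_cols = ~np.isfinite(pos)
    if nan_cols.any():
        log.warning("flatten: excluding %d columns with undetected surface",
                    int(nan_cols.sum()))

    if subvoxel:
        zi = np.arange(nz, dtype=float)
        vol = stack.volume
        ny, nx = stack.lateral_shape
        for iy in range(ny):
            for ix in range(nx):
                if nan_cols[iy, ix]:
                    continue
                src = zi + pos[iy, ix]
                col = np.interp(src, zi, vol[:, iy, ix], left=np.nan, right=np.nan)
                col[src > nz - 1] = np.nan
                out[:, iy, ix] = col
    else:
        shifts = np.rint(np.where(nan_cols, 0.0, pos)).astype(int)
        shifts[nan_cols] = -1
        emptied = shifts >= nz
        if emptied.any():
            log.warning("flatten: %d columns emptied by their shift",
                        int(emptied.sum()))
            shifts[emptied] = -1
        for s in np.unique(shifts):
            if s < 0:
                continue
            mask = shifts == s
            out[: nz - s, mask] = stack.volume[s:, mask]

    return CorneaStack(out, stack.voxel_size_xy, stack.voxel_size_z)


def extract_stroma(
    stack: CorneaStack,
    anterior_offset_um: float = 60.0,
    posterior_offset_um: float = 0.0,
    min_valid_fraction: float = 0.5,
) -> CorneaStack:
    """Cut the stromal sub-volume from a flattened stack.

    The anterior boundary is ``anterior_offset_um`` below the (flattened)
    surface — by default 60 um, a typical epithelium + Bowman's layer — and
    the posterior boundary is ``posterior_offset_um`` above the deepest slice
    that still has at least ``min_valid_fraction`` valid (non-NaN) pixels.
    Depth origin is reset to 0 at the anterior stromal boundary.
    """
    if anterior_offset_um < 0 or posterior_offset_um < 0:
        raise PreconditionError("offsets must be non-negative")
    vz = stack.voxel_size_z
    start = int(round(anterior_offset_um / vz))
    valid = np.isfinite(stack.volume).mean(axis=(1, 2))
    usable = np.flatnonzero(valid >= min_valid_fraction)
    if len(usable) == 0:
        raise RangeError("no slice has enough valid pixels")
    deepest = usable[-1]
    stop = deepest + 1 - int(round(posterior_offset_um / vz))
    if stop - start < 2:
        raise RangeError(
            f"offsets leave no stromal depth range (start={start}, stop={stop})"
        )
    return CorneaStack(stack.volume[start:stop], stack.voxel_size_xy, vz)


def compute_depth_profile(stack: CorneaStack) -> DepthProfile:
    """Average each en-face slice into the mean-amplitude depth profile.

    ``a[k]`` is the mean over valid (non-NaN) lateral pixels of slice k and
    ``z[k] = k * voxel_size_z``. The profile is truncated at the first slice
    with zero valid pixels.
    """
    vol = stack.volume
    n_valid = np.isfinite(vol).sum(axis=(1, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(vol, axis=(1, 2))
    empty = np.flatnonzero(n_valid == 0)
    n = empty[0] if len(empty) else stack.n_slices
    if n < stack.n_slices:
        log.warning("profile truncated at slice %d (no valid pixels)", n)
    if n < 2:
        raise RangeError("fewer than 2 usable slices for the depth profile")
    vz = stack.voxel_size_z
    return DepthProfile(
        z=np.arange(n) * vz,
        a=means[:n],
        z_max=n * vz,
        n_pixels_averaged=n_valid[:n],
    )
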