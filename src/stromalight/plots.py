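"""Diagnostic figures: profile + fit, residuals vs the noise band, and the
depth-dependent mean-free-path deviation with its credible intervals."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .decay import ExtendedFit, MonoExpFit  # noqa: E402
from .noise import NoiseModel  # noqa: E402
from .stack import DepthProfile  # noqa: E402

__all__ = ["plot_fit_summary"]


def plot_fit_summary(
    profile: DepthProfile,
    mono: MonoExpFit,
    noise: NoiseModel | None = None,
    extended: ExtendedFit | None = None,
    path=None,
):
    """Three-panel summary of one analysis; returns the figure.

    Left: depth profile with the mono-exponential fit. Middle: fit
    residuals with the +/-2 sigma noise band. Right (when an extended fit
    is given): posterior median and 50%/95% intervals of dls(z) with the
    control points.
    """
    n_panels = 3 if extended is not None else 2
    fig, axes = plt.subplots(1, n_panels, figsize=(4.2 * n_panels, 3.4))

    ax = axes[0]
    ax.plot(profile.z, profile.a, ".", ms=2, color="0.4", label="profile")
    ax.plot(profile.z, mono.predict(profile.z), "-", color="C3",
            label=f"fit: $l_s$={mono.l_s:.0f} µm")
    ax.set_xlabel("stromal depth z (µm)")
    ax.set_ylabel("mean amplitude (a.u.)")
    ax.legend(frameon=False, fontsize=8)

    ax = axes[1]
    resid = profile.a - mono.predict(profile.z)
    ax.plot(profile.z, resid, ".", ms=2, color="0.4")
    if noise is not None:
        band = 2.0 * noise.predict_sigma(profile.z)
        ax.fill_between(profile.z, -band, band, color="C0", alpha=0.25,
                        label=r"$\pm 2\sigma(z)$")
        ax.legend(frameon=False, fontsize=8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("stromal depth z (µm)")
    ax.set_ylabel(f"residuals  ($b_r$={mono.birge_ratio:.2f})")

    if extended is not None:
        ax = axes[2]
        med = np.median(extended.delta_curve_draws, axis=0)
        q = np.percentile(extended.delta_curve_draws, [2.5, 25, 75, 97.5], axis=0)
        ax.fill_between(extended.curve_z, q[0], q[3], color="C2", alpha=0.2)
        ax.fill_between(extended.curve_z, q[1], q[2], color="C2", alpha=0.35)
        ax.plot(extended.curve_z, med, color="C2")
        qc = np.percentile(extended.delta_control_draws, [2.5, 97.5], axis=0)
        ax.vlines(extended.control_z, qc[0], qc[1], color="k", lw=1)
        ax.axhline(0, color="k", lw=0.5)
        ax.axhspan(-0.1, 0.1, color="0.8", alpha=0.4)
        ax.set_xlabel("stromal depth z (µm)")
        ax.set_ylabel(r"$\Delta l_s(z)$")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
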