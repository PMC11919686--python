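"""Quick-look plots for the analysis outputs (SVG/PNG via matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .coat_occupancy import SaturationSummary  # noqa: E402
from .tube_profiles import RadialProfile  # noqa: E402

__all__ = ["plot_occupancy_profile", "plot_radial_profile"]


def plot_occupancy_profile(profile: pd.DataFrame,
                           fit: SaturationSummary | None = None,
                           path=None):
    """Occupancy vs. curvedness with the optional saturation-fit overlay."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    nz = profile.loc[profile["n_points"] > 0]
    centers = (nz["curvedness_lo"] + nz["curvedness_hi"]) / 2
    ax.plot(centers, nz["occupancy"], "o", ms=3.5, label="measured")
    if fit is not None:
        c = np.linspace(float(centers.min()), float(centers.max()), 200)
        y = np.clip(fit.intercept + fit.slope * np.minimum(c, fit.breakpoint),
                    0, 1)
        ax.plot(c, y, "-", lw=1.2,
                label=f"ramp fit (c* = {fit.breakpoint:.3f})")
        ax.axvline(fit.breakpoint, ls=":", lw=0.8, color="gray")
    ax.set_xlabel("curvedness (nm$^{-1}$)")
    ax.set_ylabel("coat occupancy")
    ax.set_ylim(-0.02, 1.05)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_radial_profile(profile: RadialProfile, leaflets=None, path=None):
    """Mean density vs. radius; optional leaflet-radius markers."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile.radii, profile.mean_density, "-", lw=1.2)
    if leaflets is not None:
        r_in, r_out = leaflets[0], leaflets[1]
        for r, lab in ((r_in, "inner leaflet"), (r_out, "outer leaflet")):
            ax.axvline(r, ls="--", lw=0.8, color="tab:red")
        ax.set_title(f"leaflet peaks {r_in:.1f} / {r_out:.1f} A "
                     f"(thickness {r_out - r_in:.1f} A)", fontsize=9)
    ax.set_xlabel("radius (Å)")
    ax.set_ylabel("mean density")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
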