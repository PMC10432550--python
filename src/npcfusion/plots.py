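"""Diagnostic figures: reconstruction scatter views and the z histogram."""

from __future__ import annotations

import numpy as np

from .canonical import ZHistogramFit
from .simulate import LocalizationCloud

__all__ = ["plot_reconstruction", "plot_z_histogram"]


def plot_reconstruction(cloud: LocalizationCloud, ax=None, view: str = "top",
                        max_points: int = 20000, seed: int = 0):
    """Scatter of the super-particle; ``view`` is "top" (xy) or "side" (xz)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = cloud.positions
    if len(pts) > max_points:
        pts = pts[np.random.default_rng(seed).choice(len(pts), max_points,
                                                     replace=False)]
    cols = (0, 1) if view == "top" else (0, 2)
    ax.scatter(pts[:, cols[0]], pts[:, cols[1]], s=1, alpha=0.2, lw=0)
    ax.set_aspect("equal")
    ax.set_xlabel("x [nm]")
    ax.set_ylabel("y [nm]" if view == "top" else "z [nm]")
    return ax


def plot_z_histogram(cloud: LocalizationCloud, fit: ZHistogramFit | None = None,
                     ax=None, bin_width: float = 1.0):
    """z-coordinate histogram with the bimodal fit overlaid."""
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    z = cloud.positions[:, 2]
    bins = np.arange(z.min(), z.max() + bin_width, bin_width)
    ax.hist(z, bins=bins, color="0.7")
    if fit is not None:
        grid = np.linspace(z.min(), z.max(), 400)
        dens = sum(w * norm.pdf(grid, m, s) for w, m, s in
                   zip(fit.peak_weights, fit.peak_positions, fit.peak_widths))
        ax.plot(grid, dens * len(z) * bin_width, "r-")
        ax.axvline(fit.threshold, color="k", ls="--", lw=0.8)
    ax.set_xlabel("z [nm]")
    ax.set_ylabel("count")
    return ax
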