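"""Static exports of z-score curves and surfaces."""

from __future__ import annotations

import numpy as np

from .smoothing import SmoothFit, Z_NULL_BAND


def plot_curve(fit: SmoothFit, points=None, ax=None, title: str = ""):
    """2D z-curve along phylogenetic distance: fit, 95% band, and the null band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(fit.grid, fit.lower, fit.upper, color="0.8", label="95% band")
    ax.plot(fit.grid, fit.fitted, color="C3")
    for yy in (-Z_NULL_BAND, Z_NULL_BAND):
        ax.axhline(yy, color="saddlebrown", lw=0.8)
    ax.axhline(0.0, color="0.5", lw=0.5)
    if points is not None:
        ax.plot(points[0], points[1], ".", ms=3, color="0.3", alpha=0.5)
    ax.set_xlabel("phylogenetic distance (Ma to LCA)")
    ax.set_ylabel("z")
    if title:
        ax.set_title(title)
    return ax


def plot_surface(fit: SmoothFit, ax=None, title: str = ""):
    """3D z-surface over (physical, phylogenetic) distance; gray = non-significant."""
    import matplotlib.pyplot as plt
    from matplotlib import cm

    if ax is None:
        fig = plt.figure(figsize=(7, 5))
        ax = fig.add_subplot(111, projection="3d")
    g1 = np.unique(fit.grid[:, 0])
    g2 = np.unique(fit.grid[:, 1])
    Z = fit.fitted.reshape(g1.size, g2.size)
    sig = fit.significant.reshape(g1.size, g2.size)
    colors = cm.viridis((Z - Z.min()) / (np.ptp(Z) or 1.0))
    colors[~sig] = (0.6, 0.6, 0.6, 1.0)
    X, Y = np.meshgrid(g1, g2, indexing="ij")
    ax.plot_surface(X, Y, Z, facecolors=colors, linewidth=0, antialiased=False, shade=False)
    ax.set_xlabel("physical distance (m)")
    ax.set_ylabel("phylogenetic distance (Ma)")
    ax.set_zlabel("z")
    if title:
        ax.set_title(title)
    return ax
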