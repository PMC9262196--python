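"""Plotting helpers: diel-profile panels and the temporal-niche MDS map."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_diel_profiles", "plot_mds_map", "plot_rate_series"]


def plot_diel_profiles(profiles, axes=None):
    """Mean +/- SE capture rate per WZT-hour bin, one panel per taxon."""
    import matplotlib.pyplot as plt

    profiles = list(profiles)
    if axes is None:
        _, axes = plt.subplots(1, len(profiles), sharey=True,
                               figsize=(3 * len(profiles), 2.5), squeeze=False)
        axes = axes[0]
    for ax, prof in zip(axes, profiles):
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        ax.bar(centers, prof.mean, width=np.diff(prof.bin_edges),
               yerr=prof.se, color="0.4", edgecolor="none")
        ax.axvspan(12, 24, color="0.85", zorder=0)     # night (WZT >= 12)
        ax.set_title(prof.taxon)
        ax.set_xlabel("WZT (h)")
        ax.set_xlim(0, 24)
    axes[0].set_ylabel("capture rate (h$^{-1}$)")
    return axes


def plot_mds_map(result, ax=None):
    """Bootstrap point clouds, 95% ellipses and point estimates per taxon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("tab10")
    for i, taxon in enumerate(result.taxa):
        color = cmap(i % 10)
        cloud = result.boot_coords[:, i, :]
        ax.scatter(cloud[:, 0], cloud[:, 1], s=4, alpha=0.25, color=color)
        ring = np.asarray(result.ellipse_polygon(taxon).exterior.coords)
        ax.plot(ring[:, 0], ring[:, 1], color=color)
        x, y = result.coords.loc[taxon]
        ax.scatter([x], [y], color=color, s=40, edgecolor="black", zorder=3)
        ax.annotate(taxon, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_aspect("equal")
    return ax


def plot_rate_series(series, ax=None, **plot_kw):
    """Actogram-style capture-rate trace for one replicate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    t_h = (series.times - series.times[0]) / 3600.0
    ax.plot(t_h, series.values, **plot_kw)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("rate (h$^{-1}$)" if series.kind == "rate" else "count")
    return ax
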