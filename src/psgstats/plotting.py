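"""Minimal topographic rendering: per-channel scalars as a 2-D scalp scatter."""

from __future__ import annotations

import numpy as np


def plot_topomap(values, montage, labels, ax=None, highlight=None,
                 cmap="RdBu_r", title=None):
    """Scatter per-channel values at projected (x, y) electrode positions.

    *highlight* marks a channel subset (e.g. a significant cluster) with
    ring outlines. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pos = montage.coords(labels)[:, :2]
    vmax = np.nanmax(np.abs(values)) or 1.0
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=values, s=80, cmap=cmap,
                    vmin=-vmax, vmax=vmax, edgecolors="k", linewidths=0.3)
    if highlight:
        hi = [i for i, l in enumerate(labels) if l in set(highlight)]
        ax.scatter(pos[hi, 0], pos[hi, 1], s=160, facecolors="none",
                   edgecolors="gold", linewidths=1.8)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(sc, ax=ax, shrink=0.7)
    return ax
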