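"""Quick-look plots: track maps and detection-probability grids."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_tracks", "plot_probability_grid"]


def plot_tracks(tracks, arrays=(), ax=None, smoothed=True):
    """Plan-view (east/north) track map, arrays marked with triangles.

    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for t in tracks:
        p = t.best_positions if smoothed else t.positions
        ax.plot(p[:, 0], p[:, 1], lw=1, label=t.whale_id)
        ax.plot(p[0, 0], p[0, 1], "o", ms=4, color=ax.lines[-1].get_color())
    for arr in arrays:
        ax.plot(arr.origin[0], arr.origin[1], "^", color="k", ms=9)
    ax.set_xlabel("east (m)")
    ax.set_ylabel("north (m)")
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    return ax


def plot_probability_grid(grid, arrays=(), ax=None, cmap="viridis"):
    """Heat map of a both-array detection-probability grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6.5, 6))
    p = np.ma.masked_invalid(grid.probability)
    im = ax.pcolormesh(grid.x_edges, grid.y_edges, p.T, cmap=cmap,
                       vmin=0.0, vmax=1.0)
    plt.colorbar(im, ax=ax, label="P(detected on both arrays)")
    for arr in arrays:
        ax.plot(arr.origin[0], arr.origin[1], "^", color="w", ms=9,
                markeredgecolor="k")
    ax.set_xlabel("east (m)")
    ax.set_ylabel("north (m)")
    ax.set_aspect("equal")
    return ax
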