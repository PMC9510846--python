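"""Heat-map rendering of accuracy surfaces."""

from __future__ import annotations

import numpy as np

from .sweep import AccuracySurface

__all__ = ["plot_surface"]


def plot_surface(surface: AccuracySurface, ax=None, log: bool = True,
                 cmap: str = "viridis", s: float = 4.0):
    """Scatter the (a, b) grid colored by (log) SSE.

    Infinite-SSE pairs are drawn as grey crosses. Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    a = surface.frame["a"].to_numpy()
    b = surface.frame["b"].to_numpy()
    sse = surface.sse
    finite = np.isfinite(sse)
    if log:
        # exact (zero-SSE) fits sit at the floor of the color scale
        color = np.log10(np.maximum(sse[finite], np.finfo(float).tiny))
    else:
        color = sse[finite]
    sc = ax.scatter(a[finite], b[finite], c=color, cmap=cmap, s=s, marker="s")
    if (~finite).any():
        ax.scatter(a[~finite], b[~finite], c="0.6", s=s, marker="x")
    cbar = ax.figure.colorbar(sc, ax=ax)
    cbar.set_label("log10 SSE" if log else "SSE")
    ax.set_xlabel("growth exponent a")
    ax.set_ylabel("decay exponent b")
    ax.set_title("accuracy surface")
    return ax
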