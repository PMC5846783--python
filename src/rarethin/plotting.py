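"""Quick-look map plotting for density and CV surfaces."""

from __future__ import annotations

import numpy as np

from .grids import DensityMap

__all__ = ["plot_map"]


def plot_map(dmap: DensityMap, ax=None, log: bool = False, **kwargs):
    """Scatter-style cell map of a density or CV surface.

    Masked cells are left blank.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    vals = np.where(dmap.valid, dmap.values, np.nan)
    if log:
        vals = np.log10(np.where(vals > 0, vals, np.nan))
    sc = ax.scatter(dmap.lon, dmap.lat, c=vals, s=6, marker="s", **kwargs)
    ax.figure.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax
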