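"""Optional contour-plot helper for free-energy surfaces.

Not part of the tested analysis contract; requires matplotlib (install the
``plot`` extra).
"""
from __future__ import annotations

import numpy as np

from .fes import FreeEnergySurface


def plot_fes(fes: FreeEnergySurface, ax=None, poses=None, cmap="viridis"):
    """Filled-contour plot of a surface, chi1 on x, chi2 on y, kcal/mol.

    ``poses`` may be PoseRecords (or projections) to overlay as numbered
    labels at their (chi1, chi2) positions, the way docking poses are
    marked on a conformational map.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    n = fes.n_bins
    centers = -180.0 + (np.arange(n) + 0.5) * fes.bin_width
    z = np.ma.masked_where(fes.empty_mask, fes.delta_g)
    # delta_g is indexed [chi1, chi2]; contourf wants z[y, x]
    m = ax.contourf(centers, centers, z.T, levels=12, cmap=cmap)
    plt.colorbar(m, ax=ax, label=r"$\Delta G$ (kcal/mol)")
    if poses is not None:
        for p in poses:
            rec = getattr(p, "pose", p)
            ax.annotate(str(rec.ranking), (rec.chi1, rec.chi2),
                        color="white", fontweight="bold", ha="center")
    ax.set_xlabel(r"$\chi_1$ (deg)")
    ax.set_ylabel(r"$\chi_2$ (deg)")
    ax.set_xlim(-180, 180)
    ax.set_ylim(-180, 180)
    return ax
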