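"""Plotting: retention curves and distance-matrix heatmaps with dendrograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

__all__ = ["retention_plot", "distance_heatmap"]


def retention_plot(curve, path) -> None:
    """Node/edge retention fractions vs φ* with fitted logistics and φmax."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.semilogx(curve.grid, curve.node_frac, "o", color="tab:blue", ms=4,
                label="connected nodes")
    ax.semilogx(curve.grid, curve.edge_frac, "o", color="0.5", ms=4, label="edges")
    xs = np.linspace(np.log10(curve.grid[0]), np.log10(curve.grid[-1]), 400)
    if curve.node_fit is not None:
        ax.semilogx(10**xs, curve.node_fit.predict(xs), "-", color="tab:blue")
    if curve.edge_fit is not None:
        ax.semilogx(10**xs, curve.edge_fit.predict(xs), "-", color="0.5")
    if curve.node_fit is not None and curve.edge_fit is not None:
        ax.semilogx(10**xs, curve.node_fit.predict(xs) - curve.edge_fit.predict(xs),
                    "-", color="tab:red", label="difference")
    if curve.phi_max is not None:
        ax.axvline(curve.phi_max, ls="--", color="tab:red",
                   label=f"$\\phi_{{max}}$ = {curve.phi_max:.3f}")
    ax.set_xlabel("$\\phi^*$")
    ax.set_ylabel("retained fraction")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def distance_heatmap(D, labels, linkage, path) -> None:
    """Heatmap of a layer distance matrix, rows/cols in dendrogram order."""
    order = hierarchy.leaves_list(linkage)
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(9, 4), gridspec_kw={"width_ratios": [1, 3]})
    hierarchy.dendrogram(linkage, ax=ax_d, orientation="left", no_labels=True,
                         color_threshold=0)
    ax_d.set_axis_off()
    im = ax_h.imshow(np.asarray(D)[np.ix_(order, order)], cmap="Reds", aspect="auto")
    if len(labels) <= 30:
        ax_h.set_xticks(range(len(order)), [labels[i] for i in order],
                        rotation=90, fontsize=6)
        ax_h.set_yticks(range(len(order)), [labels[i] for i in order], fontsize=6)
    fig.colorbar(im, ax=ax_h, label="Euclidean distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
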