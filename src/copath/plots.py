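"""Heatmap figures for transition deltas and module eigengenes."""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np

from .behavior.transitions import DeltaTransition
from .coexpr.eigengenes import Eigengenes


def transition_delta_heatmap(delta: DeltaTransition, pvalues=None, ax=None,
                             alpha: float = 0.05):
    """Zero-centered heatmap of a (genotype - WT) transition delta matrix.

    Red marks transitions that are more likely than in WT, blue less
    likely; cells with a permutation p-value below ``alpha`` are starred.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    vals = delta.values
    vmax = np.nanmax(np.abs(vals)) or 1.0
    im = ax.imshow(vals, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(delta.labels)), delta.labels, rotation=90)
    ax.set_yticks(range(len(delta.labels)), delta.labels)
    ax.set_xlabel("to")
    ax.set_ylabel("from")
    if pvalues is not None:
        p = np.asarray(pvalues)
        for i in range(p.shape[0]):
            for j in range(p.shape[1]):
                if np.isfinite(p[i, j]) and p[i, j] < alpha:
                    ax.text(j, i, "*", ha="center", va="center")
    ax.figure.colorbar(im, ax=ax, label="delta transition probability")
    return ax


def me_heatmap(eigengenes: Eigengenes, design, ax=None):
    """Module x sample eigengene heatmap with samples grouped by genotype."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    design = design.loc[eigengenes.me.columns]
    order = design.sort_values(["e4", "nlf"]).index
    me = eigengenes.me[order]
    vmax = np.nanmax(np.abs(me.to_numpy())) or 1.0
    im = ax.imshow(me.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_yticks(range(len(me.index)), me.index)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    # genotype group separators
    genos = design.loc[order, "genotype"].to_numpy()
    for i in np.flatnonzero(genos[:-1] != genos[1:]):
        ax.axvline(i + 0.5, color="k", lw=0.8)
    ax.figure.colorbar(im, ax=ax, label="module eigengene")
    return ax
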