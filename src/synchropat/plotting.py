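"""Minimal plotting helper: lattice heatmaps of node-valued vectors."""

from __future__ import annotations

import numpy as np

__all__ = ["lattice_heatmap"]


def lattice_heatmap(values, rows: int, cols: int, ax=None, **imshow_kwargs):
    """Render a node-valued vector (e.g. an adjacency eigenvector or a
    final species concentration) as a rows x cols heatmap.

    Nodes are assumed row-major, matching the torus builder's ordering.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    v = np.asarray(values, dtype=float).ravel()
    if v.size != rows * cols:
        raise ValueError(f"expected {rows * cols} values, got {v.size}")
    if ax is None:
        _, ax = plt.subplots()
    imshow_kwargs.setdefault("cmap", "RdBu_r")
    imshow_kwargs.setdefault("interpolation", "nearest")
    im = ax.imshow(v.reshape(rows, cols), **imshow_kwargs)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
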