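"""Heat-map and bar-plot helpers for analysis reports.

Thin matplotlib wrappers: the analysis emits the plot-ready tables, these
functions only draw them. Figures are returned so callers can adjust or
save them; pass ``path`` to save directly.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .hypergraph import Hyperedge


def cooccurrence_heatmap(counts: np.ndarray, labels: Sequence[str],
                         path: str | Path | None = None, title: str | None = None):
    """Heat map of the pairwise disease co-occurrence count matrix."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.6 * len(labels) + 2, 0.6 * len(labels) + 2))
    im = ax.imshow(np.asarray(counts), cmap="GnBu")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=8)
    ax.set_yticks(range(len(labels)), labels, fontsize=8)
    fig.colorbar(im, ax=ax, label="participants")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def cluster_barplot(clusters: Sequence[Hyperedge],
                    path: str | Path | None = None, title: str | None = None):
    """Horizontal bar plot of the top overlap-weighted multimorbidity clusters."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    labels = [", ".join(e.diseases) for e in clusters]
    weights = [e.weight for e in clusters]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(clusters) + 1.5))
    ax.barh(range(len(clusters)), weights, color="#4878a8")
    ax.set_yticks(range(len(clusters)), labels, fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel("overlap weight $W_E$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
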