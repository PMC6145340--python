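"""Plot hooks: scree plot and 2-D cluster-projection scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def scree_plot(eigenvalues: np.ndarray, n_retained: int | None = None, path: str | Path = "scree.png") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ranks = np.arange(1, len(eigenvalues) + 1)
    ax.plot(ranks, eigenvalues, "o-", ms=4)
    ax.axhline(1.0, color="grey", ls="--", lw=1, label="Kaiser threshold")
    if n_retained:
        ax.axvline(n_retained + 0.5, color="C3", ls=":", lw=1, label=f"retained = {n_retained}")
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue (correlation matrix)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cluster_projection_plot(scores: np.ndarray, labels: np.ndarray, path: str | Path = "clusters.png") -> None:
    """Cluster membership on the first two component scores."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for c in np.unique(labels):
        sel = labels == c
        ax.scatter(scores[sel, 0], scores[sel, 1], s=12, label=f"cluster {c + 1}")
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
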