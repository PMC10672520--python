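"""Static figure export: correlation maps, activity rasters, PCA scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import ActivityMask, NeuronPositions
from .correlation import CorrelationMatrix
from .embedding import EmbeddingResult

__all__ = ["correlation_map", "activity_raster", "pca_scatter"]


def correlation_map(
    pos: NeuronPositions,
    corr: CorrelationMatrix,
    threshold: float = 0.3,
    path: str | Path = "correlation_map.png",
) -> Path:
    """Neuron positions (pixel axes) with edges for pairs above the
    threshold; positive connections red, negative blue."""
    fig, ax = plt.subplots(figsize=(6, 6))
    n = pos.n_units
    for i in range(n):
        for j in range(i + 1, n):
            r = corr.values[i, j]
            if abs(r) > threshold:
                ax.plot(
                    [pos.x[i], pos.x[j]],
                    [pos.y[i], pos.y[j]],
                    color="red" if r > 0 else "blue",
                    alpha=min(abs(r), 1.0),
                    lw=0.8,
                )
    ax.scatter(pos.x, pos.y, s=18, c="black", zorder=3)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"{corr.method} correlations > {threshold}")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def activity_raster(masks: dict[str, ActivityMask], path: str | Path = "raster.png") -> Path:
    """Binarized raster per mask (e.g. original vs shuffled side by side)."""
    n = len(masks)
    fig, axes = plt.subplots(1, n, figsize=(5 * n, 4), squeeze=False)
    for ax, (label, mask) in zip(axes[0], masks.items()):
        ax.imshow(mask.active, aspect="auto", cmap="Greys", interpolation="nearest")
        ax.set_title(label)
        ax.set_xlabel("frame")
        ax.set_ylabel("unit")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def pca_scatter(
    emb: EmbeddingResult,
    labels: dict[str, str] | None = None,
    path: str | Path = "pca.png",
) -> Path:
    """Recordings in the 2-D embedding plane, colored by label."""
    fig, ax = plt.subplots(figsize=(5, 5))
    xy = emb.coordinates[["X", "Y"]]
    if labels:
        groups = sorted(set(labels.values()))
        for g in groups:
            idx = [name for name in xy.index if labels.get(name) == g]
            sub = xy.loc[idx]
            ax.scatter(sub["X"], sub["Y"], label=g)
        ax.legend()
    else:
        ax.scatter(xy["X"], xy["Y"])
    for name, row in xy.iterrows():
        ax.annotate(str(name), (row["X"], row["Y"]), fontsize=7)
    evr = emb.explained_variance_ratio
    ax.set_xlabel(f"X ({100 * evr[0]:.1f}% var)")
    ax.set_ylabel(f"Y ({100 * evr[1]:.1f}% var)" if len(evr) > 1 else "Y")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
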