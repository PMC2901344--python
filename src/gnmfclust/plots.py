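"""Diagnostic figures: dendrogram, clustered heatmap, Kaplan-Meier curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from lifelines import KaplanMeierFitter
from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

from .assignment import SurvivalTable
from .data_model import CopyNumberMatrix
from .pilot import Dendrogram


def plot_dendrogram(dend: Dendrogram, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(max(6, dend.n_leaves * 0.15), 4))
    scipy_dendrogram(dend.linkage_matrix, labels=dend.sample_ids, ax=ax,
                     leaf_font_size=6)
    ax.set_ylabel("merge height (Pearson dissimilarity)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(
    matrix: CopyNumberMatrix,
    assignment: np.ndarray,
    path: str | Path,
    vmin: float = 1.0,
    vmax: float = 3.0,
) -> None:
    """Samples (rows) ordered by cluster, segments (columns) in genome order.

    Blue-white-red encodes loss / diploid / gain; horizontal lines separate
    clusters and vertical lines separate chromosomes.
    """
    order = np.argsort(assignment, kind="stable")
    data = matrix.values[:, order].T
    fig, ax = plt.subplots(figsize=(10, max(4, matrix.n_samples * 0.08)))
    ax.imshow(data, aspect="auto", cmap="bwr", vmin=vmin, vmax=vmax,
              interpolation="nearest")
    # cluster separators
    labels = np.asarray(assignment)[order]
    for b in np.where(np.diff(labels) != 0)[0]:
        ax.axhline(b + 0.5, color="black", lw=1)
    # chromosome separators
    chroms = [s.chromosome for s in matrix.segments]
    for b in [i for i in range(1, len(chroms)) if chroms[i] != chroms[i - 1]]:
        ax.axvline(b - 0.5, color="grey", lw=0.3)
    ax.set_xlabel("segments (genome order)")
    ax.set_ylabel("samples (grouped by cluster)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_km_curves(
    assignment: dict[str, int],
    survival: SurvivalTable,
    path: str | Path,
) -> None:
    df = survival.table[survival.table["sample"].isin(assignment)].copy()
    df["group"] = df["sample"].map(assignment)
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, sub in df.groupby("group"):
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=f"cluster {g} (n={len(sub)})")
        km.plot_survival_function(ax=ax, show_censors=True)
    ax.set_xlabel(f"time ({survival.endpoint})")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
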