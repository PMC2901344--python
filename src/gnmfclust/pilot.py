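"""Pilot hierarchical clustering: propose the candidate range of cluster numbers.

Samples are clustered with average linkage on Pearson dissimilarity
(1 minus the Pearson correlation between copy-number profiles).  The
dendrogram is the primary output — the candidate range heuristic merely
brackets the largest relative gaps in merge heights, and a human inspecting
the tree remains authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, dendrogram, linkage
from scipy.spatial.distance import squareform

from .data_model import CopyNumberMatrix


@dataclass
class Dendrogram:
    """Merge sequence from scipy plus bookkeeping."""

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        order = dendrogram(self.linkage_matrix, no_plot=True)["leaves"]
        return [self.sample_ids[i] for i in order]


def pearson_dissimilarity(matrix: CopyNumberMatrix | np.ndarray) -> np.ndarray:
    """m x m matrix of 1 - Pearson correlation between sample profiles.

    Symmetric, zero diagonal, entries in [0, 2].  A constant profile has no
    defined correlation and raises, naming the sample.
    """
    if isinstance(matrix, CopyNumberMatrix):
        values, ids = matrix.values, matrix.sample_ids
    else:
        values = np.asarray(matrix, float)
        ids = [str(i) for i in range(values.shape[1])]
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [ids[j] for j in np.where(sd == 0)[0]]
        raise ValueError(
            f"constant profile(s) make correlation undefined: {', '.join(bad)}"
        )
    corr = np.corrcoef(values, rowvar=False)
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_cluster(
    distance_matrix: np.ndarray,
    sample_ids: list[str] | None = None,
    method: str = "average",
) -> Dendrogram:
    """Agglomerate a precomputed distance matrix (UPGMA by default)."""
    d = np.asarray(distance_matrix, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(d.shape[0])]
    Z = linkage(squareform(d, checks=False), method=method)
    return Dendrogram(linkage_matrix=Z, sample_ids=list(sample_ids), method=method)


def cut_dendrogram(dend: Dendrogram, k: int) -> np.ndarray:
    """Hard assignment into k clusters (labels 0..k-1)."""
    if not 1 <= k <= dend.n_leaves:
        raise ValueError(f"k={k} out of range [1, {dend.n_leaves}]")
    return cut_tree(dend.linkage_matrix, n_clusters=k).ravel()


def suggest_cluster_range(
    dend: Dendrogram, min_k: int = 2, max_k: int | None = None
) -> tuple[int, int, bool]:
    """Bracket the k values at the largest relative gaps in merge heights.

    Cutting between merge m-k and m-k+1 produces k clusters, so a large gap
    between consecutive merge heights flags a natural cut.  Gaps are scored
    relative to the tree's total height.  Returns ``(k_lo, k_hi,
    low_confidence)``; when no gap stands out (uniform data) the full
    ``[min_k, max_k]`` range comes back flagged low-confidence.
    """
    m = dend.n_leaves
    if max_k is None:
        max_k = min(m - 1, 8)
    if max_k >= m:
        raise ValueError("max_k must be < number of samples")
    if max_k <= min_k:
        raise ValueError("max_k must be > min_k")

    heights = dend.heights
    total = heights[-1] if heights[-1] > 0 else 1.0
    # gap(k): height of the merge that destroys k clusters minus the merge
    # that creates them; k clusters exist between merges m-k and m-k+1
    ks = np.arange(min_k, max_k + 1)
    gaps = np.array(
        [heights[m - k] - heights[m - k - 1] for k in ks]
    ) / total

    # a cut is "natural" when its gap spans a sizable fraction of the whole
    # tree height; unstructured data never concentrates height in one merge
    strong = gaps > 0.1
    if not strong.any():
        return min_k, max_k, True
    k_strong = ks[strong]
    return int(k_strong.min()), int(k_strong.max()), False
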