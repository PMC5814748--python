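"""Clustering evaluation metrics.

Cluster purity (per-cluster fraction of the dominant external label),
adjusted mutual information (chance-corrected, normalized by the larger
entropy), the proportion of cells assigned to robust clusters, and the
Shannon entropy of a 2-D embedding binned on a regular grid — the criterion
used to choose between PCA and t-SNE.

The Rand index is deliberately not provided: it penalizes splitting one
cell type into several clusters, which can be the correct outcome when a
novel subtype is present.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

logger = logging.getLogger(__name__)

__all__ = [
    "UNASSIGNED",
    "PurityResult",
    "cluster_purity",
    "adjusted_mutual_information",
    "proportion_robustly_clustered",
    "embedding_grid_entropy",
    "choose_embedding",
    "EmbeddingChoice",
]

#: Reserved label for cells not assigned to any robust cluster.
UNASSIGNED = -1


def _as_array(labels) -> np.ndarray:
    return np.asarray(labels)


def _assigned_mask(labels: np.ndarray) -> np.ndarray:
    if labels.dtype.kind in "iuf":
        return labels != UNASSIGNED
    return (labels != str(UNASSIGNED)) & (labels != "unassigned")


@dataclass
class PurityResult:
    per_cluster: dict
    median: float
    mean: float

    @property
    def values(self) -> list[float]:
        return list(self.per_cluster.values())


def cluster_purity(clusters, truth) -> PurityResult:
    """Per-cluster purity against external labels, plus median/mean summary.

    Purity of cluster *i* is the fraction of its cells whose external label
    equals the cluster's dominant label.  Unassigned cells are excluded.
    Dominant-label ties break lexicographically for determinism.
    """
    clusters = _as_array(clusters)
    truth = _as_array(truth)
    if clusters.shape != truth.shape:
        raise ValueError("cluster and truth label vectors differ in length")
    keep = _assigned_mask(clusters)
    clusters, truth = clusters[keep], truth[keep]
    if clusters.size == 0:
        raise ValueError("no assigned cells to evaluate")
    per: dict = {}
    for c in sorted(set(clusters.tolist())):
        members = truth[clusters == c]
        labels, counts = np.unique(members, return_counts=True)
        # np.unique sorts labels, argmax takes the first max -> lexicographic tie-break
        per[c] = float(counts.max() / members.size)
    vals = np.array(list(per.values()))
    return PurityResult(per, float(np.median(vals)), float(vals.mean()))


def adjusted_mutual_information(a, b) -> float:
    """AMI between two labelings: (MI − E[MI]) / (max(H(a), H(b)) − E[MI]).

    E[MI] is the expectation under the permutation (hypergeometric) model,
    so chance agreement scores ~0 and identical labelings score 1.  Cells
    unassigned in either labeling are excluded pairwise.  A degenerate
    single-label input returns 0 with a warning.
    """
    a = _as_array(a)
    b = _as_array(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    keep = _assigned_mask(a) & _assigned_mask(b)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no jointly assigned cells")
    if len(set(a.tolist())) < 2 or len(set(b.tolist())) < 2:
        warnings.warn("degenerate single-label input; AMI undefined, returning 0",
                      stacklevel=2)
        return 0.0
    return float(adjusted_mutual_info_score(a, b, average_method="max"))


def proportion_robustly_clustered(clusters) -> float:
    """Fraction of cells carrying a non-unassigned label."""
    clusters = _as_array(clusters)
    if clusters.size == 0:
        return 0.0
    return float(_assigned_mask(clusters).mean())


def embedding_grid_entropy(embedding: np.ndarray, bins_per_axis: int = 20) -> float:
    """Shannon entropy (nats) of cell counts on a regular 2-D grid.

    Each axis is split into ``bins_per_axis`` equal-width intervals spanning
    the data range (a zero-range axis collapses to one bin); the entropy of
    the normalized 2-D histogram measures how much spatial information the
    embedding carries.  Maximum is ``ln(bins_per_axis**2)``.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or embedding.shape[1] != 2:
        raise ValueError("embedding must be a cells x 2 matrix")
    if embedding.shape[0] == 0:
        raise ValueError("embedding has no cells")
    edges = []
    for axis in range(2):
        lo, hi = embedding[:, axis].min(), embedding[:, axis].max()
        if hi == lo:
            edges.append(np.array([lo - 0.5, hi + 0.5]))
        else:
            edges.append(np.linspace(lo, hi, bins_per_axis + 1))
    hist, _, _ = np.histogram2d(embedding[:, 0], embedding[:, 1],
                                bins=(edges[0], edges[1]))
    p = hist.ravel() / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


@dataclass
class EmbeddingChoice:
    choice: str  # "pca" or "tsne"
    pca_entropy: float
    tsne_entropy: float


def choose_embedding(expr, seed: int, n_top_genes: int = 500,
                     bins_per_axis: int = 20) -> EmbeddingChoice:
    """Pick PCA or t-SNE by grid entropy of the 2-D embedding.

    Both embeddings are computed on the log1p values of the most variable
    genes; the one with higher information content wins (ties go to PCA,
    the deterministic technique).
    """
    from .clustering import select_variable_genes, _pca_embed, _tsne_embed

    sub = select_variable_genes(expr, min(n_top_genes, expr.n_genes))
    x = np.log1p(sub.values.T)  # cells x genes
    pca2 = _pca_embed(x, 2, seed)
    tsne2 = _tsne_embed(x, 2, seed)
    h_pca = embedding_grid_entropy(pca2, bins_per_axis)
    h_tsne = embedding_grid_entropy(tsne2, bins_per_axis)
    choice = "tsne" if h_tsne > h_pca else "pca"
    logger.info("embedding entropies: PCA %.3f, t-SNE %.3f -> %s",
                h_pca, h_tsne, choice)
    return EmbeddingChoice(choice, h_pca, h_tsne)
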