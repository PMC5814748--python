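"""Robust consensus clustering of cells.

No single clustering of a single-cell dataset is trustworthy on its own:
different dimensionality reductions and different cluster counts produce
different partitions.  The procedure here clusters many views of the data
(PCA or t-SNE embeddings plus raw most-variable-gene subsets) with PAM
(k-medoids) over a range of k, records for every pair of cells the fraction
of runs in which they land in the same cluster, and extracts consensus
blocks from that co-clustering matrix by walking an average-linkage
dendrogram from the root: a subtree becomes a cluster when its mean
internal co-clustering reaches ``self_similarity`` and it holds at least
``min_size`` cells.  Cells in no such block stay unassigned.  Finally,
clusters whose expression profiles are statistically indistinguishable
(fraction of differentially expressed genes below a threshold) are merged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from .metrics import UNASSIGNED, choose_embedding
from .smoothing import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ViewSpec",
    "ClusterConfig",
    "RobustClustering",
    "select_variable_genes",
    "make_views",
    "pam_sweep",
    "kmedoids",
    "cocluster_matrix",
    "consensus_clusters",
    "merge_similar_clusters",
    "robust_cluster",
]


@dataclass(frozen=True)
class ViewSpec:
    """One reduced view of the data: its kind and dimensionality."""

    kind: str  # "pca" | "tsne" | "top_genes"
    dimensionality: int
    seed: int | None = None  # t-SNE only


@dataclass
class ClusterConfig:
    """Tunable parameters of the robust clustering procedure."""

    n_var_genes: int = 500
    pca_components: tuple[int, ...] = (5, 15, 50)
    tsne_dims: tuple[int, ...] = (2, 3)
    top_gene_counts: tuple[int, ...] = (100, 500, 1000)
    k_min: int = 5
    k_max: int = 10
    self_similarity: float = 0.6
    min_size: int = 20
    de_proportion_threshold: float = 0.1
    adj_p: float = 0.05
    embedding: str = "auto"  # "auto" | "pca" | "tsne"
    bins_per_axis: int = 20
    seed: int = 0


@dataclass
class RobustClustering:
    """Result of the consensus procedure.

    ``labels`` holds per-cell integer cluster ids with ``-1`` = unassigned;
    ``cocluster`` is the cells x cells co-clustering matrix that produced
    them.
    """

    labels: np.ndarray
    cocluster: np.ndarray
    n_clusters: int
    config: dict = field(default_factory=dict)


def select_variable_genes(expr: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Subset to the ``n`` genes with highest log1p variance.

    Restricting to the most variable genes lets biological variation
    dominate technical noise.  Original gene order is preserved among the
    selected genes.
    """
    if n > expr.n_genes:
        raise ValueError(f"requested {n} genes but matrix has {expr.n_genes}")
    variances = np.var(np.log1p(expr.values), axis=1)
    # stable sort: equal-variance genes keep input order
    top = np.sort(np.argsort(-variances, kind="stable")[:n])
    return ExpressionMatrix(expr.values[top, :],
                            [expr.gene_ids[i] for i in top],
                            list(expr.cell_ids))


def _pca_embed(x: np.ndarray, d: int, seed: int) -> np.ndarray:
    d = min(d, x.shape[0] - 1, x.shape[1])
    return PCA(n_components=d, random_state=seed).fit_transform(x)


def _tsne_embed(x: np.ndarray, d: int, seed: int) -> np.ndarray:
    perplexity = min(30.0, max(2.0, (x.shape[0] - 1) / 3.0))
    tsne = TSNE(n_components=d, perplexity=perplexity, random_state=seed,
                init="random")
    return tsne.fit_transform(x)


def make_views(
    expr: ExpressionMatrix,
    embedding_choice: str,
    seed: int,
    config: ClusterConfig | None = None,
) -> list[tuple[ViewSpec, np.ndarray]]:
    """Build the menu of reduced views used by the PAM sweep.

    For ``embedding_choice="pca"``: PCA with 5/15/50 components on the 500
    most variable genes.  For ``"tsne"``: t-SNE with 2 and 3 dimensions on
    the same genes.  Either menu is completed by the raw log1p profiles of
    the top 100/500/1000 most variable genes.  Views whose dimensionality
    cannot be realized (fewer cells than components, fewer genes than a top
    count) are dropped with a warning.
    """
    cfg = config or ClusterConfig()
    base = select_variable_genes(expr, min(cfg.n_var_genes, expr.n_genes))
    x = np.log1p(base.values.T)  # cells x genes
    views: list[tuple[ViewSpec, np.ndarray]] = []
    if embedding_choice == "pca":
        for d in cfg.pca_components:
            if d >= expr.n_cells:
                warnings.warn(f"dropping PCA view with {d} components: "
                              f"only {expr.n_cells} cells", stacklevel=2)
                continue
            views.append((ViewSpec("pca", d), _pca_embed(x, d, seed)))
    elif embedding_choice == "tsne":
        for d in cfg.tsne_dims:
            views.append((ViewSpec("tsne", d, seed),
                          _tsne_embed(x, d, seed)))
    else:
        raise ValueError(f"unknown embedding choice {embedding_choice!r}")
    for n in cfg.top_gene_counts:
        if n > expr.n_genes:
            warnings.warn(f"dropping top-{n}-gene view: matrix has only "
                          f"{expr.n_genes} genes", stacklevel=2)
            continue
        sub = select_variable_genes(expr, n)
        views.append((ViewSpec("top_genes", n), np.log1p(sub.values.T)))
    return views


def kmedoids(dist: np.ndarray, k: int, seed: int,
             max_iter: int = 100) -> np.ndarray:
    """PAM-style k-medoids on a precomputed distance matrix.

    k-medoids++-style seeding followed by alternating assignment and
    within-cluster medoid updates until the medoid set is stable.
    """
    rng = np.random.default_rng(seed)
    n = dist.shape[0]
    if k >= n:
        raise ValueError(f"k={k} requires more than k points (have {n})")
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        d2 = np.min(dist[:, medoids], axis=1) ** 2
        total = d2.sum()
        if total > 0:
            nxt = int(rng.choice(n, p=d2 / total))
        else:  # all points coincide with existing medoids
            choices = np.setdiff1d(np.arange(n), medoids)
            nxt = int(rng.choice(choices))
        medoids.append(nxt)
    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size:
                within = dist[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[int(np.argmin(within))]
        if set(new_medoids) == set(medoids):
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)


def pam_sweep(
    views: list[tuple[ViewSpec, np.ndarray]],
    k_min: int = 5,
    k_max: int = 10,
    seed: int = 0,
) -> list[np.ndarray]:
    """One PAM labeling per (view, k) pair for k in [k_min, k_max]."""
    if not (2 <= k_min <= k_max):
        raise ValueError("need k_max >= k_min >= 2")
    n_cells = views[0][1].shape[0]
    if n_cells <= k_max:
        raise ValueError(f"need more than k_max={k_max} cells, have {n_cells}")
    labelings = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(views) * (k_max - k_min + 1))
    i = 0
    for spec, mat in views:
        dist = ssd.squareform(ssd.pdist(mat))
        for k in range(k_min, k_max + 1):
            labelings.append(kmedoids(dist, k, int(child_seeds[i] % (2**31))))
            i += 1
    return labelings


def cocluster_matrix(labelings: list[np.ndarray]) -> np.ndarray:
    """Fraction of labelings in which each cell pair shares a label."""
    if not labelings:
        raise ValueError("need at least one labeling")
    n = len(labelings[0])
    acc = np.zeros((n, n))
    for lab in labelings:
        lab = np.asarray(lab)
        if lab.shape != (n,):
            raise ValueError("labelings differ in length")
        acc += lab[:, None] == lab[None, :]
    return acc / len(labelings)


def consensus_clusters(
    cocluster: np.ndarray,
    self_similarity: float = 0.6,
    min_size: int = 20,
) -> np.ndarray:
    """Extract consensus blocks from a co-clustering matrix.

    Builds an average-linkage dendrogram on the dissimilarity
    ``1 - cocluster`` and walks it breadth-first from the root, emitting a
    cluster at the largest subtree whose mean pairwise co-clustering is at
    least ``self_similarity`` and whose size is at least ``min_size``;
    descendants of an emitted subtree are not revisited.  Cells in no
    emitted block are labeled ``-1``.
    """
    cc = np.asarray(cocluster, dtype=float)
    n = cc.shape[0]
    if cc.shape != (n, n) or not np.allclose(cc, cc.T, atol=1e-12):
        raise ValueError("co-clustering matrix must be square and symmetric")
    labels = np.full(n, UNASSIGNED, dtype=int)
    if n < min_size:
        return labels
    diss = 1.0 - cc
    np.fill_diagonal(diss, 0.0)
    link = sch.linkage(ssd.squareform(diss, checks=False), method="average")
    tree = sch.to_tree(link)
    next_label = 0
    queue = [tree]
    while queue:
        node = queue.pop(0)
        members = node.pre_order(lambda leaf: leaf.id)
        if len(members) >= min_size:
            block = cc[np.ix_(members, members)]
            m = len(members)
            mean_cc = (block.sum() - np.trace(block)) / (m * (m - 1))
            if mean_cc >= self_similarity:
                labels[members] = next_label
                next_label += 1
                continue
        if not node.is_leaf():
            queue.append(node.get_left())
            queue.append(node.get_right())
    return labels


def _de_fraction(x: np.ndarray, y: np.ndarray, adj_p: float) -> float:
    """Fraction of genes differentially expressed between two cell groups.

    Per-gene two-sided Wilcoxon rank-sum with Benjamini-Hochberg
    correction; genes with undefined statistics (all-tied values) count as
    not differential.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mannwhitneyu(x, y, axis=1, alternative="two-sided")
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    rejected, _, _, _ = multipletests(pvals, alpha=adj_p, method="fdr_bh")
    return float(rejected.mean())


def merge_similar_clusters(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    de_proportion_threshold: float = 0.1,
    adj_p: float = 0.05,
    n_var_genes: int = 500,
) -> np.ndarray:
    """Merge clusters that are not substantially differentially expressed.

    Cluster medoids are hierarchically clustered (average linkage,
    Euclidean) on their log1p profiles over the most variable genes; each
    pair of clusters joined directly in that hierarchy is tested gene by
    gene, and merged when the fraction of genes with BH-adjusted p below
    ``adj_p`` is under ``de_proportion_threshold``.  Repeats until no merge
    occurs.  Unassigned cells stay unassigned; singleton clusters are
    skipped with a warning and never merged.
    """
    labels = np.asarray(labels).copy()
    logx = np.log1p(expr.values)
    mv = select_variable_genes(expr, min(n_var_genes, expr.n_genes))
    mv_log = np.log1p(mv.values)

    def medoid_profile(cluster: int) -> np.ndarray:
        members = np.flatnonzero(labels == cluster)
        sub = mv_log[:, members]  # genes x members
        d = ssd.squareform(ssd.pdist(sub.T))
        return sub[:, int(np.argmin(d.sum(axis=1)))]

    while True:
        clusters = sorted(c for c in set(labels.tolist()) if c != UNASSIGNED)
        if len(clusters) < 2:
            return labels
        profiles = np.column_stack([medoid_profile(c) for c in clusters]).T
        link = sch.linkage(profiles, method="average", metric="euclidean")
        # pairs of original clusters joined directly, nearest first
        candidates = [
            (clusters[int(a)], clusters[int(b)])
            for a, b, _, _ in link
            if a < len(clusters) and b < len(clusters)
        ]
        merged = False
        for a, b in candidates:
            ia, ib = np.flatnonzero(labels == a), np.flatnonzero(labels == b)
            if ia.size < 2 or ib.size < 2:
                warnings.warn(f"cluster of size 1 skipped in merge test "
                              f"({a if ia.size < 2 else b})", stacklevel=2)
                continue
            frac = _de_fraction(logx[:, ia], logx[:, ib], adj_p)
            if frac < de_proportion_threshold:
                logger.info("merging clusters %s and %s (DE fraction %.3f)",
                            a, b, frac)
                labels[ib] = a
                merged = True
                break
        if not merged:
            return labels


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map cluster ids to 0..k-1 in order of first appearance."""
    out = np.full_like(labels, UNASSIGNED)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == UNASSIGNED:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def robust_cluster(expr: ExpressionMatrix,
                   config: ClusterConfig | None = None) -> RobustClustering:
    """Run the full consensus procedure on an expression matrix.

    Picks the embedding technique by 2-D grid entropy (unless fixed in the
    config), builds the view menu, sweeps PAM over views and k, extracts
    consensus blocks from the co-clustering matrix and merges statistically
    indistinguishable clusters.  Deterministic under the config seed.
    """
    cfg = config or ClusterConfig()
    if expr.n_cells < cfg.min_size:
        raise ValueError(
            f"need at least min_size={cfg.min_size} cells, have {expr.n_cells}")
    provenance = asdict(cfg)
    if cfg.embedding == "auto":
        ec = choose_embedding(expr, cfg.seed, cfg.n_var_genes,
                              cfg.bins_per_axis)
        embedding = ec.choice
        provenance["entropy_pca"] = ec.pca_entropy
        provenance["entropy_tsne"] = ec.tsne_entropy
    else:
        embedding = cfg.embedding
    provenance["embedding_used"] = embedding
    views = make_views(expr, embedding, cfg.seed, cfg)
    labelings = pam_sweep(views, cfg.k_min, cfg.k_max, cfg.seed)
    cc = cocluster_matrix(labelings)
    labels = consensus_clusters(cc, cfg.self_similarity, cfg.min_size)
    labels = merge_similar_clusters(expr, labels,
                                    cfg.de_proportion_threshold, cfg.adj_p,
                                    cfg.n_var_genes)
    labels = _relabel(labels)
    n_clusters = len(set(labels.tolist()) - {UNASSIGNED})
    provenance["n_views"] = len(views)
    provenance["n_labelings"] = len(labelings)
    logger.info("robust clustering: %d clusters, %.1f%% of cells assigned",
                n_clusters, 100.0 * float((labels != UNASSIGNED).mean()))
    return RobustClustering(labels, cc, n_clusters, provenance)
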