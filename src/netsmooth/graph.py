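"""Gene networks used as smoothing priors.

A :class:`GeneNetwork` is a weighted (possibly signed, possibly directed)
graph over gene identifiers.  For diffusion it is turned into a
column-normalized adjacency matrix: each gene's outgoing edge weights are
scaled to sum to one (sum of absolute values for signed networks), so that
hub genes do not dominate their neighbours.  Genes left without edges keep
an all-zero column and behave as pass-through nodes under the random-walk
kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "NormalizedAdjacency",
    "load_edge_list",
    "filter_by_score_quantile",
    "normalize",
    "shuffle_gene_labels",
    "subset_to_genes",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file contains a malformed row."""


@dataclass
class GeneNetwork:
    """Weighted gene-gene graph.

    Parameters
    ----------
    genes
        Ordered, unique gene identifiers. Includes isolated genes.
    edges
        Mapping ``(source, target) -> weight``.  For undirected networks each
        edge is stored once under a canonical (sorted) key and symmetrized
        when the adjacency matrix is built.  No self-loops.
    directed
        Whether edge direction is meaningful.
    signed
        Whether negative weights (inhibitory interactions) are allowed.
    """

    genes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    directed: bool = False
    signed: bool = False

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on gene {u!r}")
            if not self.signed and w <= 0:
                raise ValueError(
                    f"non-positive weight {w} on edge ({u}, {v}) in unsigned network"
                )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_sequence(self) -> list[int]:
        """Sorted degree sequence (undirected degree: incident edge count)."""
        deg: dict[str, int] = {g: 0 for g in self.genes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return sorted(deg.values())


@dataclass
class NormalizedAdjacency:
    """Column-normalized adjacency bound to its gene order.

    Every column with at least one nonzero entry sums to 1 (sum of absolute
    values for signed networks); the diagonal is zero.
    """

    matrix: sp.csc_matrix
    gene_order: list[str]
    signed: bool = False

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)

    def toarray(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def _canonical_key(u: str, v: str, directed: bool) -> tuple[str, str]:
    if directed:
        return (u, v)
    return (u, v) if u <= v else (v, u)


def load_edge_list(
    path,
    directed: bool = False,
    signed: bool = False,
    header: bool = False,
    delimiter: str | None = None,
) -> GeneNetwork:
    """Read a 2- or 3-column edge list (``gene_a  gene_b  [weight]``).

    A missing weight column means weight 1.0.  Duplicate (source, target)
    pairs collapse to the maximum absolute weight; self-loops are dropped
    with a warning.  Malformed rows raise :class:`EdgeListParseError`
    naming the line.
    """
    genes: dict[str, None] = {}  # insertion-ordered set
    edges: dict[tuple[str, str], float] = {}
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            if len(parts) not in (2, 3):
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise EdgeListParseError(
                        f"{path}: line {lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
            else:
                w = 1.0
            genes.setdefault(u)
            genes.setdefault(v)
            if u == v:
                n_self_loops += 1
                continue
            key = _canonical_key(u, v, directed)
            if key in edges:
                if abs(w) > abs(edges[key]):
                    edges[key] = w
            else:
                edges[key] = w
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self_loops)
    return GeneNetwork(list(genes), edges, directed=directed, signed=signed)


def filter_by_score_quantile(network: GeneNetwork, quantile: float) -> GeneNetwork:
    """Keep only edges with weight strictly above the given score quantile.

    Reproduces the construction of a confidence-filtered smoothing graph
    from a scored interaction database (e.g. keeping the 10% most confident
    STRING interactions with ``quantile=0.9``).  Retained edges become
    unweighted (weight 1.0); isolated genes stay in the gene list.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError(f"quantile must be in [0, 1), got {quantile}")
    if not network.edges:
        raise ValueError("cannot filter an empty edge set")
    weights = np.array(list(network.edges.values()), dtype=float)
    if quantile == 0.0:
        kept = dict.fromkeys(network.edges, 1.0)
    else:
        cut = float(np.quantile(weights, quantile))  # linear-interp empirical CDF
        kept = {k: 1.0 for k, w in network.edges.items() if w > cut}
    logger.info(
        "score-quantile filter q=%.3g: kept %d / %d edges", quantile, len(kept),
        network.n_edges,
    )
    return GeneNetwork(list(network.genes), kept, directed=network.directed,
                       signed=False)


def normalize(network: GeneNetwork) -> NormalizedAdjacency:
    """Column-normalized adjacency matrix for diffusion.

    Undirected edges are symmetrized; each column is divided by its sum of
    absolute values (all-zero columns stay zero), so every gene's outgoing
    weights sum to one in absolute value and the spectral radius of the
    result is at most one.
    """
    if network.n_genes == 0:
        raise ValueError("cannot normalize an empty network")
    idx = {g: i for i, g in enumerate(network.genes)}
    # A[target, source] = w: column j is the outgoing distribution of gene j
    rows, cols, vals = [], [], []
    for (u, v), w in network.edges.items():
        rows.append(idx[v])
        cols.append(idx[u])
        vals.append(w)
        if not network.directed:
            rows.append(idx[u])
            cols.append(idx[v])
            vals.append(w)
    n = network.n_genes
    a = sp.csc_matrix(
        (np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n)
    )
    col_sums = np.asarray(abs(a).sum(axis=0)).ravel()
    scale = np.divide(1.0, col_sums, out=np.zeros_like(col_sums),
                      where=col_sums > 0)
    a = a @ sp.diags(scale)
    return NormalizedAdjacency(a.tocsc(), list(network.genes),
                               signed=network.signed)


def shuffle_gene_labels(network: GeneNetwork, seed: int) -> GeneNetwork:
    """Permute gene identifiers uniformly at random, keeping the graph fixed.

    The edge structure (and hence the degree sequence) is untouched; only
    which gene sits on which node changes.  This is the null model for
    testing whether the network carries real prior information: a shuffled
    network has the same topology but its edges no longer connect
    functionally related genes.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(network.n_genes)
    mapping = {g: network.genes[p] for g, p in zip(network.genes, perm)}
    edges = {
        _canonical_key(mapping[u], mapping[v], network.directed): w
        for (u, v), w in network.edges.items()
    }
    return replace(network, genes=list(network.genes), edges=edges)


def subset_to_genes(network: GeneNetwork, keep) -> GeneNetwork:
    """Induced subgraph on ``keep`` ∩ network genes."""
    keep = set(keep)
    genes = [g for g in network.genes if g in keep]
    if not genes:
        raise ValueError("no overlap between keep-set and network genes")
    gene_set = set(genes)
    edges = {
        (u, v): w for (u, v), w in network.edges.items()
        if u in gene_set and v in gene_set
    }
    return replace(network, genes=genes, edges=edges)
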