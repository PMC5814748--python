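"""Data-driven selection of the smoothing parameter alpha.

The random walk has one free parameter: the restart rate ``1 - alpha``.
Because the right amount of smoothing is dataset-dependent, alpha is chosen
by re-running the full robust clustering pipeline on the smoothed data for
each alpha on a grid and picking the value that maximizes either the
proportion of cells placed in robust clusters (the default criterion) or
the grid entropy of the 2-D embedding.  The grid always contains 0, the
no-smoothing baseline, and ties break toward smaller alpha (less
smoothing).  The same master seed is used at every alpha so that
differences between grid points are attributable to alpha alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterConfig, RobustClustering, robust_cluster
from .graph import GeneNetwork
from .metrics import (adjusted_mutual_information, choose_embedding,
                      cluster_purity, proportion_robustly_clustered)
from .smoothing import ExpressionMatrix, netsmooth

logger = logging.getLogger(__name__)

__all__ = ["AlphaScan", "DEFAULT_GRID", "scan_alpha", "pick_alpha_entropy"]

DEFAULT_GRID = tuple(round(0.1 * i, 1) for i in range(10))  # 0.0 .. 0.9


@dataclass
class AlphaScan:
    """Per-alpha record of the robustness scan."""

    grid: list[float]
    proportion_robust: list[float]
    entropy_2d: list[float]
    chosen_alpha: float
    criterion: str
    purity: list[float] | None = None  # median cluster purity per alpha
    ami: list[float] | None = None
    clusterings: dict = field(default_factory=dict, repr=False)

    def as_table(self) -> list[dict]:
        rows = []
        for i, a in enumerate(self.grid):
            row = {"alpha": a,
                   "proportion_robust": self.proportion_robust[i],
                   "entropy_2d": self.entropy_2d[i]}
            if self.purity is not None:
                row["median_purity"] = self.purity[i]
            if self.ami is not None:
                row["ami"] = self.ami[i]
            rows.append(row)
        return rows


def _argmax_smallest(grid: list[float], scores: list[float]) -> float:
    """Grid value with the highest score; ties go to the smallest alpha."""
    best = max(scores)
    for a, s in zip(grid, scores):
        if s >= best - 1e-12:
            return a
    return grid[0]  # pragma: no cover


def scan_alpha(
    expr: ExpressionMatrix,
    network: GeneNetwork,
    grid=DEFAULT_GRID,
    seed: int = 0,
    truth=None,
    config: ClusterConfig | None = None,
    criterion: str = "robustness",
    clip_negative: bool = False,
) -> AlphaScan:
    """Scan alpha, robust-clustering the smoothed data at each grid value.

    Records the proportion of cells in robust clusters and the 2-D grid
    entropy per alpha; when external ``truth`` labels are supplied, also
    median cluster purity and AMI.  ``chosen_alpha`` maximizes the selected
    criterion (``"robustness"`` or ``"entropy"``).
    """
    grid = [float(a) for a in grid]
    if any(not 0.0 <= a < 1.0 for a in grid):
        raise ValueError("grid values must be in [0, 1)")
    if criterion not in ("robustness", "entropy"):
        raise ValueError(f"unknown criterion {criterion!r}")
    cfg = config or ClusterConfig(seed=seed)
    cfg.seed = seed
    prop, entropy, purity, ami = [], [], [], []
    clusterings: dict[float, RobustClustering] = {}
    for a in grid:
        clip = clip_negative or network.signed
        sm = expr.copy() if a == 0.0 else netsmooth(expr, network, a,
                                                    clip_negative=clip)
        rc = robust_cluster(sm, cfg)
        clusterings[a] = rc
        prop.append(proportion_robustly_clustered(rc.labels))
        ec = choose_embedding(sm, seed, cfg.n_var_genes, cfg.bins_per_axis)
        entropy.append(max(ec.pca_entropy, ec.tsne_entropy))
        if truth is not None:
            if rc.n_clusters > 0:
                purity.append(cluster_purity(rc.labels, truth).median)
                ami.append(adjusted_mutual_information(rc.labels, truth))
            else:
                purity.append(float("nan"))
                ami.append(0.0)
        logger.info("alpha=%.2f: %.1f%% robust, entropy %.3f",
                    a, 100 * prop[-1], entropy[-1])
    scores = prop if criterion == "robustness" else entropy
    chosen = _argmax_smallest(grid, scores)
    return AlphaScan(grid, prop, entropy, chosen, criterion,
                     purity if truth is not None else None,
                     ami if truth is not None else None,
                     clusterings)


def pick_alpha_entropy(
    expr: ExpressionMatrix,
    network: GeneNetwork,
    grid=DEFAULT_GRID,
    seed: int = 0,
    config: ClusterConfig | None = None,
    clip_negative: bool = False,
) -> float:
    """Alpha maximizing the 2-D embedding grid entropy of the smoothed data.

    A cheaper alternative to the robustness criterion: no clustering is
    run, only the 2-D embeddings.  Ties break toward smaller alpha.
    """
    grid = [float(a) for a in grid]
    if any(not 0.0 <= a < 1.0 for a in grid):
        raise ValueError("grid values must be in [0, 1)")
    cfg = config or ClusterConfig(seed=seed)
    entropies = []
    for a in grid:
        clip = clip_negative or network.signed
        sm = expr.copy() if a == 0.0 else netsmooth(expr, network, a,
                                                    clip_negative=clip)
        ec = choose_embedding(sm, seed, cfg.n_var_genes, cfg.bins_per_axis)
        entropies.append(max(ec.pca_entropy, ec.tsne_entropy))
    return _argmax_smallest(grid, entropies)
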