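"""Random-walk-with-restarts smoothing of expression matrices.

A walker on the gene graph moves to a neighbour with probability ``alpha``
times the (column-normalized) edge weight and restarts at its origin with
probability ``1 - alpha``.  The stationary distribution of this process
defines the smoothing kernel

    K = (1 - alpha) (I - alpha A)^{-1}

and the network-smoothed expression profile is ``E_sm = K E``.  ``alpha = 0``
is a perfect restart rate — no smoothing; larger ``alpha`` diffuses each
gene's signal further across its network neighbourhood, so a gene with a
spuriously low count (a dropout) whose neighbours are highly expressed is
pulled up after smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import GeneNetwork, NormalizedAdjacency, normalize, subset_to_genes

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SmoothingKernel",
    "build_kernel",
    "smooth_iterative",
    "netsmooth",
]

# Above this size a dense factorization of (I - alpha*A) is avoided.
_DENSE_SOLVE_MAX_GENES = 4000


@dataclass
class ExpressionMatrix:
    """Genes-by-cells expression matrix with identifiers.

    ``values[i, j]`` is the (normalized) count of gene ``gene_ids[i]`` in
    cell ``cell_ids[j]``.  Input values must be nonnegative; identifiers
    must be unique and match the matrix dimensions.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.cell_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float),
                   [str(g) for g in frame.index],
                   [str(c) for c in frame.columns])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_ids),
                                list(self.cell_ids))


@dataclass
class SmoothingKernel:
    """Dense diffusion kernel ``K = (1 - alpha)(I - alpha A)^{-1}``."""

    matrix: np.ndarray
    alpha: float
    gene_order: list[str]


def build_kernel(adj: NormalizedAdjacency, alpha: float) -> SmoothingKernel:
    """Closed-form RWR kernel for a normalized adjacency.

    Realized as a linear solve against the identity (LU factorization),
    never an explicit matrix inverse.  For an unsigned adjacency with no
    zero columns the kernel is column-stochastic; zero-degree genes get an
    identity column and pass their own signal through unchanged.
    """
    _check_alpha(alpha)
    n = adj.n_genes
    if alpha == 0.0:
        return SmoothingKernel(np.eye(n), 0.0, list(adj.gene_order))
    system = sp.identity(n, format="csc") - alpha * adj.matrix
    try:
        if n <= _DENSE_SOLVE_MAX_GENES:
            k = scipy.linalg.solve(system.toarray(), np.eye(n))
        else:
            lu = spla.splu(system.tocsc())
            k = lu.solve(np.eye(n))
    except (scipy.linalg.LinAlgError, RuntimeError) as exc:  # pragma: no cover
        raise ArithmeticError(f"singular smoothing system at alpha={alpha}") from exc
    k = (1.0 - alpha) * k
    # Fully isolated genes (zero row and column) have no neighbours to
    # exchange signal with; they pass their own signal through unchanged
    # rather than being damped by the restart factor.
    absmat = abs(adj.matrix)
    isolated = (np.asarray(absmat.sum(axis=0)).ravel() == 0) & \
               (np.asarray(absmat.sum(axis=1)).ravel() == 0)
    for i in np.flatnonzero(isolated):
        k[i, i] = 1.0
    return SmoothingKernel(k, alpha, list(adj.gene_order))


def smooth_iterative(
    f0: np.ndarray,
    adj: NormalizedAdjacency,
    alpha: float,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> tuple[np.ndarray, bool]:
    """Power iteration ``f_{t+1} = alpha A f_t + (1 - alpha) f0``.

    Returns the final iterate and a convergence flag.  Converges
    geometrically at rate ``alpha`` for a (sub)stochastic adjacency; used as
    a cross-check of, and memory-light alternative to, :func:`build_kernel`.
    """
    _check_alpha(alpha)
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    f0 = np.asarray(f0, dtype=float)
    squeeze = f0.ndim == 1
    f = f0.reshape(-1, 1) if squeeze else f0
    base = (1.0 - alpha) * f
    cur = f
    converged = False
    for _ in range(max_iter):
        nxt = alpha * (adj.matrix @ cur) + base
        delta = np.max(np.abs(nxt - cur))
        cur = nxt
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "RWR iteration did not converge in %d steps (residual %.3g)",
            max_iter, float(delta),
        )
    # isolated genes pass through unchanged, as in the closed-form kernel
    absmat = abs(adj.matrix)
    isolated = (np.asarray(absmat.sum(axis=0)).ravel() == 0) & \
               (np.asarray(absmat.sum(axis=1)).ravel() == 0)
    if isolated.any():
        cur = cur.copy()
        cur[isolated, :] = f[isolated, :]
    return (cur.ravel() if squeeze else cur), converged


def netsmooth(
    expr: ExpressionMatrix,
    network: GeneNetwork,
    alpha: float,
    clip_negative: bool = False,
) -> ExpressionMatrix:
    """Smooth an expression matrix over a gene network.

    Genes shared between the matrix and the network are smoothed with the
    RWR kernel restricted to that shared set; genes absent from the network
    pass through unchanged.  Output row order and identifiers equal the
    input's.  For signed networks ``clip_negative`` is mandatory and
    negative smoothed values are set to zero.
    """
    _check_alpha(alpha)
    if network.signed and not clip_negative:
        raise ValueError("clip_negative=True is required for signed networks")
    shared = [g for g in expr.gene_ids if g in set(network.genes)]
    if not shared:
        raise ValueError(
            "no genes shared between the expression matrix and the network "
            f"(expression ids look like {expr.gene_ids[:3]}, network ids like "
            f"{network.genes[:3]}; check the identifier namespaces)"
        )
    logger.info(
        "netsmooth alpha=%.3g: %d genes covered by the network, %d pass through",
        alpha, len(shared), expr.n_genes - len(shared),
    )
    out = expr.values.copy()
    if alpha > 0.0:
        sub = subset_to_genes(network, shared)
        adj = normalize(sub)
        kernel = build_kernel(adj, alpha)
        order = {g: i for i, g in enumerate(kernel.gene_order)}
        rows = np.array([i for i, g in enumerate(expr.gene_ids) if g in order])
        # map expression rows onto the kernel's gene order, smooth, restore
        perm = np.array([order[expr.gene_ids[i]] for i in rows])
        aligned = np.empty((len(rows), expr.n_cells))
        aligned[perm, :] = expr.values[rows, :]
        smoothed = kernel.matrix @ aligned
        out[rows, :] = smoothed[perm, :]
    if clip_negative:
        np.clip(out, 0.0, None, out=out)
    return ExpressionMatrix(out, list(expr.gene_ids), list(expr.cell_ids))


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
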