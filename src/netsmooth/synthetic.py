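"""Synthetic networks and dropout-corrupted count matrices with ground truth.

The generator emulates the regime network smoothing targets: cell types are
defined by coordinated expression programs (gene modules), the prior graph
is modular and aligned with those programs, and measured counts suffer
expression-dependent dropout — lowly expressed genes are far more likely to
record a false zero.  Concretely:

* the network is a stochastic block model whose blocks are the gene modules;
* baseline gene means are log-normal; each cell type up-regulates its own
  subset of modules by a fold change; per-cell means are scaled to a target
  library size; counts are negative binomial;
* dropout zeroes each entry with probability ``logistic(-steepness *
  (log-mean - midpoint))``, so the dropout probability falls with expression.

Everything is deterministic under the seed, and the full ground truth
(labels, means, dropout mask, module membership) is returned so every
pipeline stage can be tested without external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph import GeneNetwork
from .smoothing import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticDataset",
    "generate_network",
    "generate_counts",
    "benchmark_instance",
    "BENCHMARK_PROFILES",
]


@dataclass
class SyntheticDataset:
    """A generated dataset with complete ground truth."""

    counts: ExpressionMatrix
    true_labels: np.ndarray          # cell type per cell
    network: GeneNetwork
    modules: np.ndarray              # module id per gene
    true_means: np.ndarray           # genes x types expected expression
    dropout_applied: np.ndarray      # genes x cells boolean mask
    seed: int
    params: dict


def generate_network(
    n_genes: int,
    n_modules: int,
    p_within: float,
    p_between: float,
    seed: int,
) -> tuple[GeneNetwork, np.ndarray]:
    """Stochastic-block-model gene network.

    Genes are split as evenly as possible into ``n_modules`` modules; an
    (unweighted, undirected) edge appears with probability ``p_within``
    inside a module and ``p_between`` across modules.  Returns the network
    and the per-gene module assignment.
    """
    if not p_within > p_between:
        raise ValueError("p_within must exceed p_between")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    modules = np.arange(n_genes) % n_modules
    iu, ju = np.triu_indices(n_genes, k=1)
    prob = np.where(modules[iu] == modules[ju], p_within, p_between)
    mask = rng.random(prob.size) < prob
    edges = {(genes[i], genes[j]): 1.0
             for i, j in zip(iu[mask], ju[mask])}
    return GeneNetwork(genes, edges, directed=False, signed=False), modules


def _solve_dropout_midpoint(
    log_mu: np.ndarray,
    nb_zero_prob: np.ndarray,
    target_zero_fraction: float,
    steepness: float,
) -> float:
    """Bisection for the logistic midpoint hitting a target zero fraction.

    The expected overall zero fraction combines the per-entry sampling-zero
    probability of the negative binomial with logistic dropout; the
    midpoint is solved so the expectation matches the target.
    """
    def expected_zero(mid: float) -> float:
        p_drop = 1.0 / (1.0 + np.exp(steepness * (log_mu - mid)))
        return float(np.mean(p_drop + (1.0 - p_drop) * nb_zero_prob))

    lo, hi = log_mu.min() - 20.0, log_mu.max() + 20.0
    if target_zero_fraction <= expected_zero(lo):
        return lo
    if target_zero_fraction >= expected_zero(hi):
        return hi
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expected_zero(mid) < target_zero_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_counts(
    network_modules: np.ndarray,
    n_cells: int,
    n_types: int,
    libsize: float = 2000.0,
    nb_dispersion: float = 0.3,
    dropout_midpoint: float | None = None,
    dropout_steepness: float = 1.0,
    seed: int = 0,
    fold_change: float = 4.0,
    target_zero_fraction: float | None = 0.4,
    network: GeneNetwork | None = None,
    align_programs: bool = True,
) -> SyntheticDataset:
    """Negative-binomial counts with type-specific programs and dropout.

    Each cell type up-regulates a distinct subset of the gene modules by
    ``fold_change``; expected counts are scaled so each cell's total is
    ``libsize``; counts are NB with the given dispersion (variance
    ``mu + dispersion * mu^2``); dropout is Bernoulli per entry with
    probability ``logistic(-steepness * (log-mean - midpoint))``.  When
    ``dropout_midpoint`` is None it is solved so the expected overall zero
    fraction equals ``target_zero_fraction``.  ``align_programs=False``
    decouples expression programs from the module structure (an
    uninformative-network negative control).
    """
    modules = np.asarray(network_modules)
    n_genes = modules.size
    n_modules = int(modules.max()) + 1
    if n_types > n_modules:
        raise ValueError("n_types must not exceed the number of modules")
    rng = np.random.default_rng(seed)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    program_modules = modules
    if not align_programs:
        program_modules = rng.permutation(modules)
    # type t up-regulates module t; remaining modules are shared background
    type_means = np.tile(base[:, None], (1, n_types))
    for t in range(n_types):
        up = program_modules == t
        type_means[up, t] *= fold_change
    type_means *= libsize / type_means.sum(axis=0, keepdims=True)

    labels = np.repeat(np.arange(n_types), int(np.ceil(n_cells / n_types)))[:n_cells]
    mu = type_means[:, labels]  # genes x cells

    # NB parameterized by mean and dispersion: var = mu + d*mu^2
    if nb_dispersion > 0:
        r = 1.0 / nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p).astype(float)
        nb_zero_prob = p ** r
    else:
        counts = rng.poisson(mu).astype(float)
        nb_zero_prob = np.exp(-mu)

    log_mu = np.log(np.maximum(mu, 1e-12))
    if dropout_midpoint is None:
        if target_zero_fraction is None:
            raise ValueError("give dropout_midpoint or target_zero_fraction")
        dropout_midpoint = _solve_dropout_midpoint(
            log_mu, nb_zero_prob, target_zero_fraction, dropout_steepness)
    p_drop = 1.0 / (1.0 + np.exp(dropout_steepness * (log_mu - dropout_midpoint)))
    dropped = rng.random(mu.shape) < p_drop
    counts[dropped] = 0.0

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    cell_ids = [f"cell{j:04d}" for j in range(n_cells)]
    expr = ExpressionMatrix(counts, gene_ids, cell_ids)
    params = dict(n_cells=n_cells, n_types=n_types, libsize=libsize,
                  nb_dispersion=nb_dispersion,
                  dropout_midpoint=float(dropout_midpoint),
                  dropout_steepness=dropout_steepness,
                  fold_change=fold_change, seed=seed,
                  align_programs=align_programs,
                  realized_zero_fraction=float(np.mean(counts == 0)))
    logger.info("synthetic counts: %d genes x %d cells, %.1f%% zeros",
                n_genes, n_cells, 100 * params["realized_zero_fraction"])
    return SyntheticDataset(expr, labels, network, modules, type_means,
                            dropped, seed, params)


#: Named benchmark presets.  "default" is the reference condition used by
#: the cross-module tests: 300 genes in 6 modules, 3 cell types, 150 cells,
#: ~40% zeros overall.
BENCHMARK_PROFILES = {
    "easy": dict(n_genes=300, n_modules=6, n_types=3, n_cells=150,
                 target_zero_fraction=0.20, fold_change=6.0,
                 nb_dispersion=0.3, seed=1235),
    "default": dict(n_genes=300, n_modules=6, n_types=3, n_cells=150,
                    target_zero_fraction=0.40, fold_change=2.5,
                    nb_dispersion=1.0, seed=1234),
    "hard": dict(n_genes=300, n_modules=6, n_types=3, n_cells=150,
                 target_zero_fraction=0.65, fold_change=2.5,
                 nb_dispersion=0.5, seed=1236),
}


def benchmark_instance(profile: str = "default") -> SyntheticDataset:
    """Generate a named benchmark preset (deterministic)."""
    if profile not in BENCHMARK_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; "
                         f"choose from {sorted(BENCHMARK_PROFILES)}")
    p = BENCHMARK_PROFILES[profile]
    network, modules = generate_network(
        p["n_genes"], p["n_modules"], p_within=0.2, p_between=0.01,
        seed=p["seed"])
    ds = generate_counts(
        modules, n_cells=p["n_cells"], n_types=p["n_types"],
        target_zero_fraction=p["target_zero_fraction"],
        fold_change=p["fold_change"], nb_dispersion=p["nb_dispersion"],
        seed=p["seed"], network=network)
    ds.params["profile"] = profile
    ds.params.update(p)
    return ds
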