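# netsmooth

Network-diffusion smoothing for single-cell RNA-seq, with robust consensus
clustering and data-driven selection of the smoothing strength.

## The problem

Single-cell RNA-seq suffers from *dropout*: a gene that is actually
expressed records a false zero because its transcripts were not captured,
and the dropout rate is highest for lowly expressed genes.  The resulting
sparsity degrades clustering and other downstream analyses.  Genes do not
act alone, though — they work in pathways and complexes — so a prior
gene–gene interaction network (e.g. a confidence-filtered STRING graph)
tells us which neighbours a gene's missing signal can be borrowed from.

## The method

Expression profiles are diffused over the gene network with a random walk
with restarts.  For a column-normalized adjacency matrix *A* (each gene's
outgoing edge weights sum to 1) and restart rate 1 − α, the walk

  f_{t+1} = α A f_t + (1 − α) f_0

converges to f_∞ = (1 − α)(I − αA)⁻¹ f_0, defining the smoothing kernel

  **K_α = (1 − α)(I − αA)⁻¹**,  E_smooth = K_α E,

applied column-wise to the genes × cells matrix *E*.  α = 0 means no
smoothing; larger α diffuses signal further across the network.  Because
*A* is column-stochastic, each cell's total expression is conserved.

Around the kernel the package provides:

- **Robust consensus clustering** — PAM (k-medoids) over many views of the
  data (PCA 5/15/50 components or t-SNE 2/3 dimensions on the 500 most
  variable genes, plus the raw top 100/500/1000 variable genes) for
  k = 5…10; pairwise co-clustering frequencies; consensus blocks from an
  average-linkage dendrogram (mean internal co-clustering ≥ 0.6, size ≥ 20;
  other cells stay unassigned); merging of clusters whose differential-
  expression fraction is below 0.1 at BH-adjusted p < 0.05.
- **Evaluation metrics** — per-cluster purity against external labels,
  adjusted mutual information AMI = (MI − E[MI]) / (max(H_L, H_C) − E[MI]),
  proportion of cells in robust clusters, and Shannon entropy of a 2-D
  embedding binned on a 20×20 grid (used to choose PCA vs t-SNE).
- **α selection** — re-run the clustering pipeline on smoothed data over a
  grid of α and pick the value maximizing the proportion of robustly
  clustered cells (or, alternatively, the embedding entropy).
- **Synthetic benchmarks** — modular (stochastic-block-model) gene networks
  aligned with cell-type expression programs, negative-binomial counts and
  expression-dependent logistic dropout, with full ground truth.

## Worked example

`examples/03_alpha_selection.py` generates the default benchmark
(300 genes, 6 network modules, 3 cell types, 150 cells, ~40% zeros) and
scans α:

```
 alpha   robust   purity    AMI
   0.0     0.00      nan   0.00
   0.1     0.00      nan   0.00
   0.2     0.51     1.00   1.00
   0.3     0.17     1.00   0.00
   0.4     0.51     1.00   1.00
   0.5     0.72     1.00   1.00
   0.6     0.63     1.00   1.00
   0.7     0.73     1.00   0.77
   0.8     0.85     1.00   0.64
   0.9     0.82     1.00   0.74
chosen alpha: 0.8
```

At α = 0 (no smoothing) the dropout-corrupted data yields no robust
clusters at all.  Smoothing over the gene network restores the structure:
at the chosen α = 0.8, 85% of cells land in robust clusters, every cluster
is pure, and the AMI against the true cell types is 0.64 (1.00 at
α = 0.4–0.6).  `examples/04_shuffled_network_control.py` shows this is the
network's doing, not generic shrinkage: with gene labels shuffled, smoothing
usually recovers nothing (AMI 0 in 4 of 5 shuffles).

The other examples show the smoothing primitive itself
(`01_network_smoothing.py`) and the clustering/metrics stack
(`02_robust_clustering.py`).

A thin CLI wraps the same functions:

```sh
netsmooth simulate --profile default --out data/
netsmooth smooth --expr data/counts.mtx --network data/network.tsv --alpha 0.5 --out smoothed.tsv
netsmooth cluster --expr smoothed.tsv --labels data/truth.tsv --seed 1234 --out clust/
netsmooth evaluate --clusters clust/clusters.tsv --truth data/truth.tsv
```

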