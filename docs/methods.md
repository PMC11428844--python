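# Methods

## Model

The pipeline embeds cells with a variational graph autoencoder whose decoder
is attention-based, then clusters the embedding.

**Preprocessing.** Raw UMI counts R (cells × genes) are filtered (cells
expressing < `min_genes_per_cell` genes, default 200; then genes expressed in
< `min_cells_per_gene` of the surviving cells, default 3 — cells first, genes
recomputed on the remainder). Counts are optionally scaled per cell to
`target_sum` (default 10⁴; `total_normalize=False` reproduces the log-only
regime some datasets call for) and log1p-transformed. Highly variable genes
are ranked by binned normalized dispersion: per-gene dispersion var/mean in
log space, z-scored within 20 quantile bins of the mean; z-ties are broken by
raw dispersion so zero-variance genes in singleton bins cannot win by index.
The top `n_top_hvg` (default 2000) are kept, z-scored per gene with the
population standard deviation (ddof=0 throughout the package), and clipped
from above at `scale_max` = 10 (upper-only, a literal reading of "maximum
value"). PCA to `pca_dim` = 50 components (or min(n, m) − 1 if smaller)
yields Y; each component's sign is fixed by making its largest-magnitude
loading positive, so runs are deterministic across solvers.

**Cell graph.** S is the matrix of pairwise Pearson correlations between
cell rows of the scaled expression matrix, negatives clipped to 0 (the
downstream row normalization assumes nonnegative weights), diagonal zeroed;
constant rows get zero similarity. Network enhancement then denoises S:

- transition matrix P: each row of S restricted to its `k_ne` = 10 largest
  entries and normalized to sum 1 (all-zero rows fall back to uniform
  weights over the lowest-index neighbors, with a warning);
- local network matrix T_ij = Σ_k P_ik P_jk / Σ_v P_vk, with 0/0 read as 0
  when a column of P is empty; the inner index runs over all n cells
  (the localized variant restricted to neighbor sets is deliberately not
  used — the published chain states the full sum);
- one diffusion step Ŝ = α·T S T + (1 − α)·T with `ne_alpha` = 0.5
  (`ne_iterations` exposes repeated application for experimentation;
  default 1);
- thresholding E_ij = S_ij where Ŝ_ij ≥ t, else 0, symmetrized by
  elementwise max. t is the `ne_threshold_quantile` quantile of the
  off-diagonal Ŝ entries (an absolute override exists).

The default quantile is 0.9. This is a deliberate design point: with a
median threshold the surviving support on realistic clustered data strictly
contains every cell's `k_graph` nearest neighbors, so the mask changes
nothing downstream and the denoising stage is a no-op. At 0.9 roughly 10% of
cell pairs survive (about twice `k_graph` edges per row), which prunes weak
spurious edges inside the kNN range while leaving cluster structure intact.

The final graph A keeps each cell's `k_graph` = 15 largest E entries
(isolated rows are rescued from S; ties break toward the lower index),
row-normalizes, symmetrizes by averaging, and zeroes the diagonal. A
disconnected node after the fallback is an error: the graph convolution
requires every cell to have a neighbor.

**Autoencoder.** The encoder is a two-layer GCN over
Ã = D^{−1/2}(A + I)D^{−1/2}; self-loops are added before normalization
(`add_self_loops`, default on) because a zero-diagonal adjacency would
discard each cell's own features. The two posterior heads share the first
layer: H = ReLU(Ã Y W₀), μ = Ã H W₁, log σ = Ã H W₂. No biases in GCN
layers. Sampling uses Z = μ + ε ⊙ exp(log σ) with ε ~ N(0, I) from the run's
seeded generator; evaluation mode returns Z = μ.

The decoder is two stacked single-head GAT layers (latent → hidden with ELU,
hidden → input with identity; biases allowed). Attention follows
e_ij = LeakyReLU(aᵀ[W h_i ‖ W h_j]) with slope 0.2, softmax-normalized over
the neighborhoods given by the nonzero structure of A plus self-loops. The
inner-product decoder sigmoid(Z Zᵀ) is retained for the no-attention
ablation; since it reconstructs a cell–cell matrix rather than features, its
reconstruction error is measured against the cell graph A (the natural
target of a graph-reconstructing decoder).

**Loss.** L = α·L_rec + β·L_KL with both weights default 1. L_rec is
(1/n)‖Y − Y′‖² — per-cell, not per-entry, averaging, taken literally from
the defining formula (a mean-absolute-error switch exists,
`reconstruction="mae"`, off by default). L_KL is the KL divergence of each
cell's posterior from the standard normal, ½Σ(μ² + σ² − log σ² − 1) per
cell, averaged over cells; σ² is computed as exp(2·log σ).

**Training.** Full-batch Adam (lr `learning_rate` = 1e-3, no weight decay)
for at most `max_epochs` = 300 epochs. Every `check_interval` = 10 epochs
the evaluation embedding is clustered with k-means and scored by the mean
silhouette coefficient; the best-scoring checkpoint is kept and training
stops after `patience_checks` = 2 consecutive checks more than
`drop_tolerance` = 0.01 below the best. The best checkpoint — not the last
epoch — is returned, because the stop rule by construction detects decline
after the peak. `fixed_epochs` disables the checks (the fixed-epoch
ablation defaults to 180). The silhouette uses k-means labels recomputed at
each check.

**Clustering.** k is estimated by Leiden community detection
(RB-configuration partition, `leiden_resolution` = 1.0, seeded) on an
unweighted kNN graph (`leiden_neighbors` = 15) of the PCA matrix Y, unless
`n_clusters` overrides it. Final labels come from k-means++ with
`kmeans_restarts` = 20 initializations on the returned embedding.

**Metrics.** ARI (pair counting on the contingency table, with a zero
denominator — both partitions trivial — scoring 1.0), NMI
(2·MI/(H(U) + H(V)) with natural logs and 0·log 0 := 0; zero total entropy
scores 1.0, zero MI scores 0.0), and the mean silhouette (Euclidean; a
singleton-cluster cell scores 0, as does a cell with a = b = 0). These are
implemented directly from the defining formulas; the test suite cross-checks
them against both brute-force reimplementations and scikit-learn.

## Numerical core

The model runs on a small reverse-mode automatic-differentiation engine over
NumPy arrays (`scvgatae.autograd`): broadcast-aware arithmetic, matmul, the
GCN/GAT activations, and a masked row softmax for attention, plus an Adam
optimizer. Gradient correctness is verified against central finite
differences in the test suite. At the problem sizes the package targets in
tests (hundreds to a few thousand cells; dense n × n attention), full-graph
NumPy training takes seconds per run on one CPU.

## Synthetic data

`scvgatae.synthetic` generates clustered counts: per-gene baseline means are
log-normal (heavy-tailed, as in real UMI data); each cluster up-shifts a
disjoint marker set of `de_fraction` of the genes by exp(`de_log_fold`);
counts are gamma-Poisson (negative binomial, variance μ + φμ² with
dispersion φ = `nb_dispersion`); dropout is an independent Bernoulli mask
applied after sampling, keeping the planted structure transparent. The
default spec — 300 cells, 1000 genes, 3 equal clusters, 10% markers at
log-fold 2, φ = 0.3, 30% dropout — is the condition under which the test
suite measures parameter recovery (median ARI/NMI over seeds 0–2).

The generator emulates dropout, overdispersion, and heavy-tailed expression,
but not batch effects, doublets, ambient RNA, library-size gradients
confounded with cell type, or trajectory (non-cluster) structure. Passing
recovery tests therefore demonstrates that the chain of graph denoising,
variational embedding, and clustering correctly recovers well-separated
discrete populations under dropout noise; it does not certify performance on
real tissues with overlapping or continuous populations.

## Design choices and degenerate inputs

- Hidden size 128 and latent size 16; sizes in this range are standard for
  graph autoencoders on a 50-dimensional PCA input and were fixed once.
- kNN ties everywhere break toward the lower index, making the whole graph
  chain a deterministic function of its input.
- All randomness (weight init, reparameterization draws, k-means, Leiden)
  derives from the single config seed; a pipeline run is bit-reproducible.
- Counts are densified in memory; at the package's target scales this is
  far below memory limits, but million-cell matrices would need a sparse
  path (a known limitation).
- Degenerate inputs fail loudly with the responsible stage named: QC that
  removes every cell or gene reports which threshold did it, a zero-total
  cell under normalization is an error (it should have been filtered), a
  disconnected graph node is an error, and a non-finite loss aborts
  training with the epoch in the message.

## Limitations

- k from Leiden at resolution 1.0 can over- or under-split datasets whose
  community structure differs from the k-means geometry; `n_clusters`
  overrides it.
- The adaptive stopper assumes silhouette rises then falls; on flat
  schedules it simply runs to `max_epochs`.
- Single attention head; no minibatching (full-graph training only); no
  ZINB likelihood — reconstruction is in PCA space, not count space.
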