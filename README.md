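# scvgatae

Unsupervised clustering of single-cell RNA-seq data with a **variational
graph attention autoencoder** over a **network-enhancement-denoised cell
graph**.

scRNA-seq count matrices are high-dimensional, sparse, and noisy: dropout
events and technical variation make naive cell–cell similarities unreliable,
and purely feature-based autoencoders ignore the structural relationships
between cells. This package targets analysts who want cluster labels for a
UMI count matrix (10x-style MTX directory or dense CSV/TSV) without manual
tuning of the number of clusters or the number of training epochs.

## Method

1. **Preprocessing.** QC filtering (cells expressing < 200 genes, genes
   expressed in < 3 cells), per-cell total-count normalization to 10⁴
   (optional), log1p, highly-variable-gene selection by binned normalized
   dispersion, per-gene z-scoring clipped at 10, and PCA to d = 50, giving
   the feature matrix Y ∈ ℝⁿˣᵈ.
2. **Cell graph.** Pearson correlations between cells (negatives clipped)
   form S; network enhancement denoises it:
   a row-stochastic transition matrix P restricted to each cell's k = 10
   strongest neighbors, a local network matrix
   T_ij = Σ_k P_ik P_jk / Σ_v P_vk, one diffusion step
   Ŝ = α·T S T + (1−α)·T, and a threshold mask E_ij = S_ij·1[Ŝ_ij ≥ t].
   kNN sparsification and row normalization of E give the symmetric cell
   graph A.
3. **Autoencoder.** A two-layer GCN encoder on Ã = D^{−1/2}(A+I)D^{−1/2}
   outputs a per-cell Gaussian posterior (μ, log σ); Z = μ + ε⊙σ is sampled
   with the reparameterization trick and decoded back to the feature space
   by two stacked graph-attention (GAT) layers. The loss is
   α·(1/n)‖Y − Y′‖² + β·KL(N(μ, σ²) ‖ N(0, I)).
4. **Adaptive stopping.** Every 10 epochs the evaluation embedding Z = μ is
   clustered by k-means and scored by the silhouette coefficient
   s = (b − a)/max(a, b); training keeps the best-scoring checkpoint and
   stops after a sustained drop.
5. **Clustering.** k-means on the final embedding, with k estimated by
   Leiden community detection on a kNN graph of Y.

Ablation variants from the method's design study — denoising off, an
inner-product decoder, an all-attention encoder, and fixed 180-epoch
training — are reachable through a single `ablation` config key.

## Worked example

```python
from scvgatae import RunConfig, run_pipeline
from scvgatae.synthetic import SimulationSpec, generate_counts

counts, truth = generate_counts(SimulationSpec(seed=0))  # 300 cells, 3 clusters
result = run_pipeline(counts, RunConfig(seed=0), truth)
print(f"estimated clusters: {result.k}")
print(f"epochs trained: {len(result.history.epochs)} "
      f"(best checkpoint at {result.history.best_epoch})")
for name, value in result.metrics.items():
    print(f"{name}: {value:.3f}")
```

prints

```
estimated clusters: 3
epochs trained: 80 (best checkpoint at 60)
silhouette: 0.657
ari: 1.000
nmi: 1.000
```

Leiden recovers the three planted clusters, adaptive stopping halts at epoch
80 keeping the epoch-60 checkpoint, and the k-means labels match the planted
partition perfectly (adjusted Rand index and normalized mutual information
both 1.0); the silhouette of 0.657 says the latent clusters are compact and
well separated.

The same run from a shell:

```sh
scvgatae simulate --out data/ --preset medium --seed 0
scvgatae run --counts data/ --format mtx --labels data/labels.csv --out results/ --seed 0
scvgatae evaluate --pred results/clusters.csv --truth data/labels.csv
```

Stage-wise subcommands (`preprocess`, `graph`, `train`, `cluster`) expose the
intermediate artifacts; see `scvgatae --help`.

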