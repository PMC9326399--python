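# omicsfuse

Multimodal similarity integration for tumor subtyping: per-modality
density-aware kernels, kernel addition, tensor-product-graph diffusion,
spectral clustering with dip-statistic model selection, and a
diffusion-potential (PHATE-style) 2-D embedding, with downstream marker
scores, pairwise differential tests and Kaplan–Meier / log-rank survival
comparisons.

The package is aimed at computational-biology practitioners who have
sample-matched bulk omics matrices — RSEM-style gene expression, Illumina
450k methylation beta values, and microbiome log2-CPM abundances — plus a
clinical table, and who want to partition a tumor cohort into molecular
subtypes without committing to any single data modality. A synthetic
tri-modal cohort generator with planted subtypes, a latent differentiation
gradient, and cluster-linked survival makes every stage testable at desk
scale.

## Method

For each modality, samples × features data are reduced to an n × n
affinity with a self-tuning, density-aware kernel

```
W_ij = exp( − d_ij² / ( σ_i σ_j (CNN_ij + 1) ) )
```

where `d_ij` is Euclidean distance, `σ_i` is the distance from sample *i*
to its k-th nearest neighbor, and `CNN_ij` counts the common members of
the two samples' k-NN sets (amplifying similarity inside locally dense
neighborhoods). The per-modality affinities are combined by elementwise
addition and denoised by diffusion on the tensor-product graph: after kNN
sparsification and row normalization by the dense row sums (giving a
strictly substochastic S), the iteration

```
Q₁ = S,   Q_{t+1} = S Q_t Sᵀ + I
```

converges to `Q* = Σ_m S^m (S^m)ᵀ` — exactly the diffusion on the n² pair
graph with adjacency S ⊗ S, computed without ever materializing it.

The number of clusters K comes from the *multimodality gap*: eigenvectors
of `D^{-1/2} Q D^{-1/2}` that encode community structure have strongly
multimodal score distributions (Hartigan dip statistic on the indicator
scale), while the trailing noise eigenvectors sit an order of magnitude
lower; K is placed at the largest (relative) drop in the per-eigenvector
dip sequence. Cluster labels come from k-means on the row-normalized
leading eigenvectors. The 2-D view row-normalizes Q into a diffusion
operator P, powers it (t = 200 in the integrated pipeline), maps rows to
log-potentials `U_i = −log(P^t_i· + ε)`, and embeds the potential
distances by metric MDS (classical solution + SMACOF).

The dip statistic itself is implemented from first principles as the
minimal sup-norm distance between the empirical CDF and the class of
unimodal CDFs, via the iterative convex-minorant / concave-majorant
modal-interval algorithm, and is verified in the test suite against an
independent linear-programming oracle.

## Worked example

Simulate a 360-sample tri-modal cohort (nine planted subtypes: one
microbiome+expression-marked viral group, one group separable only
through global hypomethylation, an EMT-high group, two generic expression
subtypes, and a four-slice basal differentiation gradient), then run the
full pipeline:

```
$ omicsfuse simulate --out cohort/ --seed 0
wrote cohort of 360 samples to cohort/

$ omicsfuse run --rna cohort/expression.tsv --meth cohort/methylation.tsv \
    --micro cohort/microbiome.tsv --clinical cohort/clinical.tsv \
    --out results/ --seed 0
K=9 samples=360 out=results/
```

The run selects **K = 9** by the multimodality gap and writes seven
artifacts (`similarity.tsv`, `embedding.tsv`, `clusters.tsv`,
`scores.tsv`, `de.tsv`, `survival.tsv`, `run_log.txt`), each stamped with
the configuration hash and seed:

```
$ head -4 results/clusters.tsv
# config_hash=0ec8e1a5bbb86bdc	seed=0
sample_id	cluster_label	K	method_k
S0000	5	9	multimodality_gap
S0001	5	9	multimodality_gap

$ grep logrank results/survival.tsv
# logrank_chi2=94.3617	df=8	p=6.034731606e-17
```

The nine clusters have sizes 41, 40 ×7, 39 and an adjusted Rand index of
0.994 against the planted subtypes (`cohort/truth.tsv`); the across-cluster
log-rank test (χ² = 94.4, 8 df, p ≈ 6×10⁻¹⁷) reflects the planted
subtype-linked hazards, including a threefold hazard ratio across the
gradient arm. `scores.tsv` carries the per-sample basal composite score
(sum of z-scored basal markers minus the mesenchymal and epithelial
sums) and an EMT score; `embedding.tsv` holds the PHATE1/PHATE2
coordinates. K selection is data-driven and stochastic at these effect
sizes: across seeds it lands on 9 in about three of five cohorts and on
a neighboring value otherwise — see `docs/methods.md` for its behavior
under eigenvector degeneracy.

Everything is also available as a library:

```python
from omicsfuse import (SimConfig, simulate_cohort, zscore_features,
                       integrate_modalities, cluster_similarity)

expr, meth, micro, clin, truth = simulate_cohort(SimConfig(seed=0))
w = integrate_modalities([zscore_features(expr), meth, micro])
clusters = cluster_similarity(w, k_min=2, k_max=12, seed=0)
```

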