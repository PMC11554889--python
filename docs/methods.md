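# Methods

Statistical models, parameter defaults, and numerical conventions of the
`keygenes` pipeline. Every default named here lives in
`keygenes.config.PipelineConfig`; nothing downstream hard-codes a cutoff.

## 1. Data model and pooling

An `ExpressionDataset` is a genes × samples matrix of log-scale intensities
with a binary phenotype label (1 = case, 0 = control) and a dataset tag per
sample. Duplicate gene ids in an input table are collapsed by averaging
their rows (the usual many-probes-per-gene situation on arrays).

`pool_datasets` concatenates two or more datasets over their shared genes.
Because different collections sit on different intensity scales, each
dataset is z-scaled **per gene within the dataset** before concatenation
(`pool_zscale=True` by default). This removes dataset-level location/scale
batch effects but deliberately destroys absolute means; fold changes must
therefore be computed on unpooled (or unscaled) data, which is why the
screen accepts a separate `logfc_data` argument.

## 2. Inverse-gamma variance filter

**Model.** Across genes, the per-gene population variance σ² of log
expression is treated as a draw from an inverse-gamma(α, β) distribution —
the standard conjugate choice for variances, with a heavy right tail that
matches the empirical spread of gene variances. For gene *i* with unbiased
sample variance *s²ᵢ* (ddof = 1), the filter reports the upper-tail
probability

    pᵢ = Pr[σ² ≥ s²ᵢ] = survival function of InvGamma(α̂, β̂) at s²ᵢ.

At *s²ᵢ = 0* the survival function equals 1 exactly — a constant gene is
maximally unremarkable — and *pᵢ* decreases monotonically in *s²ᵢ*. Genes
with *pᵢ* strictly below `variance_p_cutoff` (default 0.05) are retained as
candidates: under the case/control mixture a differentially expressed gene
has pooled variance inflated by the squared group-mean difference, so large
variance is evidence of differential expression without using the labels.

**Fitting.** Default is method-of-moments (`variance_fit_method="mom"`):
with sample mean *m* and variance *v* of the positive *s²* values,
α̂ = m²/v + 2 and β̂ = m(α̂ − 1); these invert the inverse-gamma mean and
variance and are closed-form, fast, and robust. `"mle"` refines the MoM
estimate numerically via `scipy.stats.invgamma.fit`. Zero variances are
excluded from the fit (they are not in the distribution's support) and
assigned p = 1 directly; at least 10 positive variances are required for a
fit, and an all-constant matrix skips the fit and returns p = 1 for every
gene.

## 3. Weighted co-expression analysis

**Adjacency.** Unsigned weighted adjacency *aᵢⱼ = |cor(xᵢ, xⱼ)|^β* over the
filtered genes. Genes with zero variance are rejected with an error naming
the offending ids (their correlation is undefined).

**Soft-threshold choice.** β is the smallest power in `soft_power_grid`
(default 1–20) whose connectivity distribution fits a scale-free law with
signed R² ≥ `scale_free_r2_cutoff` (default 0.8). The fit index bins the
connectivities *kᵢ = Σⱼ≠ᵢ aᵢⱼ* into equal-width bins on the **linear** *k*
scale, regresses log₁₀ p(k) on log₁₀ mean-k across occupied bins, and signs
R² by the negated slope sign (so an increasing log-log relationship scores
negatively). If no candidate reaches the cutoff, the power with the highest
index is used and a warning is raised.

*Caveat.* Binned scale-free fit indices are unreliable at very high powers:
raising any adjacency to a large β collapses most connectivities toward
zero, which can manufacture an apparently falling tail even for independent
noise. The default grid stops at 20 and the scan frame
(`SoftThresholdScan.to_frame()`) reports mean connectivity per power so
users can see when the network has degenerated (mean k ≪ 1 is a red flag).
On genuinely modular data with heterogeneous module sizes the cutoff is
typically reached at a moderate power.

**Topological overlap and clustering.** TOM_ij = (Lᵢⱼ + aᵢⱼ) /
(min(kᵢ, kⱼ) + 1 − aᵢⱼ) with Lᵢⱼ = Σᵤ aᵢᵤaᵤⱼ, diagonal 1. Genes are
clustered by average-linkage hierarchical clustering on 1 − TOM, cut
statically at `cut_height=0.99`; clusters below `min_module_size=30` go to
the unassigned label 0. Modules whose eigengenes have correlation
dissimilarity (1 − cor) below `merge_height=0.1` are merged iteratively.

**Eigengenes and module–trait.** A module eigengene is the first principal
component of the per-gene standardized module submatrix, scaled to unit
sample variance and signed so that it correlates positively with the mean
expression profile (removing the PCA sign ambiguity). Module–trait
association is the Pearson correlation between the eigengene and the 0/1
phenotype, with the exact two-sided Student-t p-value on n − 2 degrees of
freedom. A module is significant when |r| > `module_trait_r_cutoff` (0.6)
**and** p < `module_trait_p_cutoff` (0.005).

**Signature genes.** Within significant modules, a gene is a signature gene
when module membership MM = |cor(gene, eigengene)| ≥ `mm_cutoff` (0.8,
inclusive) and gene significance GS = |cor(gene, trait)| ≥ `gs_cutoff`
(0.7, inclusive).

## 4. Per-gene classifier screen

All pooled samples are split once into stratified 60% train / 40% test
(`train_fraction=0.60`); every gene is evaluated on the **same** split so
that per-gene metrics are comparable (`split_per_gene=False`; the
alternative re-splits per gene with per-gene sub-seeds).

Each gene's expression is the sole feature of two classifiers:

- a random forest (`rf_trees=50`, `rf_max_depth=3`). With a single feature,
  deep forests can only overfit the training sample order of a continuous
  variable — shallow stumps capture everything a monotone one-dimensional
  decision surface can express, generalize better, and are several times
  faster; 50 trees suffice because the trees differ only through
  bootstrapping.
- a linear SVM (`svm_c=1.0`) with Platt-style decision scores.

From the test-set scores the screen computes ROC AUC and **ACC**, defined as
the accuracy at the largest score threshold whose test false positive rate
is at most `fpr_level=0.10` (ties resolved toward the higher threshold).
A gene is called when AUC ≥ `auc_cutoff` (0.85) and ACC ≥ `acc_cutoff`
(0.85) hold for **both** models, and |log₂FC| > `logfc_cutoff` (1.0), where
log₂FC = log₂(mean case / mean control) on positive-scale values
(direction convention switchable via `logfc_direction`). The call is "up"
for logFC > 1, "down" for logFC < −1.

Degenerate genes (constant on the training split) score AUC 0.5 and are
never called.

## 5. Common DEGs, hub ranking, MCODE

The unsupervised signature genes and the supervised DEGs are intersected
(cDEGs) and projected onto an interaction network read from a TSV edge
list; scores on a 0–1000 scale are divided by 1000 and edges below
`edge_score_cutoff=0.4` are dropped, self-loops removed, duplicate edges
keep the maximum weight.

Six per-node measures are computed on the unweighted topology:

- **degree** — neighbor count.
- **closeness** — harmonic closeness Σᵤ≠ᵥ 1/d(v, u), which stays
  well-defined on disconnected graphs (unreachable nodes contribute 0).
- **MNC** — size of the largest connected component of the open
  neighborhood subgraph N(v).
- **DMNC** — |E(MNC component)| / |V(MNC component)|^ε with
  `dmnc_epsilon=1.7`; 0 when the component has fewer than 2 nodes.
- **EPC** — edge-percolated component: over `epc_trials=1000` Monte-Carlo
  rounds, each round draws one uniform threshold and keeps the edges whose
  uniform random weight exceeds it; a node's score is its mean retained
  component size. This is the only stochastic measure; it takes an explicit
  seed and is reproducible given it. With retention forced to 1 the score
  degenerates to the node's component size (used as a correctness check).
- **MCC** — maximal clique centrality Σ_{C ∋ v} (|C| − 1)! over maximal
  cliques; on a triangle-free graph this reduces exactly to degree. Clique
  enumeration is guarded by `clique_budget` (default 2 × 10⁶ cliques) and
  raises rather than hanging on pathological dense graphs.

Each measure ranks nodes descending; the aggregate score is the **mean
rank** over the six measures (`rank_aggregation="mean_rank"`), ties broken
by node id for determinism, and the top `hub_top_n=10` nodes are the key
genes. The alternative `"top_k_intersection"` reports nodes appearing in
every measure's top-k list.

**MCODE.** Node scores are core-clustering coefficient × highest k-core
number; complexes grow greedily from unvisited seed maxima, admitting
neighbors whose score is within `mcode_node_score_cutoff=0.2` of the seed
(bounded by `mcode_max_depth`), then are trimmed to the
`mcode_k_core`-core. A complex's score is density × size.

**Validation.** The final panel is evaluated as a joint feature set of a
multivariate random forest on a fresh stratified split of the pooled data,
reporting test AUC and the ROC curve.

## 6. Synthetic data generators

**Expression.** A latent-factor model: module *m*'s genes are
*x = baseline + √ρ·e_m + √(1 − ρ)·ε* with eigengene series
*e_m ~ N(0, I)* and noise *ε ~ N(0, noise_sd²)*, so at `noise_sd=1` the
within-module Pearson correlation is exactly ρ in expectation. Background
genes are pure noise at full `noise_sd`. Differential expression is an
additive group-mean offset of `de_effect_size × noise_sd`: up genes shift
cases up, down genes shift controls up — same mean difference either way,
and all group means stay positive so ratio fold changes remain defined.
DE genes are planted inside modules first (`de_in_modules=True`) with
direction policy `alternate`/`up`/`down`/`by_module`. The returned
`PlantedTruth` records DE directions, module assignments, and the latent
eigengene series, so recall/precision/ARI are computable exactly.

This emulates the qualitative structure of multi-cohort case/control
array data — correlated gene modules, a minority of shifted genes, positive
log-scale baselines — not any particular platform's noise model
(no heteroscedasticity, no probe effects).

*Closed-form anchors used in tests:* a single standardized Gaussian feature
separated by δ between groups has theoretical ROC AUC Φ(δ/√2); the group
mean difference equals δ·noise_sd exactly in expectation; the zero-variance
p-value is exactly 1.

**Network.** `simulate_network` plants `n_hubs` hub nodes on an
Erdős–Rényi(`background_p`) background: hubs are wired into cliques of
`clique_size` and each hub additionally connects to a random
`hub_fanout_fraction=0.10` of the periphery, keeping hub degrees well above
the background distribution at defaults. `PlantedTruth.hub_ids` names the
planted hubs.

## 7. Determinism

Every stochastic step derives its generator from the global seed via
`stage_seed(seed, "stage/name")`, a `numpy.random.SeedSequence` keyed by the
stage name's bytes. Sub-seeds are plain ints below 2³¹ for libraries with
int-seed APIs. Reruns at the same seed are bit-identical, and changing one
stage's name or adding a stage does not perturb the others.

## 8. Limitations

- The variance filter assumes a common inverse-gamma law across genes; when
  a large fraction of genes is differentially expressed with big shifts,
  the fitted tail fattens and the filter loses power for moderate-variance
  DE genes.
- The scale-free fit index inherits the known weaknesses of binned log-log
  regression (see the caveat in §3); it is a heuristic for choosing β, not
  a test of scale-freeness.
- Per-gene classifiers on one shared split make metrics comparable across
  genes but correlated across genes; the screen controls per-gene criteria,
  not a family-wise error rate.
- MCC is exponential in the worst case; the clique budget turns pathological
  inputs into a clean error instead of a hang.
- EPC is Monte-Carlo: scores carry O(1/√trials) noise, so exactly
  symmetric nodes may not tie on the aggregate rank. Increase `epc_trials`
  if near-ties matter.
- No multiple-testing correction, batch-effect modeling beyond per-dataset
  z-scaling, or covariate adjustment is performed.
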