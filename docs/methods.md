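# Methods

## Model

The data are `L` omic blocks `X_l` (samples × features; gene expression,
methylation M-values, copy-number intensities) over the same `n` samples.
After per-block preprocessing (below), the blocks are column-concatenated
into the extended matrix `X = [X₁, …, X_L]` and factorized as

    minimize ‖X − Z W‖²_F + λ (α‖W‖₁ + (1−α)‖W‖₂²)

one rank-1 layer at a time: `z ← Xw/‖Xw‖`, `w ← S_en(X'z; λ, α)`, iterated
to convergence, where `S_en(b) = sign(b)·max(|b| − λα, 0) / (1 + λ(1−α))`
is the elastic-net proximal (thresholding) operator, applied elementwise.
`w` is renormalized to unit length with the scale absorbed into
`d = z'Xw`, so `d` is comparable to a singular value; subsequent layers fit
the deflated residual `X − d z w'`. At `λ = 0` the procedure reduces
exactly to the SVD, which the test suite uses as an oracle. Initialization
is the leading singular vector of the current residual, making the fit
deterministic. An alternative thresholding denominator `λ(1−α)` is
available (`verbatim=True`) for compatibility with the non-standard form
occasionally seen in print; it is degenerate at `λ(1−α) = 0` and not the
default.

Tissue or covariate effects are removed before factorization by
residualizing every column on the membership design `Q`:
`X ← (I − Q(Q'Q)⁻¹Q')X`. One-hot designs use group demeaning (O(np));
general designs use QR residualization. The dense n×n projector is never
formed.

## Penalty and rank selection

Per axis, λ is selected from a 50-point log-spaced grid on
`[λ_max·10⁻⁴, λ_max]` with `λ_max = max|X'z₀|/α` (the smallest penalty
zeroing all loadings at the first step). The proportion of variance
explained, `PVX(λ) = d(λ)²/‖X‖²_F`, decreases monotonically in λ; the
chosen λ minimizes the discrete second derivative of PVX on the log-λ
axis (central differences, endpoints excluded, ties toward the sparser
end) — the point where PVX enters its sharpest drop, i.e. where the
features that carry the structure start being removed. On the planted
benchmark (three factors with 5% support in a 150×600 three-block layout,
noise at half the factor scale) this rule recovers per-axis supports
within a few features of the planted 30 and a support F1 ≈ 0.97.

The number of axes, when not given, is chosen by the scree elbow of the
singular values (maximum perpendicular distance to the line joining the
first and last values); an explicit integer override is supported.

## Preprocessing

* QC removes features that are all zero, have coefficient of variation
  below 1% (sd/|mean|·100 on observed entries; mean-zero features are left
  to the other rules), or exceed 20% missingness; samples above 20%
  missingness are dropped. Precedence: all-zero, then missingness, then CV.
* Missing entries are imputed by k-nearest neighbours (k = 3): the mean of
  the k nearest samples under the nan-aware Euclidean distance (mutually
  observed features, scaled by the fraction observed) computed on
  per-column standardized values (delegated to scikit-learn's KNNImputer,
  wrapped with the standardize/unstandardize step).
* Methylation β values are mapped to M-values as `log2(β/(1−β))` with β
  clipped to `[10⁻⁶, 1−10⁻⁶]`; the plain ratio `β/(1−β)` is available as a
  verbatim variant. Probe-level methylation is collapsed to CpG islands by
  maximum connectivity: the representative probe maximizes the sum of
  absolute Pearson correlations with the island's other probes.
* Counts are log-transformed as `ln(x + 1)`.
* Standardization uses variance denominator `n` (not n−1), so each
  standardized column has sum of squares `n` and each `√p_l`-weighted
  block has total energy exactly `n`; this makes the PVX bookkeeping and
  the block-balance property exact rather than approximate.

## Embedding and clustering

t-SNE runs once per admissible perplexity (perplexity < n/3; the paper-
scale defaults 50/100 suit thousands of samples, the bundled fixtures use
15/30 to match ~30-sample clusters) with a fixed seed and a generous
iteration ceiling (the optimizer stops early on plateau); the map with the
lowest final KL cost is kept. Scores are embedded on their natural scale
`Z·diag(d)` so axes contribute by variance explained.

DBSCAN's ε is tuned by maximizing the mean silhouette over non-noise
points in the map, over a grid of radii spanning the 1st–90th percentile
of min_pts-nearest-neighbour distances (stopping short of the outlier tail
whose radii bridge distinct clusters). Silhouette over assigned points
alone is maximized by degenerate partitions — a few tiny cores with most
samples labelled noise — so candidates leaving more than 10% of samples
unassigned are only used as a fallback. min_pts defaults to 10. Noise
samples (label −1) are excluded from all downstream statistics and from
recovery metrics, mirroring samples that map to no cluster.

Silhouette is computed in the embedding space, not the score space: the
clusters are defined on the map, so the map is where their compactness is
judged.

## Gene scores and signatures

For gene g with selected features F_g (nonzero loading on at least one
selected axis), the per-sample score is `X[:, F_g] · w̃_g` with
`w̃_g[j] = Σ_k d_k W[k, j]` summed over the selected axes (an unweighted
variant is available). Genes with no selected feature are omitted, not
zero-filled. Functional-class scores use the same construction over all
selected features of a set's member genes.

Cluster differences are tested per gene/class by one-way ANOVA at the
Bonferroni threshold `0.05 / (#genes + #classes)`. Significant genes
proceed to Tukey HSD over all cluster pairs. By default the Tukey stage
also runs at the Bonferroni-corrected level rather than 0.05 within gene:
the tested genes were selected by the factorization from the same data,
and the selection favours features correlated with the cluster-structured
score axes, which inflates pairwise type-I error at the nominal level.
With the corrected level the planted-signature benchmark (3 clusters × 10
genes, 1.5 sd coupled GE/CNV shifts, 40 samples per cluster) is recovered
with recall ≈ 0.97 at precision 1.0, and structureless data yield no
signature genes in ≥ 95% of seeds. `tukey_across_genes=False` restores
the within-gene 0.05 convention.

A gene joins cluster c's signature iff every (c, c′) comparison rejects
with a consistent sign, and it qualifies for exactly one cluster; with
three or more clusters this automatically excludes monotone genes (which
qualify for both extremes). Signatures are disjoint by construction.

Phenotype association uses Kruskal–Wallis per numeric covariate
(chi-square for categoricals), with Dunn's rank-based pairwise test
(tie-corrected z statistics, Holm adjustment) only after a significant
omnibus. Survival uses the K-group log-rank test with Kaplan–Meier
medians per cluster (not reached ⇒ NaN). Gene-set over-representation is
a hypergeometric tail test with Benjamini–Hochberg adjustment — a local
stand-in for web-service enrichment tools, by design.

## Synthetic data

`generate_multiomic` builds `X_l = tissue + Z_true W_true + signatures +
noise`:

* **Tissue effects**: i.i.d. per-feature mean shifts per tissue,
  `N(0, tissue_sd²)`; default tissue_sd = 3 × factor_sd, making tissue the
  dominant structure, as in real pan-cancer data.
* **Factors**: per-cluster centroids picked by greedy maximin from
  standard-normal candidates (well-separated by construction), within-
  cluster spread 0.35, scores standardized per factor; loadings sparse
  (default 5% support) with magnitudes `factor_sd·U(0.5, 1.5)` and random
  signs, so every supported feature carries signal.
* **Signatures**: disjoint gene sets per cluster; each gene's GE and CNV
  features are shifted by `signature_effect` (default 1.5) noise-sds with
  a shared sign within the gene's cluster — the coupled
  expression/copy-number deregulation the factorization is meant to
  expose. Factor supports are drawn disjoint from signature-gene features;
  otherwise the planted "exclusive" truth would be contradicted by factor
  structure on those genes.
* **Gene map**: one gene ↔ one GE feature, one CNV feature (where block
  widths allow) and one or two METH features; chromosomes cyclic.
* **Noise**: i.i.d. Gaussian per block (scalar or per-block scale,
  default 0.5 × factor_sd); optional uniform missingness.

What this emulates: block-scale imbalance, tissue dominance, sparse
cross-omic factors, cluster-exclusive coupled deregulation, missingness.
What it does not: count overdispersion, copy-number segmentation, CpG
spatial correlation, batch effects (accepted as an upstream correction),
or realistic feature dependence within a block. Passing recovery tests
therefore demonstrates the machinery's correctness under the assumed
generative structure, not performance on real cohorts.

## Problem sizes and defaults

The bundled benchmarks run on a laptop-scale footprint chosen to exercise
every stage meaningfully: the `tiny` fixture has n = 120 samples, blocks
of 200/300/150 features, 3 tissues, 4 clusters and 10 signature genes per
cluster; the support-recovery benchmark is 150 × 600 with three 5%-support
factors; null calibrations use 100–200 replicates. Key defaults: α = 0.5,
50-point λ grid, tol 10⁻¹⁰, max 500 iterations per rank-1 fit, t-SNE
perplexities 50/100 (15/30 in the fixtures), DBSCAN min_pts 10, family
level 0.05.

## Known limitations

* The rank-1 subproblem is non-convex; the deterministic SVD warm start
  makes fits reproducible but a global optimum is not guaranteed, and the
  PVX path can show sub-tolerance wiggles on deflated residuals (warned,
  not fatal).
* The λ rule assumes a visible PVX shoulder; on structure-free residuals
  the chosen λ is essentially arbitrary (and harmless, as the resulting
  axes carry no support).
* Exclusive signatures are conservative by design: genes deregulated in
  two or more clusters are not reported as signatures of either.
* Survival utilities assume right-censoring with cluster-independent
  censoring.
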