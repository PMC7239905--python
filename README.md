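# panomix

Multi-omic integration by sparse singular value decomposition, for finding
groups of tumors (or any samples) that share molecular alterations *beyond*
their tissue of origin.

Pan-cancer collections of gene expression (GE), DNA methylation (METH) and
copy-number (CNV) profiles cluster first and foremost by cell type: tissue
effects dominate every naive embedding. `panomix` implements a four-step
framework that removes those effects and lets the residual cancer signal
surface:

1. **Integration.** Each omic block `X_l` (samples × features) is centered,
   standardized and divided by `√p_l`, then column-concatenated into the
   extended matrix `X = [X₁, …, X_L]`, so no block dominates by width.
   Tissue (or any covariate) effects are removed by projecting onto the
   orthogonal complement of the membership design:
   `X ← (I − Q(Q'Q)⁻¹Q') X`.
2. **Sparse factorization.** `X ≈ Z W` is fitted one rank-1 factor at a
   time by minimizing `‖X − ZW‖²_F + λ(α‖W‖₁ + (1−α)‖W‖₂²)` with
   alternating thresholded updates and deflation. The elastic-net
   thresholding operator zeroes features with negligible contribution; λ is
   chosen per axis as the point where the proportion of variance explained
   (PVX) drops sharpest along a dense λ grid (minimum discrete second
   derivative), with α = 0.5 for equal LASSO/ridge weight.
3. **Cluster discovery.** The informative score axes are embedded in 2-D
   with t-SNE (lowest final KL cost across candidate perplexities) and
   clustered with DBSCAN, its radius ε tuned by maximizing the silhouette.
4. **Signatures and phenotypes.** Per-gene scores — the gene's selected
   columns of `X` weighted by their loadings — are tested across clusters
   (one-way ANOVA with Bonferroni family control, Tukey HSD pairwise). A
   gene enters a cluster's *signature* only when it separates that cluster
   from **every** other cluster with a consistent direction. Clusters are
   further characterized by Kruskal–Wallis/Dunn tests on covariates,
   log-rank tests on survival, and hypergeometric gene-set
   over-representation.

A synthetic-data module generates multi-block data with known tissue
effects, sparse cross-block factors, planted sample clusters and
cluster-exclusive gene signatures, so every step can be validated against
ground truth.

## Worked example

Generate the bundled desk-scale benchmark (120 samples, three omic blocks
of 200/300/150 features, 3 tissues whose mean shifts are three times the
factor scale, 4 planted clusters crossing the tissues, 10 signature genes
per cluster) and run the whole pipeline:

```sh
panomix fixture demo --preset tiny
panomix run demo/config.yaml
```

which prints (numbers from the run manifest):

```json
{
  "n_axes": 6,
  "clustering": {
    "eps": 0.4170457682228259,
    "min_pts": 10,
    "silhouette": 0.9510411753686221,
    "n_clusters": 4,
    "n_noise": 7
  },
  "ari_vs_planted_clusters": 1.0,
  "n_signature_genes": 48
}
```

With tissue effects projected out, the four planted clusters — each a mix
of all three tissues — are recovered exactly (adjusted Rand index 1.0
over the assigned samples; 7 samples are left as DBSCAN noise). Re-running
with `--no-project` recovers the three *tissues* instead: the dominant
signal before correction is where the samples came from, not what their
tumors share. The 48 signature genes include the 40 planted ones.

The same pipeline is available as a library:

```python
from panomix import (SynthConfig, generate_multiomic, standardize_and_weight,
                     concatenate_blocks, build_indicator, apply_projection,
                     fit_ssvd, tsne_embed, dbscan_tune)

blocks, truth = generate_multiomic(SynthConfig(seed=42))
X = concatenate_blocks([standardize_and_weight(b) for b in blocks])
X = apply_projection(X, build_indicator(truth.tissue_labels))
result = fit_ssvd(X, n_axes=6)            # per-axis lambda tuned from PVX
emb = tsne_embed(result.Z * result.d, perplexities=(15, 30), seed=42)
clusters = dbscan_tune(emb.coords)
```

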