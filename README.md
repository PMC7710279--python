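# regenmap

Single-cell multi-omic analysis of hepatocyte state diversification during
liver regeneration.

After partial hepatectomy (PHx), mouse hepatocytes re-enter the cell cycle
and a subset transiently adopts a fetal-like, progenitor-marker-expressing
state with a distinct chromatin landscape.  `regenmap` implements the
computational pipeline for dissecting this process from scRNA-seq,
scATAC-seq and bulk ATAC-seq time-course data:

- **QC and IO** — MTX/BED/TSV readers and writers; mitochondrial and
  feature-count filters for cells, TSS-enrichment and fragment-count filters
  for nuclei (`regenmap.io_qc`).
- **Transcriptomic states** — normalization, Leiden clustering on a kNN
  graph, hierarchical grouping of cluster profiles, marker-signature
  scoring, a dichotomized perivenous/periportal zonation call, NNLS bulk
  deconvolution, preranked GSEA and correlation with the L1–L9
  portal-to-central zonation layers (`regenmap.rna_states`).
- **Regulons** — GENIE3-style random-forest coexpression links, promoter
  motif scanning and pruning, recovery-AUC (AUCell) regulon activity and
  per-cluster regulon ranking (`regenmap.grn`).
- **Chromatin** — TF-IDF/LSI embedding, pseudo-bulk aggregation, Wilcoxon
  differential accessibility at |log2FC| and BH-adjusted-p thresholds,
  distance-weighted gene activity scores, chromVAR-style motif deviation
  z-scores, and moderated-t time-course analysis with fuzzy c-means module
  clustering (`regenmap.chromatin`).
- **Regulon↔chromatin linking** — the pipeline's centerpiece: latent
  Dirichlet allocation (collapsed Gibbs) on binarized accessibility, model
  selection over topic numbers, per-cell region probabilities
  p(r|c) = Σ_t θ_ct φ_tr, peak signatures built from each RNA cluster's top
  regulons, recovery-AUC signature enrichment, and a Pearson correspondence
  matrix mapping ATAC clusters onto RNA states (`regenmap.topics`).
- **Dynamics** — steady-state RNA velocity (per-gene γ from extreme-quantile
  fits, v = u − γs), a cosine transition kernel, and shortest-path
  pseudotime from a chosen root (`regenmap.dynamics`).
- **Synthetic data** — generators for all of the above with planted ground
  truth (states, regulons, topics, kinetic modules, zonation gradients,
  splicing ratios, motif placements), so every stage is testable without
  downloads (`regenmap.synthdata`), plus recovery benchmarks
  (`regenmap.evaluation`).

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from regenmap import synthdata, io_qc, rna_states, dynamics
from regenmap.containers import SignatureSet

# simulate 800 hepatocytes in 4 states with regulons, zonation and kinetics
adata, truth = synthdata.gen_rna_counts(n_cells=800, n_genes=300,
                                        n_clusters=4, seed=11)

filtered = io_qc.filter_cells_rna(adata, max_mito_fraction=0.2, min_features=100)
print("QC:", filtered.uns["qc_report"])

norm = rna_states.normalize_counts(filtered)
clusters = rna_states.cluster_cells(norm, n_neighbors=15, resolution=1.0, seed=0)
keep = np.isin(adata.obs_names, filtered.obs_names)
print("clusters found:", clusters.n_clusters,
      "| ARI vs planted states:",
      round(adjusted_rand_score(truth.cluster_labels[keep], clusters.labels), 3))

fit = dynamics.fit_gamma(adata.layers["spliced"], adata.layers["unspliced"])
ok = fit["fitted"].to_numpy()
err = np.median(np.abs(fit["gamma"].to_numpy()[ok] / truth.gamma_true[ok] - 1))
print(f"splicing ratio gamma: fitted {int(ok.sum())} genes, "
      f"median relative error {err:.3f}")

pv = SignatureSet("perivenous", {g for g in adata.var_names if g.startswith("pv")})
pp = SignatureSet("periportal", {g for g in adata.var_names if g.startswith("pp")})
zones = rna_states.dichotomized_zonation(norm, pv, pp)
print("zonation classes:", zones["zonation_class"].value_counts().to_dict())
```

Output:

```
QC: {'removed_high_mito': 80, 'removed_low_features': 0, 'cells_retained': 720, 'features_removed': 0}
clusters found: 4 | ARI vs planted states: 0.996
splicing ratio gamma: fitted 300 genes, median relative error 0.014
zonation classes: {'co-expressing': 271, 'PP': 227, 'PV': 222}
```

The QC step removes exactly the planted 10% high-mitochondrial cells;
clustering recovers the four planted states almost perfectly; the
steady-state fit recovers each gene's splicing ratio γ to ~1% at 10%
multiplicative noise; and the dichotomized zonation score splits cells into
perivenous, periportal and co-expressing classes along the planted lobule
coordinate.

A thin CLI mirrors the main stages
(`regenmap simulate|qc-rna|qc-atac|cluster-rna|lsi|da|timecourse|topics|velocity|pseudotime`);
see `regenmap --help`.

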