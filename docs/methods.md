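# Methods

`regenmap` reimplements, as a tested library, a single-cell multi-omic
analysis of hepatocyte state diversification during liver regeneration after
partial hepatectomy (PHx): transcriptomic state discovery, regulon inference,
chromatin accessibility analysis, topic-model-based linking of regulons to
chromatin, and RNA velocity / pseudotime.  Because the original tissue data
are not shipped with the package, every stage is validated on synthetic data
whose planted structure makes recovery measurable; this note records the
models, the defaults, and what the synthetic benchmarks do and do not show.

## Synthetic data model (`regenmap.synthdata`)

The generators are pure functions of their parameters and a seed.

**RNA counts.**  Cells belong to one of `n_clusters` states; counts are
negative binomial with dispersion 0.3 (Var = m + 0.3 m²), a realistic scRNA
overdispersion that avoids extreme zero inflation.  Three kinds of structure
are planted on top of log-normal baseline means:

- *Regulons*: each transcription factor (TF) has a per-cell activity
  `a = exp(μ_cluster + ε)`, with `μ` high (log 2) in the TF's home state and
  low (log 0.4) elsewhere, and `ε ~ N(0, 0.8)`.  TF expression and
  target-gene means are proportional to `a`, so TF→target edges are
  recoverable from coexpression alone, within and across states.  TF
  baseline means are drawn well above the detection floor — a usable TF
  panel is expression-filtered in practice, and a TF whose own transcript is
  barely sampled cannot anchor coexpression inference.  The activity spread
  0.8 gives the tree-ensemble inference a realistic per-cell signal; smaller
  spreads leave edge recovery dominated by cluster-mean confounding.
- *Markers*: 15 genes per state at 6-fold elevation, which is what makes the
  states separable by graph clustering.
- *Zonation*: a per-cell coordinate z ∈ [0,1] (0 = central/perivenous,
  1 = portal/periportal); perivenous genes have means linear and decreasing
  in z, periportal genes increasing — so the dichotomized zonation score is
  monotone in z and testable by rank correlation.

Spliced counts are the count matrix; unspliced counts are `γ_g · s` times
log-normal noise (`splicing_noise`, default 0.1), with `γ_g` log-normal
around 0.5.  At zero noise the steady-state fit recovers γ to machine
precision by construction.  A configurable share of cells (default 10%)
receives a high mitochondrial fraction, planted above the QC threshold.

**Accessibility.**  Cells are true latent-Dirichlet-allocation draws: each
region has one dominant topic (block-structured region-topic multinomials,
90% of a topic's mass uniform on its block), each cell's topic weights are a
Dirichlet draw concentrated on its state's topic, and a Poisson number of
region tokens (~8% of regions per nucleus) is drawn from the mixture.  Peaks
covering the gene bodies of planted regulons are assigned to the topic of
the TF's home state, planting a state↔regulon↔peak-block correspondence;
the remaining peaks are intergenic (clear of gene bodies ±2 kb) with random
topics, so signature construction is not contaminated by foreign-topic peaks
that merely sit near regulon genes.  One state can be split into
sub-clusters that share its topic profile but carry small private accessible
region sets — the multi-cluster "fetal-like" geometry used by the end-to-end
benchmark.  Fragment records mix a triangular insertion density (±1 kb of
TSSs) with uniform background for good nuclei (50% TSS fraction) and uniform
placement for bad nuclei; fragment lengths are a nucleosomal mixture with
modes near 80 and 230 bp.

**Bulk time course.**  Regions follow one of up to eight log2 fold-change
shapes over 0/48/72/96 h (early burst, sustained induction, early loss,
sustained loss, late gain, late loss, spike-then-undershoot, V-shaped)
against log-normal baselines, times multiplicative log-normal replicate
noise; the rest are flat nulls.  On the log scale the noise is exactly
normal, so the moderated-t calibration check is a clean test of the
statistic rather than of a distributional approximation.

**References.**  An 89-gene zonation panel with smooth monotone or unimodal
profiles over layers L1..L9 (L1 central, L9 portal); disjoint
hepatocyte/Kupffer/endothelial marker sets with matching expression
profiles; one probability-matrix motif per TF whose consensus is embedded at
a recorded offset in every true target's promoter.  These are synthetic
stand-ins for the published references (zonation layer profiles, cell-type
markers, motif databases), which are not redistributable here.

**What the benchmarks do not show.**  The generators omit doublets, ambient
RNA, batch effects, Tn5 sequence bias, GC confounding, peak-calling
uncertainty and read-level artifacts.  Passing recovery tests therefore
demonstrates the correctness of each algorithm under its own model
assumptions, not robustness to every failure mode of real tissue data.

## Quality control (`regenmap.io_qc`)

RNA cells are filtered on mitochondrial fraction (default ≤ 0.2) and
detected features (default ≥ 200); features expressed in fewer than 3 cells
are dropped.  ATAC nuclei are filtered on TSS enrichment (default ≥ 4) and
fragment count (default ≥ 1000).  The criteria follow the study design; the
numeric cutoffs are package defaults chosen as field-standard values.  TSS
enrichment counts both fragment endpoints as insertions and divides mean
per-bp depth within ±50 bp of TSSs by mean depth in the outer 100 bp of the
±2 kb flanks; a uniform insertion density scores ≈ 1.  No Tn5 +4/−5 shift is
applied by default since the synthetic fragments carry no offset; a flag
enables it.  All filters are idempotent and order-preserving.

## Transcriptomic states (`regenmap.rna_states`)

Normalization is `log(1 + c·10⁴/total)`.  Clustering is PCA (30 components)
→ Euclidean 15-NN graph → Leiden at resolution 1.0 (deterministic per seed),
built directly on scikit-learn + igraph + leidenalg.  Cluster profiles are
grouped by average-linkage agglomeration on 1 − Pearson.  Signature scores
are means of per-gene z-scores (across cells), chosen over control-bin
subtraction for testability; they are invariant to global library-size
rescaling.  The dichotomized zonation call compares perivenous and
periportal scores with a ±0.5 z-unit dead zone ("co-expressing" between).
Deconvolution is non-negative least squares on the marker-gene union with
renormalized fractions (the upstream method is unspecified in the source
study; NNLS is the standard non-negative choice with closed-form
testability).  Preranked GSEA uses the weighted running-sum statistic with
gene-label permutations; NES divides ES by the mean |ES| of sign-matched
permutations and the p-value is the two-sided empirical tail
`(1 + #{|ES_perm| ≥ |ES|})/(1 + n_perm)`.  Zonal-layer correlation z-scores
each cluster profile and each layer profile across the 89 shared genes and
reports the per-pair Pearson correlation with a best-layer assignment —
z across genes, which makes a profile copied from a layer correlate at
exactly 1.

## Regulons (`regenmap.grn`)

Coexpression links follow the GENIE3 recipe: per target gene, a 500-tree
random forest (sqrt feature subsampling) predicts the unit-variance-scaled
target from TF expression; link importance is the forest's unnormalized
variance-reduction importance, so importances are comparable across targets
and a TF duplicated as two identical columns splits its importance between
them.  Promoters are TSS −500/+100 windows; motif scanning scores summed
log2 odds on both strands with N contributing 0, and a hit requires ≥ 80% of
the maximum attainable score.  Pruning keeps, per TF, the top-50 links whose
target promoters contain a motif hit.  Regulon activity is the recovery AUC
(AUCell statistic) over the top 5% of each cell's expression ranking —
rank-based, hence invariant to monotone transforms.  Per-cluster ranking
uses mean AUC, ties broken by TF name.

## Chromatin (`regenmap.chromatin`)

TF-IDF/LSI: binarize (count ≥ 1), term frequency per cell, idf
`log(1 + n_cells/n_cells_with_peak)`, `log1p(·×10⁴)`, truncated SVD;
component 1 is dropped when |r| with cell depth exceeds 0.9.  Single-pass
(no iterative refinement).  Single-cell differential accessibility uses the
two-sided Wilcoxon rank-sum on depth-normalized counts (pseudocount 1 per
10⁴) with BH adjustment; the statistic is antisymmetric under group swap.
Gene activity sums peak counts with weight 1 over the gene body ±2 kb and
exp(−d/5000) up to 100 kb.  Motif deviations follow the chromVAR scheme:
expected counts from global peak fractions, raw deviation
(obs − exp)/exp, z-scored against 50 background sets matched per member peak
on mean-accessibility bins (GC is unavailable for synthetic peaks; the
matching covariate is recorded in metadata).

The bulk time course compares each time point to 0 h with a moderated t on
log2 median-of-ratios-normalized counts.  The variance prior (d0, s0²) is
fitted by moments: s0² from the mean of the per-region pooled variances and
d0 by numerically solving the second-moment equation of the scaled
inverse-chi-square hierarchy, with d0 → ∞ when the observed spread of s² is
at the pure-sampling floor (no heterogeneity) and d0 = 0 reducing to the
ordinary t.  Median-of-ratios size factors (rather than totals) keep the
planted differential regions from shifting the null fold-changes.  Regions
significant (|log2FC| > 0.5, adjusted p < 0.05) at any time point are
clustered by hand-written fuzzy c-means (fuzzifier 2, 100 restarts, best
objective kept) on z-standardized mean time profiles; no fuzzy-clustering
package is available in the environment.

## Topic linking (`regenmap.topics`)

LDA is collapsed Gibbs sampling on the binarized matrix (cells = documents,
accessible-region occurrences = tokens), numba-accelerated, with
cisTopic-style priors α = 50/T, β = 0.1, 500 sweeps with 250 burn-in by
default, and φ/θ estimated from post-burn-in averaged counts with Dirichlet
smoothing.  Model selection scores each candidate T by the post-burn-in mean
of the full collapsed joint log P(w, z | α, β) (Dirichlet-multinomial form):
the plain token likelihood from point estimates grows monotonically with T
and cannot select a topic number, while the collapsed joint penalizes
superfluous topics and recovers the planted T on block data.  Reliable
selection also needs enough tokens per cell relative to α — with the
standard α = 50/T prior, nuclei opening only a few dozen regions are
prior-dominated; the benchmarks use ~80 open regions per nucleus.

Region-per-cell probabilities are p(r|c) = Σ_t θ_ct φ_tr.  Peak signatures
collect, per scRNA cluster, the peaks overlapping the gene bodies ±2 kb of
the top-5 regulons' TFs and targets, merged as a peak-id union.  Signature
enrichment ranks regions per cell by p(r|c) and applies the same recovery
AUC as regulon activity (the cited linking method scores signatures by
recovery of ranked region probabilities).  The correspondence matrix
correlates each ATAC cluster's mean signature-score profile (column
z-scored) against each signature's indicator direction, reporting the
argmax signature and an "exclusive" flag when the top correlation beats the
runner-up by 0.2.

The end-to-end benchmark plants 5 regulons per state so that "the top 5
regulons per cluster" are that cluster's own regulons — mirroring the real
analysis, where the top regulons of each cluster are distinct.  With few
planted TFs shared among all clusters' top-5 lists, signatures lose
discriminative power by construction, not through any pipeline defect.

## Dynamics (`regenmap.dynamics`)

The steady-state velocity model replaces the likelihood-based dynamic model
of the source analysis: the dynamic model's EM over latent times is out of
proportion to its role here, while the steady-state model is testable by
closed-form recovery.  γ is fit per gene by zero-intercept least squares
(Σus/Σs²) on cells in the extreme 5% quantiles of spliced expression; genes
with < 10 selected cells or zero Σs² are flagged unfitted.  Velocity is
v = u − γ∘s.  The transition kernel softmaxes cosine similarities between a
cell's velocity and its kNN displacement vectors (scale 0.1 by default).
Pseudotime is the min-max-scaled shortest-path distance from a user-chosen
root over the kNN graph — the root is specified, not inferred, matching how
the biological start state was chosen by inspection in the source analysis.

## Problem sizes and determinism

The acceptance benchmarks run, per seed: parameter recovery at 500–1000
cells and 200–300 genes; error control with 50 replicates of 200-region
nulls; time courses of 400–600 regions × 3 replicates; and an end-to-end
linking run with 2000 RNA cells, 1500 ATAC nuclei, 9 states (one split into
three ATAC sub-clusters) and 5000 regions, with 150 Gibbs sweeps and
50-tree forests.  These sizes keep a full run on one CPU core in the
minutes range while leaving every recovery criterion comfortably away from
its threshold.  All randomness flows through explicit integer seeds; every
generator and fit is bitwise reproducible for a fixed seed.

## Known limitations

- Peak calling, read alignment and barcode processing are out of scope;
  peaks and fragments are inputs (pseudo-bulk profiles can be exported as
  bedGraph for external callers).
- The steady-state velocity model cannot capture transient induction
  kinetics that the dynamic model resolves.
- chromVAR background matching uses accessibility bins only; with real
  sequence, GC-binned matching should be preferred.
- The LDA is plain collapsed-Gibbs LDA; no hierarchical Dirichlet process,
  no variational inference.
- UMAP-style 2-D embeddings are treated as pluggable visualization, not
  implemented here.
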