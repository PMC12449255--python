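# Methods

This note documents the modelling choices behind `scpoem`, the parameters
that matter, what the synthetic data generator does and does not emulate,
and the numerical conventions used throughout.

## Data model and preprocessing

Input is one homogeneous cell population with paired counts: ATAC
`X ∈ N^{n×p}` (cells × peaks) and RNA `Y ∈ N^{n×q}` (cells × genes) over
matched barcodes. All genomic coordinates are 0-based half-open (BED
convention); every interval-overlap test in the package is half-open.

Cell QC removes cells outside configurable total-count bounds (defaults:
the 1st/99th percentiles of the per-cell totals, the usual reading of
"excessively low or high"; note percentile bounds are resolved per call, so
exact idempotence of the filter holds for explicit numeric bounds), cells
above 20% mitochondrial reads, and — regardless of bounds — cells with zero
counts in either modality, which no downstream step can use. Feature QC
keeps autosomal features (sex and mitochondrial chromosomes excluded, the
whitelist configurable), drops features overlapping a blacklist (empty by
default so synthetic data needs no genome files), and applies the detection
thresholds: peaks in ≥ 5 cells, genes in ≥ 1% of cells.

RNA normalisation is library-size scaling to 10⁴ per cell, `log1p`, HVG
selection, and per-gene z-scaling of the HVG submatrix. HVGs are ranked by
scanpy's binned normalized-dispersion statistic (`flavor="seurat"`), with an
explicit top-`n` cut so exactly `n_hvg` genes are kept (ties broken by
column order). ATAC TF-IDF uses TF = within-cell count fraction and
IDF = log(1 + n/(1 + df)); zeros are preserved exactly.

## Peak–peak co-accessibility

The workflow follows Cicero's outline: binarise `X`, embed cells, aggregate
k-nearest-neighbour metacells, and fit a graphical Lasso per genomic window.
Windows of 500 kb tile each chromosome with 50% overlap; peaks belong to a
window by midpoint; per-window absolute partial correlations
(−Θ_ij/√(Θ_ii Θ_jj) from the estimated precision Θ of the standardised
window submatrix) are averaged over the windows containing a pair.
Cross-chromosome entries are structurally zero. Non-converged or singular
fits retry once with a ridge-stabilised (+10⁻³ I) correlation matrix.

The aggregation size `knn_k` is the statistically load-bearing knob.
Overlapping-neighbourhood metacells autocorrelate the samples the graphical
Lasso sees, shrinking the effective sample size by roughly the neighbourhood
size; this only pays off when the binary profiles are extremely sparse.
The default is therefore `knn_k = 1` (no aggregation — appropriate at the
few-tens-of-percent detection rates of the bundled simulator, and in that
case the UMAP cell embedding is skipped as irrelevant), with `knn_k ≈ 50`
recommended for real scATAC matrices at ~1–5% detection. The cell embedding
for aggregation is UMAP (cosine metric, 10 components by default; a
randomised-SVD mode exists for speed). The graphical-Lasso penalty default
is 0.05 on correlation matrices, distance-independent; this is deliberately
simpler than Cicero's distance-scaled penalty.

A structural caveat: partial correlations *condition away* shared drivers.
In a block of peaks opened by one latent factor, each pairwise partial
correlation is attenuated by the rest of the block (for an equicorrelated
block of size m with marginal correlation ρ the partial correlation is
ρ/(1+(m−2)ρ)), so co-accessibility weights within large single-factor
blocks are genuinely small — a property of the estimator, not a bug.

## Gene–gene network

For each gene `j`, the remaining genes are globally column-centred, their
top `K' = min(5, q−1, n−1, numerical rank)` principal components are taken
(exact SVD up to 400 columns, seeded randomised SVD beyond), and
`β̂_j = V_j (UᵀU)^{-1} Uᵀ Y_j` back-projects the OLS fit on the scores.
Assembling |β̂| column-wise, symmetrising by elementwise maximum, and
keeping entries strictly above the 95th percentile of all off-diagonal
values (zeros and symmetric copies included; the "higher" quantile method
guarantees at most 5% survive) yields `W_gg`. Genes isolated by the
threshold become dead rows in the gene transition matrix; walks reaching
them truncate rather than fabricate transitions.

## Peak–gene networks

Candidate peaks for a gene are those overlapping the gene body ± 100 kb
(half-open; a TSS-anchored mode is available). Per gene: Lasso with the
penalty chosen by 5-fold cross-validation on standardised predictors
(|coefficients|), random forest (100 trees, depth 6, impurity importances),
and XGBoost (100 trees, depth 6, gain importances), each with a
deterministic per-gene seed. A failed regression yields a zero column and a
warning, never a pipeline abort.

## Transitions and walks

Every weight matrix is winsorised at the 10th/90th percentiles of its
*nonzero* values (linear-interpolation quantiles; zeros untouched) and
row-normalised. The peak→gene and gene→peak transitions average the three
row-normalised method matrices (transposed for gene→peak); a row is dead
only if dead under all three methods, and partially-dead rows are
renormalised to sum to one. Clip-then-normalise is scale-invariant.

Walks follow the fixed six-node scheme: from each peak root `P1`, a gene
chain `G1 ~ P_pg(P1)`, `G2 ~ P_gg(G1)`, `G3 ~ P_gg(G2)` and a peak chain
`P2 ~ P_pp(P1)`, `P3 ~ P_pp(P2)`; symmetrically from each gene root. Each
root emits five directed pairs weighted `e^{-0.1k}` by the number `k` of
intermediate nodes. Pairs are kept as a multiset (each occurrence is a
gradient term); chains stop at dead rows and only realised pairs are
emitted. Two-step returns (`P3 = P1`) are allowed — the walk has no
exclusion rule.

## Embedding training

One table `F` serves both the centre and context roles. Initialisation is
uniform(−0.5/d, 0.5/d). Negatives are drawn uniformly over all peaks and
genes (with replacement, excluding the pair's own endpoints) for every pair
regardless of type; a unigram^0.75 alternative was considered and rejected
because nodes here have no frequency skew comparable to word corpora.

Two defaults matter and both are logged:

* **Per-epoch path resampling** (`resample_paths=True`): each epoch draws a
  fresh set of five meta-paths per node. With a single static sample the
  realised pair frequencies are a high-variance estimate of the transition
  distributions and the ranking is measurably noisier (planted-link AUROC
  ≈ 0.70 static vs ≈ 0.88 resampled on the bundled simulator); resampling
  also matches the "paths per node per epoch" training description the
  design follows. A static mode is kept for strict corpus-style training.
* **Linear learning-rate decay** from 0.1 to 0 across epochs
  (`lr_decay="linear"`): constant 0.1 leaves the iterates on a stationary
  noise floor; decay anneals it away. Constant mode is a flag.

Early stopping (plateau of the epoch-mean objective, tol 1e-4, patience 5)
exists but is off by default: with resampling the epoch objective fluctuates
and the plateau rule fires spuriously. Divergence (non-finite `F`) aborts
with a diagnostic. With a fixed seed the whole pipeline — simulation, QC,
networks, walks, SGD — is byte-reproducible; parallelism is deliberately
absent (`n_jobs=1` everywhere).

## Distances, rankings, subgroups, differential analysis

Peak–gene rankings use Euclidean distance, ties broken by peak index;
importance = `exp(−distance)`, so `−log` recovers the distance exactly.
Ranking *evaluation* uses the pair universe of peaks within 200 kb of the
gene body — the protocol used for peak–gene detection assessment — which is
wider than the 100 kb candidate window the regressions see.

Gene subgroups come from k-means on gene embedding rows followed by greedy
repair to hard size bounds (oversized clusters shed farthest members to the
nearest non-full cluster; undersized clusters pull nearest available
genes). Feasibility (`n_groups·size_min ≤ q ≤ n_groups·size_max`) is
checked up front. Peak assignment is the union of each member gene's K
nearest peaks (default K=5) or a centroid-radius rule.

Differential regulation builds a cosine-similarity KNN graph (k = 20,
negative similarities clipped to zero) per condition from the gene embedding
rows and embeds both jointly through the unnormalised Laplacian of the
two graphs anchored gene-to-gene. The anchor weight defaults to the maximum
weighted degree of the two graphs: any eigenmode that splits the two copies
of a gene then costs at least 2·max-degree ≥ λ_max(L) more than its
condition-consistent counterpart, so when the two graphs agree the retained
eigenvectors are exactly condition-symmetric and every displacement is zero
— the identical-input null holds by construction, not by tolerance tuning.
Scores are per-gene Euclidean displacements between the two halves of the
joint embedding (trivial near-zero eigenvalues dropped); significance, if
requested, comes from permuting the gene-identity correspondence, which is
robust where a parametric approximation would not be. Swapping the two
conditions leaves the scores unchanged.

Subsample stability re-runs the full pipeline on two random 90% cell
subsamples and reports per-gene Spearman correlations of the peak-distance
vectors over the peaks retained in both runs; the label-shuffled control
permutes the peak correspondence of the same two runs, so no extra fits are
needed.

## Synthetic data

The generator emulates one homogeneous population: peaks on a regular grid
(12 kb spacing, 500 bp width, two chromosomes) grouped into contiguous
blocks of 10 driven by per-cell Gaussian block factors through a Bernoulli
logit (base logit −0.5, loading 1.5); counts are the open state inflated by
a small Poisson and thinned by 30% dropout. Genes sit in 4 co-expression
modules (log-scale loading 0.8); 20 of the 40 genes carry one planted cis
link — the gene body is placed within 60 kb of its regulatory peak so the
link always lies inside the ±100 kb candidate window among ~16 decoy peaks.
Expression is negative-binomial (dispersion 2.0) around
`exp(log 3 + module effect + 2.0 · centred accessibility of the planted
peak)` with 20% dropout. Effect size 2.0 on the log scale is a strong but
realistic cis effect: it leaves count-level peak–gene correlations of only
~0.25 after noise and dropout, so recovery is not trivial.

What the simulator does **not** emulate: batch effects, multiple cell
types, fragment-level ATAC structure, distance-decaying co-accessibility
within blocks (blocks are single-factor, the hard case for partial
correlations), trans regulation, or peak–peak/gene–gene edges that are
themselves confounded with the planted links. Passing tests therefore show
the machinery is correct and can recover clean planted structure at desk
scale; they do not certify performance on real multiome data.

A fixed worked example (20 cells × 12 peaks × 4 genes with hand-built,
dead-row-free networks) pins down the walk emission law exactly:
`|E| = T·(p+q)·5` and three distinct pair weights.

## Problem sizes and defaults

The default study conditions (500 cells, 200 peaks, 40 genes, 20 links) fit
one full pipeline in ~15 s on one CPU with `d=32`, `T=5`, 50 epochs; the
acceptance script's five seeds plus two stability fits take a few minutes.
The model-scale defaults (`d=100`, 100 epochs, batch 32, learning rate 0.1,
M=5 negatives, T=5) follow the published training configuration and are
what `scpoem run` uses unless overridden.

## Known limitations

* The graphical-Lasso co-accessibility weights underestimate large
  single-factor blocks (see above); Cicero's distance-scaled penalty is not
  implemented, only a distance-independent one.
* Lasso cross-validation per gene is the main cost at large q; the
  ensemble can be reduced to a single regressor where runtime matters.
* The per-gene PC regression is O(q) SVDs; above a few thousand HVGs a
  shared-subspace approximation would be preferable.
* Dead transition rows (genes isolated by the 95th-percentile threshold)
  truncate walks, so such genes receive systematically fewer training
  pairs and their embeddings are noisier.
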