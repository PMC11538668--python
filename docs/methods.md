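# Methods

## Scope and data model

`zonatlas` operates on Space Ranger-style bundles: a gene × spot integer
count matrix (MatrixMarket), features and barcodes TSVs, and a tissue
positions CSV. Only `in_tissue == 1` spots are read. Samples from
different nutritional conditions are merged by column concatenation with
condition-suffixed barcodes; no anchor-based batch integration is
performed. This is deliberate: the downstream statistics are computed per
condition or on jointly normalized data, and the synthetic studies used for
validation carry no batch structure. Analyses of real multi-slide data
with strong batch effects should integrate externally before import.

## Normalization and clustering

Counts are normalized as `log1p(count · scale / spot_total)` with
`scale = 1e4` (log library-size normalization). This replaces
variance-stabilizing transforms on purpose: it is fully specified,
dependency-free, monotone within a spot, and sufficient for the recovery
problems the pipeline is validated on. PCA (default 30 components) is
computed on per-gene standardized values of the top 2000 genes by variance;
clustering is Leiden modularity optimization (Reichardt–Bornholdt
configuration null, default resolution 0.8) on the symmetrized k-NN graph
(default k = 15, Euclidean in PC space), with labels relabelled by cluster
size so runs are deterministic under a fixed seed. The exact number of
clusters is data- and resolution-dependent and is never treated as a
target.

Per-spot QC reports genes detected, total UMIs, mitochondrial UMI fraction
(gene symbols with the mouse `mt-` prefix) and hemoglobin UMI fraction
(Hba-a1/Hba-a2/Hbb-bs/Hbb-bt). Zero-UMI spots are dropped. Clusters whose
median hemoglobin fraction exceeds 0.1 are flagged *minor*
(erythroid-contaminated, the "inner cluster" phenomenon of liver Visium
data) and excluded from axis inference; all other clusters are *major*.
Whether to exclude such spots from the axis is in principle an open choice;
exclusion is the default because globin-dominated spots carry little
hepatocyte signal and distort the expression manifold.

## Portal–central axis

The axis is reconstructed with diffusion pseudotime on major-cluster spots
jointly across conditions (a per-sample mode is available by running the
pipeline per bundle):

1. **Kernel.** `K_ij = exp(−d_ij² / (σ_i σ_j))` on PC-space distances with
   per-spot adaptive bandwidth σ_i = distance to the k-th nearest
   *distinct* neighbor. Counting duplicate spots would let σ_i → 0, making
   the walk nearly reducible — spurious eigenvalues at 1 that swamp the
   metric — so duplicates are skipped and σ is floored at 10⁻³ of the
   median pairwise distance. A fixed-width kernel is available.
2. **Spectrum.** The row-normalized transition matrix is diagonalized via
   the symmetric conjugation `D^{-1/2} K D^{-1/2}`; the trivial constant
   eigenvector is dropped and the top components (default 10) are kept with
   deterministic sign.
3. **Metric.** Components are weighted by λ/(1−λ) — the diffusion
   pseudotime metric, which sums the random walk over all path lengths.
   Plain eigenvalue weighting (`scaling="eigenvalue"`) is available, but on
   a one-dimensional gradient tissue the local kernel's spectrum decays
   slowly and the higher harmonics of the leading component then corrupt
   distances; λ/(1−λ) damps them and is the standard pseudotime choice.
4. **Root and orientation.** The root is the diffusion-space medoid of the
   cluster with the highest mean portal-marker expression (configurable);
   pseudotime is the Euclidean distance to the root in weighted
   diffusion-component space, min–max rescaled to [0, 1]. If mean
   portal-marker expression correlates positively with t, the axis is
   flipped, so t = 0 is always periportal. Orientation is idempotent and
   requires at least one marker from each pole.

The min–max rescale preserves ranks but not spacing: inferred t is a
monotone, generally nonlinear distortion of the anatomical coordinate.
Downstream statements should therefore be read rank-wise (rank correlation
is also how axis recovery is validated).

## Zonation classification

Genes are eligible when detected with **more than 10 counts in at least
200 spots** of the condition being classified (strict inequality on the
count, inclusive on the spot number). Eligible genes are summarized as
20-bin mean profiles of normalized expression along t — binning stabilizes
least squares on overdispersed counts and matches how profiles are
plotted; a raw-spot mode exists. Three families are fitted:

| family      | model                      | start values                            |
|-------------|----------------------------|-----------------------------------------|
| `poly2`     | `a + bt + ct²`             | unity (solved in closed form, see below) |
| `gauss`     | `h·exp(−(t−μ)²/2σ²)`       | h = 1, μ = mean(t), σ = 1               |
| `inv_gauss` | `C − h·exp(−(t−μ)²/2σ²)`   | C = max(y), h = max−min, μ = mean(t), σ = 1 |

The quadratic is linear in its coefficients, so the iterative refinement
from unit start values converges to the unique least-squares optimum; it is
solved directly by linear least squares for numerical exactness (an exactly
constant input short-circuits to the constant fit so its normalized range
is exactly zero). The peak models use bounded trust-region least squares
with σ ∈ [0.02, 10], μ ∈ [−0.5, 1.5], h ≥ 0, C ≥ 0 — the bounds prevent
degenerate spikes and runaway centers; this is a deliberate tightening of
unbounded fitting. Failed optimizations are recorded (`converged=False`),
never raised; a gene with no converged fit is labeled non-zonated with a
warning.

Model selection is by AIC `n·log(rss/n) + 2k` over converged fits, ties
broken poly2 → gauss → inv_gauss (the simplest family wins). Fitted
extrema are evaluated on a 512-point grid over the observed t range so
boundary-clipped and interior extrema are handled uniformly across
families; with 512 points the grid quantization error on the normalized
range of a σ ≥ 0.02 peak is below 1e-6.

**Normalized range** = `(max − min)/max` of the selected fitted curve, 0
when the fitted maximum is ≤ 1e-8. Labels:

* normalized range < 0.1 → **non_zonated**;
* selected `inv_gauss` with an interior argmin whose endpoints both exceed
  the trough by ≥ 0.1·max → **bipolar**;
* otherwise by argmax position m (relative to the observed t range):
  m ≤ 0.25 → **periportal**, m ≥ 0.75 → **pericentral**, interior →
  **midzonal**.

The 0.25/0.75 pole boundaries are a design choice (exposed in config),
mirroring the convention that the outer quarter of the axis at each end
belongs to the poles. The label rule is equivariant under axis flips
(periportal ↔ pericentral; the other labels fixed) and invariant to
rescaling the expression values, both of which are property-tested.
Transitions between conditions are plain cross-tabulations over genes
classified in both conditions; marginals conserve label counts exactly.

## Differential expression and ssGSEA

Marker/DE testing is the two-sided Wilcoxon rank-sum test on normalized
values: exact enumeration when both groups have ≤ 10 spots, tie-corrected
normal approximation otherwise, Benjamini–Hochberg FDR across genes. The
average log2 fold change is `log2((mean_a + 1)/(mean_b + 1))` on de-logged
normalized values; the pseudocount of 1 bounds the statistic at zero means.
Defaults: `|log2FC| > 0.25`, `FDR < 0.05`. No moderated-t path is
implemented.

ssGSEA ranks genes within each spot (descending, average ranks for ties)
and integrates the running difference between the in-set ECDF weighted by
rank^α (α = 0.25) and the unweighted out-set ECDF; the score is the sum of
that running difference over all positions. Sets sharing fewer than 5
genes with the matrix are skipped. Across-spot min–max normalization is
available but off by default. The five MSigDB set names used in the
fasting study ship as documented placeholders with empty member lists —
set membership requires MSigDB and is not bundled.

## Synthetic lobule studies

The simulator is the package's validation instrument; its defaults define
the study conditions used by the test suite and the acceptance script.

* **Geometry.** Two hexagonal lobules (circumradius 1) tiled edge to edge,
  500 spots each on a triangular lattice (seeded exact subsample of the
  lattice points inside each hexagon). The true coordinate r is the
  distance to the nearest central-vein center over the lobule radius,
  clipped to [0, 1]; with 500 spots per lobule the radial histogram
  occupies well over the 9 concentric layers of the anatomical unit. The
  analysis-axis truth is `t_true = 1 − r` (0 = periportal).
* **Panel.** 120 genes per family: periportal and pericentral monotone
  quadratics (slope parameters keep the profile monotone and the
  normalized range well above 0.1), midzonal Gaussians (μ ∈ [0.35, 0.65],
  σ ∈ [0.08, 0.15]), bipolar inverted Gaussians (trough depth 60–90% of
  the plateau), and flat genes. Landmark ids (Alb, Cyp2f2, Glul, Lgr5,
  Scd1, …) name the leading genes of each family for readability.
* **Condition effects.** Per zonated family, one eighth of the genes
  switch to flat in the refed condition (the lipogenic Fasn/Thrsp-style
  loss of zonation; 10% of the panel in total) and a further tenth get a
  1.5× fasted amplitude boost. Mitochondrial proportions are multiplied by
  1.5 in the fasted condition.
* **Counts.** Expected per-spot gene proportions are baseline abundance ×
  profile mean, renormalized to sum to one; library sizes are log-normal
  (σ = 0.25) around 24 000 UMIs — the per-spot depth scale of real liver
  Visium data — and counts are negative-binomial with a single global
  dispersion (default 10; variance m + m²/10). Mitochondrial flat genes
  are pinned at a baseline giving ≈ 15% mito UMI share and hemoglobin
  genes at ≈ 2%, matching real liver spots; 5% of spots ("erythroid")
  have hemoglobin proportions inflated 20-fold, which makes them
  globin-dominated and separable by clustering, as in real tissue.

What the simulator does **not** emulate: batch/slide effects, per-gene
dispersion, cell-type mixtures within spots, spatial covariance beyond the
radial coordinate, and segmentation noise in the lobule geometry. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct when its model family matches the data-generating process at a
realistic depth and noise level — not that real-tissue profiles are free of
the confounders above.

## Problem sizes and determinism

The default validation study is 600 genes × 1000 spots per condition ×
three conditions; the full analysis (simulation through classification)
runs in about a minute on one CPU, and the test suite in under two. All
stochastic steps consume explicit seeds; the pipeline fans one global seed
out to per-stage seeds by hashing the stage name (CRC-32 mixed with the
seed), and identical configurations produce byte-identical artifacts.

## Known limitations

* Pseudotime is a rank-faithful but nonlinearly stretched version of the
  anatomical coordinate; fitted peak positions (μ) are in inferred-axis
  units, not micrometres.
* The AIC-based family selection can prefer a concave quadratic over a
  Gaussian for broad midzonal peaks; the label is usually still correct
  because both yield an interior argmax.
* Wilcoxon DE across conditions treats spots as independent replicates;
  with one slide per condition, biological and slide effects are
  confounded (as in any unreplicated spatial design).
* The erythroid flag is a cluster-median rule; isolated contaminated spots
  inside hepatocyte clusters are not flagged.
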