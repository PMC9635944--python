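# Methods

This note documents the models, parameter choices and numerical decisions
behind `lipidhet`, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic count model

`simulate_counts` draws UMI counts from a negative-binomial model: gene g in
cell c has mean `μ_gc = L_c · w_g f_g,SC(c) / Σ_g' w_g' f_g',SC(c)` and
variance `μ + φ μ²`. Components:

* **Gene relative abundances** `w_g`: log-normal with σ = 1.5, the heavy
  right tail typical of transcriptome abundance distributions. SCD, FADS2
  and FASN are pinned to a well-expressed level (5 × e^σ) so their
  sub-cluster means are estimable from a few hundred cells.
* **Library sizes** `L_c`: log-normal with mean 5,000 UMIs and log-sd 0.25
  per cell.
* **Dispersion** φ = 0.4, in the range fitted to droplet scRNA-seq data.
* **Planted programs** `f_g,SC`: fold 4 applied to SCD in SCD-Hi, FADS2 in
  FADS2-Hi, FASN in FASN-Hi, all three in Triple-Hi, and fold 1/4 for all
  three in Triple-low. Forty lipid-pathway genes are each up-regulated
  (fold 4) in one program sub-cluster round-robin — this is what plants
  cross-sub-cluster variance exclusively in the Lipid metabolism set.
  Twenty private marker genes per sub-cluster (outside every metabolic
  pathway) give each cluster an identity for the marker-based resolution
  rule without touching the pathway comparison.
* **Cohort structure**: six patients mixed uniformly in each program
  sub-cluster; the planted PatientSpecific cluster draws all cells from one
  patient; Singleton has one cell.
* **Low-quality cluster**: library sizes scaled by 0.3 and gene weights
  raised to the power 1.5 before renormalization. The power term emulates
  degraded/low-complexity cells: it concentrates counts on abundant genes
  so the cluster is depressed in detected genes (nGene) as well as in
  library size (nUMI) — the two metrics the curation rule requires — while
  its median nGene (≈330) still clears the QC floor of 200, as a real
  low-quality cluster that survives QC must.
* **Mitochondrial genes**: 50 genes whose weights are scaled to ≈5% of
  counts, so the default cells sit well below the 20% QC ceiling.

Defaults (≈400 cells per program sub-cluster, ≈2,000–2,300 cells total,
2,000 genes) are the study conditions for all recovery experiments.

What the generator does **not** emulate: doublets, ambient RNA,
batch/chemistry effects, gene–gene correlation beyond the planted programs,
and patient-level expression shifts. Recovery results therefore show that
the pipeline's rules are implemented correctly and are sensitive at
realistic effect sizes — not that they are robust to every artifact of real
tumor data.

## QC and normalization

Removal rules are strict inequalities (removed when nUMI < 401,
nGene < 200, nGene > 6000, pct_mito > 20), so a cell at any boundary is
kept. `pct_mito` is computed on raw UMI counts (the matrix is UMI-based;
read-level fractions are unavailable from a count matrix). Each removed
cell is logged with the first rule that caught it, in the order
low_umi → low_genes → high_genes → high_mito. CP100k divides by the cell
total and scales by 10⁵; log expression downstream is ln(1 + CP100k)
(natural log, the common single-cell convention).

## Standardized variance (vst)

Per gene, raw-count mean and sample variance are computed across cells; a
local polynomial regression (degree 2, tricube weights, span 0.3 — i.e.
each fit uses the nearest 30% of genes on the log10-mean axis) predicts
log10 variance from log10 mean; counts are standardized by the predicted
sd, clipped **above** at √n_cells (counts are bounded below, so large
negative residuals cannot occur), and the score is Σz²/(n−1) with the
pre-clip mean. Zero-variance genes score 0. Ranking is by descending score
with lexicographic gene-ID tie-break so the enrichment input is
deterministic. Variable-gene selection keeps genes with mean normalized
expression in [0.125, 3] and standardized variance > 0.5; the variance
threshold is exposed as a single parameter (quantile-based dispersion
measures can be substituted by passing a different score vector).

## Preranked enrichment

The enrichment score is the classic weighted KS running sum (hit increment
|score|^p normalized over the set, miss decrement 1/(N−|S|)); ES is the
signed maximum-magnitude deviation, with exact magnitude ties broken toward
the positive deviation (guarded by a 10⁻¹² tolerance so float accumulation
noise cannot flip a mathematical tie). Significance uses gene-label
permutations: null ES for random same-size sets (pools shared between sets
of equal size), sign-stratified NES (ES divided by the mean |null ES| of
matching sign, the original GSEA convention) and the add-one permutation
p-value `(1 + #extreme) / (1 + #same-sign)`, which can never be exactly 0.
FDR across sets is Benjamini–Hochberg. Multilevel p-value refinement is
deliberately not reproduced: the NES ordering — the heterogeneity readout —
is unaffected, and the permutation estimator is exactly calibrated (the
null-uniformity check in the acceptance suite verifies this directly).
Default 10,000 permutations; recovery experiments use 500 and the
calibration check 1,000, which bound p-resolution but not the NES ranking.

## Marker tests and curation

The Wilcoxon rank-sum test uses the exact distribution for small tie-free
samples and the tie-corrected normal approximation otherwise. The hurdle
test is a two-part approximation to a full hurdle regression: a 1-df
binomial likelihood-ratio test on detection frequency plus a Welch t on log
expression among expressing cells (t² ≈ χ²₁), summed with summed df;
components that are undefined (no detection contrast, fewer than two
expressing cells per group) are dropped, and a gene expressed nowhere gets
p = 1. Fold change is (mean CP100k + 1)/(mean CP100k + 1), pseudocount 1.
BH adjustment is applied per test across genes within a cluster.

Resolution selection formalizes "chosen when known cell types appear" —
which requires human annotation — as the only objective rule available:
the largest resolution at which every cluster has ≥ 10 markers at
FDR < 0.01 under both tests with fold ≥ 2. Curation thresholds: singleton
< 2 cells; patient dominance strictly > 0.75 for one patient ("over 75%")
and ≥ 0.85 for two; "substantially lower" quality quantified as both
median nUMI and median nGene below 0.5 × the median over cells of the other
surviving clusters, evaluated simultaneously for all candidates. All
thresholds are configurable.

## Sub-cluster Z-scores and GSVA

Both Z conversions use the sample (n−1) standard deviation across
sub-clusters — with five sub-clusters the n vs n−1 choice is material
(ratio √(5/4) ≈ 1.12) and the sample form is used consistently; a gene with
identical means across sub-clusters gets Z = 0 with a warning. Program
calls use |Z| ≥ 0.5 (tau): all three fatty-acid genes high → Triple-Hi, all
low → Triple-low, exactly one high → that gene's -Hi label; several-but-not-
all high produce a composite label (e.g. "SCD+FASN-Hi") and none high
"Unclassified", surfacing ambiguity rather than forcing one of five names.

GSVA scores follow the kernel-CDF algorithm: size-factor normalization
(cell total / median total) + log1p in place of a heavier
variance-stabilizing fit — the kernel CDF step is rank-based and dominates
the transform, so this substitution changes little; then per gene a
Gaussian-kernel smoothed CDF across cells (bandwidth sd/4), per cell a
descending ranking of that statistic with symmetrically centered ranks
|n/2 − r|, and a weighted KS walk whose score is (max positive deviation)
− |max negative deviation|, bounded in [−1, 1]. Zero-variance genes are
dropped first. The computation is O(n_cells² · n_genes) and is meant for
matrices already restricted to the sub-clusters of interest.

## Isotopologue correction and fatty-acid quantification

The correction matrix `M[i,j] = C(n−j, i−j) p^{i−j} (1−p)^{n−i}` gives the
probability that a molecule with j tracer carbons appears at M+i when each
unlabeled carbon is ¹³C with probability p = 0.0107 (the accepted natural
abundance; configurable). Columns sum to 1 for any p ∈ [0,1). Correction
solves raw ≈ Mx by non-negative least squares — noise can otherwise produce
negative fractions — and renormalizes x to sum 1; tracer impurity and
heteroatom isotopes (O, H, S) are not modeled (carbon-only correction).
Fractional contribution is Σ i·xᵢ/(n Σ xᵢ), invariant to intensity scaling.

Desaturation indices are computed on raw ion counts; the
internal-standard/protein normalization cancels in the ratio and the
identity is asserted in the tests. The SCD index is palmitoleate/palmitate
and the FADS2 index sapienate/palmitate — the product-over-substrate
orientation; the reciprocal orientation that appears in some figure
captions is the same information inverted, and the product/substrate form
is the package's convention. The standard curve is an OLS fit with
intercept on the 9-point dilution series; inverse prediction
(response − intercept)/slope gives the amount, negative amounts clamp to 0
with a warning, and concentration is amount_µg / MW / volume_µL × 10⁶ with
a 20 µL default extraction volume.

## Death assay

The Cell Death Index is dead count / confluence (percent, 0–100]); a
timepoint with non-positive confluence yields a missing index, never a
fabricated one. The simulator accumulates Poisson increments (so counts are
integer, monotone non-decreasing) under logistic confluence growth damped
by the death burden; 109 timepoints at 2 h spacing span 9 days.

## Problem sizes and numerics

Recovery experiments run 20 seeds at the default ≈2,000-cell, 2,000-gene
condition with 500-permutation enrichment; the calibration check uses 200
random sets, 1,000 genes and 1,000 permutations; the enrichment-score
oracle is enumerated exhaustively for all sets of size ≤ 4 over 8–20-gene
rankings at weights 0 and 1. Numerical tolerances: Z-row moments to 1e-9,
oracle agreements to 1e-12, isotopologue round trips to 1e-8, CP100k sums
to 1e-6 relative. The loess window uses the k = ⌈0.3·n⌉ nearest genes with
tricube weights clipped at 1e-12 to keep the weighted least squares well
posed.

## Known limitations

* Clustering itself (graph construction, modularity optimization,
  embeddings) is out of scope; labelings are inputs.
* The hurdle test approximates a full hurdle regression without covariates
  (e.g. cellular detection rate); on data with strong detection-rate
  confounding its p-values will be optimistic.
* GSVA scoring scales quadratically in cells.
* The isotopologue correction is carbon-only; panels measured on fragments
  containing derivatization carbons need an adjusted carbon count.
* Synthetic recovery rates certify rule implementations at planted effect
  sizes, not performance on real tumor data.
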