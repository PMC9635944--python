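# lipidhet

Single-cell metabolic-heterogeneity scoring, fatty-acid program
classification and ¹³C fatty-acid tracing analysis.

Glioblastoma (GBM) grows in a lipid-poor microenvironment and its cancer
cells rely on *de novo* fatty-acid synthesis (FASN) followed by
mono-desaturation of palmitate either to palmitoleate (via SCD) or to the
unusual fatty acid sapienate (via FADS2). `lipidhet` implements the
computational side of studying that heterogeneity, for analysts working with
single-cell RNA-seq of tumors plus GC-MS fatty-acid panels:

1. **Cell QC and normalization** — cells are removed when nUMI < 401,
   nGene < 200, nGene > 6000 or > 20% mitochondrial counts; expression is
   normalized to counts per 100k (CP100k), `x_gc / Σ_g x_gc × 10⁵`.
2. **Heterogeneity scoring** — genes are ranked by their vst standardized
   variance across cancer cells and the ranked list is scored by preranked
   gene-set enrichment against a seven-set metabolic collection (one global
   set, five KEGG-style subcategories — Carbohydrate, Energy, Lipid,
   Nucleotide, Amino acid metabolism — and a remainder set). The normalized
   enrichment score (NES) of a pathway is its heterogeneity readout:
   `NES = ES / mean(|ES_null| of the same sign)` over gene-label
   permutations.
3. **Sub-cluster curation** — candidate clusterings are screened by a
   marker rule (every cluster needs ≥ 10 genes with FDR < 0.01 under both a
   Wilcoxon rank-sum and a two-part hurdle test, and fold change ≥ 2);
   sub-clusters are then removed when they are singletons, patient-specific
   (> 75% one patient, or ≥ 85% two patients) or low quality (median nUMI
   and nGene both under half of the remaining cells').
4. **Program classification** — per-sub-cluster mean CP100k expression of
   SCD, FADS2 and FASN is converted to Z-scores across sub-clusters,
   `Z_g,SC = (Ē_g,SC − μ(Ē_g)) / σ(Ē_g)`, and thresholded at |Z| ≥ 0.5 into
   the programs SCD-Hi, FADS2-Hi, FASN-Hi, Triple-Hi and Triple-low.
   GSVA-style kernel-CDF scores summarize cell-fate meta-modules the same
   way.
5. **¹³C tracing and fatty-acid quantification** — raw isotopologue
   spectra are corrected for natural ¹³C abundance (binomial convolution
   matrix, non-negative least squares), the tracer fractional contribution
   is `FC = Σᵢ i·xᵢ / (n Σᵢ xᵢ)`, desaturation activity is read out as the
   product/substrate ratios palmitoleate/palmitate (SCD index) and
   sapienate/palmitate (FADS2 index), and absolute concentrations come from
   a 9-point standard curve.
6. **Cell death analysis** — the Cell Death Index is the Sytox-positive
   dead-cell count divided by well confluence at each imaging timepoint.

Because the matching patient data are controlled-access, the package ships a
first-class synthetic-data module that generates every input with planted
ground truth — negative-binomial UMI counts with planted program
sub-clusters, a low-quality cluster, a patient-specific cluster,
mitochondrial genes, tracer spectra with natural-abundance convolution, and
death-assay time series — so the whole pipeline is testable end to end.

## Worked example

```python
import lipidhet as lh

adata, truth = lh.simulate_counts(lh.SimConfig(seed=0))
filtered, qc, removed = lh.qc_filter_cells(adata)

surviving, log = lh.curate_subclusters(
    truth.cell_subcluster, truth.cell_patient, qc)
prog = filtered[filtered.obs["subcluster"].isin(surviving)].copy()

ranked = lh.rank_genes(lh.standardized_variance(prog))
sets = lh.assemble_metabolic_sets(truth.pathway_mapping)
print(lh.gsea_preranked(ranked, sets, n_perm=10_000, seed=0)
      .sort_values("nes", ascending=False).round(3))

cp = lh.normalize_cp100k(prog)
profile = lh.cluster_mean_zscores(cp, prog.obs["subcluster"])
print(lh.classify_fa_programs(profile))
```

prints

```
                            es    nes   pval    fdr  size
set
Lipid metabolism         0.924  6.195  0.000  0.000    43
ALL METABOLISM           0.239  2.885  0.000  0.000   233
Carbohydrate metabolism  0.172  1.120  0.317  0.444    40
Nucleotide metabolism    0.147  0.956  0.504  0.588    40
Amino acid metabolism   -0.091 -0.705  0.853  0.853    40
Other Metabolism        -0.218 -1.471  0.072  0.126    30
Energy metabolism       -0.205 -1.598  0.038  0.088    40
{'FADS2-Hi': 'FADS2-Hi', 'FASN-Hi': 'FASN-Hi', 'SCD-Hi': 'SCD-Hi',
 'Triple-Hi': 'Triple-Hi', 'Triple-low': 'Triple-low'}
```

Lipid metabolism is by far the most heterogeneous pathway (NES 6.2,
permutation p below 10⁻⁴ at 10,000 permutations) because the generator
planted cross-sub-cluster expression programs only in lipid-pathway genes,
and all five planted fatty-acid programs are recovered exactly. The
curation step removed exactly the planted singleton, patient-specific and
low-quality clusters (`log` lists each with its reason).

On the tracing side:

```python
spectra, panel, curve, _ = lh.simulate_tracer_panel(
    {"palmitate": 0.45, "palmitoleate": 0.3, "sapienate": 0.7},
    {"palmitate": 16, "palmitoleate": 16, "sapienate": 16},
    noise_cv=0.01, seed=0)
x = lh.natural_abundance_correction(spectra[("palmitate", 0)],
                                    residual_tol=float("inf"))
print(round(lh.fractional_contribution(x), 4))   # 0.4494  (planted: 0.45)
print(lh.desaturation_indices(panel)[["scd_index", "fads2_index"]].round(3))
```

recovers the planted glucose-tracer fractional contribution to within the
1% measurement noise.

A thin CLI mirrors the library: `lipidhet simulate`, `lipidhet qc`,
`lipidhet hetero`, `lipidhet classify`, `lipidhet tracer correct`,
`lipidhet death`, `lipidhet simulate-assays`.

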