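"""Synthetic data with planted ground truth for every pipeline stage.

Three generators:

* :func:`simulate_counts` — a multi-patient UMI count matrix with planted
  fatty-acid-program sub-clusters (SCD-Hi, FADS2-Hi, FASN-Hi, Triple-Hi,
  Triple-low), a low-quality cluster (reduced library size), a
  patient-specific cluster, a singleton cluster, mitochondrial genes and a
  KEGG-like pathway -> category -> gene mapping.  Counts are negative
  binomial with gene-level relative abundances drawn log-normally and scaled
  per cell to a log-normal library size; program genes are fold-changed in
  their sub-cluster.  The cross-sub-cluster fold changes planted in the
  lipid-pathway genes are what makes lipid metabolism the most heterogeneous
  pathway downstream.

* :func:`simulate_tracer_panel` — 13C-glucose tracing spectra: planted
  per-species label distributions (binomial in the tracer enrichment)
  convolved with binomial natural 13C abundance, a fatty-acid ion-count
  panel with a heptadecanoate internal standard, and a 9-point standard
  dilution series; multiplicative log-normal noise with a given CV.

* :func:`simulate_death_assay` — cumulative dead-cell counts (Poisson
  increments) and logistic confluence curves per well and condition.

All generators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData

from .fame import (
    FattyAcidPanel,
    IsotopologueVector,
    NATURAL_13C,
    StandardCurve,
    correction_matrix,
)

__all__ = [
    "PROGRAM_SUBCLUSTERS",
    "SimConfig",
    "PlantedTruth",
    "simulate_counts",
    "make_candidate_labelings",
    "TracerTruth",
    "simulate_tracer_panel",
    "simulate_death_assay",
    "write_counts",
    "read_counts",
]

PROGRAM_SUBCLUSTERS = ("SCD-Hi", "FADS2-Hi", "FASN-Hi", "Triple-Hi", "Triple-low")
LOWQ = "LowQuality"
PATIENT_SPECIFIC = "PatientSpecific"
SINGLETON = "Singleton"
FA_GENES = ("SCD", "FADS2", "FASN")

CATEGORY_PREFIX = {
    "Carbohydrate metabolism": "CARB",
    "Energy metabolism": "ENER",
    "Lipid metabolism": "LIPID",
    "Nucleotide metabolism": "NUCL",
    "Amino acid metabolism": "AMIN",
}


def _default_subcluster_sizes() -> dict[str, int]:
    sizes = {name: 400 for name in PROGRAM_SUBCLUSTERS}
    sizes[LOWQ] = 150
    sizes[PATIENT_SPECIFIC] = 150
    sizes[SINGLETON] = 1
    return sizes


@dataclass
class SimConfig:
    """Study conditions for the synthetic count matrix.

    Defaults: six patients, five ~400-cell program sub-clusters (about 2,000
    program cells), a 150-cell low-quality cluster with library sizes scaled
    by 0.3, a 150-cell single-patient cluster, a singleton, 2,000 genes of
    which 50 are mitochondrial (~5% of counts), mean library 5,000 UMIs,
    negative-binomial dispersion 0.4 and a 4-fold program effect.
    """

    n_patients: int = 6
    n_cells_per_subcluster: dict[str, int] = field(
        default_factory=_default_subcluster_sizes)
    n_genes: int = 2000
    n_mito_genes: int = 50
    library_size_mean: float = 5000.0
    library_size_sigma: float = 0.25  # log-normal sd of library sizes
    nb_dispersion: float = 0.4
    program_fold: float = 4.0
    lowq_library_factor: float = 0.3
    lowq_complexity_power: float = 1.5  # skews lowq gene weights (degraded RNA)
    patient_mix: pd.DataFrame | None = None  # subcluster x patient, rows sum to 1
    gene_abundance_sigma: float = 1.5
    mito_fraction: float = 0.05
    n_category_genes: int = 40
    n_other_metab_genes: int = 30
    n_marker_genes: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_genes < 1 or self.n_mito_genes < 0:
            raise ValueError("sizes must be positive")
        if any(n < 1 for n in self.n_cells_per_subcluster.values()):
            raise ValueError("every sub-cluster needs at least one cell")
        if not 0 < self.lowq_library_factor < 1:
            raise ValueError("lowq_library_factor must be in (0, 1)")
        if self.program_fold <= 1:
            raise ValueError("program_fold must exceed 1")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("dispersion and library size must be positive")
        n_special = (
            len(FA_GENES)
            + self.n_category_genes * len(CATEGORY_PREFIX)
            + self.n_other_metab_genes
            + self.n_marker_genes * (len(PROGRAM_SUBCLUSTERS) + 2)
            + self.n_mito_genes
        )
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_special} structured genes")
        if self.patient_mix is not None:
            rows = self.patient_mix.sum(axis=1)
            if not np.allclose(rows, 1.0):
                raise ValueError("patient_mix rows must sum to 1")


@dataclass
class PlantedTruth:
    """Ground truth planted by :func:`simulate_counts`."""

    cell_subcluster: pd.Series
    cell_patient: pd.Series
    subcluster_program: dict[str, str]
    pathway_mapping: pd.DataFrame  # columns pathway, category, gene
    program_genes: dict[str, list[str]]  # subcluster -> up/down-regulated genes
    marker_genes: dict[str, list[str]]
    lipid_program_genes: list[str]
    fold_matrix: pd.DataFrame  # gene x subcluster multiplicative folds


def _gene_table(cfg: SimConfig) -> pd.DataFrame:
    """Gene identifiers with category / pathway / role annotations."""
    rows: list[tuple[str, str, str, str]] = []  # gene, pathway, category, role
    rows += [
        ("SCD", "Fatty acid metabolism", "Lipid metabolism", "fa_gene"),
        ("FADS2", "Fatty acid metabolism", "Lipid metabolism", "fa_gene"),
        ("FASN", "Fatty acid metabolism", "Lipid metabolism", "fa_gene"),
    ]
    for cat, prefix in CATEGORY_PREFIX.items():
        role = "lipid_program" if cat == "Lipid metabolism" else "category"
        for i in range(cfg.n_category_genes):
            rows.append((f"{prefix}{i:03d}", f"{prefix} pathway", cat, role))
    for i in range(cfg.n_other_metab_genes):
        rows.append((f"OMET{i:03d}", "Uncategorized pathway", "", "other_metab"))
    for sc in (*PROGRAM_SUBCLUSTERS, LOWQ, PATIENT_SPECIFIC):
        tag = sc.replace("-", "").replace("_", "").upper()
        for i in range(cfg.n_marker_genes):
            rows.append((f"MK{tag}{i:03d}", "", "", f"marker:{sc}"))
    for i in range(cfg.n_mito_genes):
        rows.append((f"MT-{i:03d}", "", "", "mito"))
    n_filler = cfg.n_genes - len(rows)
    for i in range(n_filler):
        rows.append((f"GENE{i:04d}", "", "", "background"))
    return pd.DataFrame(rows, columns=["gene", "pathway", "category", "role"])


def _fold_matrix(cfg: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    subclusters = list(cfg.n_cells_per_subcluster)
    F = pd.DataFrame(1.0, index=genes["gene"], columns=subclusters)
    f = cfg.program_fold
    up = {
        "SCD": ("SCD-Hi", "Triple-Hi"),
        "FADS2": ("FADS2-Hi", "Triple-Hi"),
        "FASN": ("FASN-Hi", "Triple-Hi"),
    }
    for g, scs in up.items():
        for sc in scs:
            if sc in F.columns:
                F.loc[g, sc] = f
        if "Triple-low" in F.columns:
            F.loc[g, "Triple-low"] = 1.0 / f
    # lipid program genes: each up in one program sub-cluster (round-robin),
    # planting cross-sub-cluster variance in the Lipid pathway only
    lipid = genes.loc[genes["role"] == "lipid_program", "gene"].tolist()
    programs = [sc for sc in PROGRAM_SUBCLUSTERS if sc in F.columns]
    for i, g in enumerate(lipid):
        F.loc[g, programs[i % len(programs)]] = f
    # marker genes: up only in their own sub-cluster
    for sc in (*PROGRAM_SUBCLUSTERS, LOWQ, PATIENT_SPECIFIC):
        if sc not in F.columns:
            continue
        mk = genes.loc[genes["role"] == f"marker:{sc}", "gene"]
        F.loc[mk, sc] = f
    return F


def _patient_mix(cfg: SimConfig) -> pd.DataFrame:
    subclusters = list(cfg.n_cells_per_subcluster)
    if cfg.patient_mix is not None:
        return cfg.patient_mix
    patients = [f"P{i + 1}" for i in range(cfg.n_patients)]
    mix = pd.DataFrame(
        1.0 / cfg.n_patients, index=subclusters, columns=patients)
    if PATIENT_SPECIFIC in mix.index:
        mix.loc[PATIENT_SPECIFIC] = 0.0
        mix.loc[PATIENT_SPECIFIC, patients[0]] = 1.0
    return mix


def simulate_counts(config: SimConfig | None = None) -> tuple[AnnData, PlantedTruth]:
    """Generate a UMI count matrix with planted sub-cluster programs.

    Returns ``(adata, truth)``: cells x genes AnnData with raw integer
    counts, ``obs['patient']``/``obs['subcluster']`` and ``var['mito']``.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = _gene_table(cfg)
    fold = _fold_matrix(cfg, genes)
    mix = _patient_mix(cfg)

    # gene relative abundances: log-normal, FA genes well-expressed, mito
    # genes scaled to the target fraction of counts
    w = rng.lognormal(mean=0.0, sigma=cfg.gene_abundance_sigma, size=len(genes))
    is_fa = genes["role"].eq("fa_gene").to_numpy()
    w[is_fa] = np.exp(cfg.gene_abundance_sigma) * 5.0
    is_mito = genes["role"].eq("mito").to_numpy()
    if is_mito.any():
        other = w[~is_mito].sum()
        w[is_mito] *= cfg.mito_fraction * other / ((1 - cfg.mito_fraction)
                                                   * w[is_mito].sum())

    cell_rows, sub_labels, pat_labels = [], [], []
    phi = cfg.nb_dispersion
    r = 1.0 / phi
    for sc, n_cells in cfg.n_cells_per_subcluster.items():
        lib = rng.lognormal(
            mean=np.log(cfg.library_size_mean) - cfg.library_size_sigma**2 / 2,
            sigma=cfg.library_size_sigma,
            size=n_cells,
        )
        weights = w * fold[sc].to_numpy()
        if sc == LOWQ:
            # degraded cells: smaller libraries and lower transcriptome
            # complexity (counts concentrated on the abundant genes)
            lib = lib * cfg.lowq_library_factor
            weights = weights**cfg.lowq_complexity_power
        p_gene = weights / weights.sum()
        mu = lib[:, None] * p_gene[None, :]
        counts = rng.negative_binomial(r, r / (r + mu))
        cell_rows.append(counts)
        sub_labels += [sc] * n_cells
        pat_labels += list(
            rng.choice(mix.columns, size=n_cells, p=mix.loc[sc].to_numpy()))

    X = np.vstack(cell_rows)
    obs = pd.DataFrame(
        {"patient": pat_labels, "subcluster": sub_labels},
        index=[f"CELL{i:05d}" for i in range(X.shape[0])],
    )
    var = pd.DataFrame(
        {
            "mito": genes["role"].eq("mito").to_numpy(),
            "role": genes["role"].to_numpy(),
        },
        index=genes["gene"],
    )
    adata = AnnData(X=X.astype(np.int64), obs=obs, var=var)

    mapping = genes.loc[genes["pathway"] != "", ["pathway", "category", "gene"]]
    program = {sc: sc for sc in PROGRAM_SUBCLUSTERS if sc in fold.columns}
    for sc, label in ((LOWQ, LOWQ), (PATIENT_SPECIFIC, PATIENT_SPECIFIC),
                      (SINGLETON, SINGLETON)):
        if sc in fold.columns:
            program[sc] = label
    program_genes = {
        sc: fold.index[fold[sc] != 1.0].tolist() for sc in fold.columns
    }
    marker_genes = {
        sc: genes.loc[genes["role"] == f"marker:{sc}", "gene"].tolist()
        for sc in (*PROGRAM_SUBCLUSTERS, LOWQ, PATIENT_SPECIFIC)
        if sc in fold.columns
    }
    truth = PlantedTruth(
        cell_subcluster=obs["subcluster"].copy(),
        cell_patient=obs["patient"].copy(),
        subcluster_program=program,
        pathway_mapping=mapping.reset_index(drop=True),
        program_genes=program_genes,
        marker_genes=marker_genes,
        lipid_program_genes=genes.loc[
            genes["role"] == "lipid_program", "gene"].tolist(),
        fold_matrix=fold,
    )
    return adata, truth


def make_candidate_labelings(
    truth: PlantedTruth,
    subclusters: list[str] | None = None,
    seed: int = 0,
) -> list:
    """Candidate clusterings at three mock resolutions from the truth.

    Restricted to ``subclusters`` (default: the five program sub-clusters):
    resolution 0.5 merges sub-cluster pairs (coarse but still marked),
    resolution 1.0 is the planted labeling, and resolution 2.0 additionally
    carves a spurious cluster out of a random 10% of all cells — a mixture
    with no coherent expression program and hence no distinguishing
    markers, so the marker rule fails for that candidate.
    """
    from .curation import Labeling

    rng = np.random.default_rng(seed)
    subclusters = subclusters or list(PROGRAM_SUBCLUSTERS)
    labels = truth.cell_subcluster[truth.cell_subcluster.isin(subclusters)]

    merged = labels.copy()
    for a, b in zip(subclusters[0::2], subclusters[1::2]):
        merged[labels.isin([a, b])] = f"{a}|{b}"

    noisy = labels.copy().astype(object)
    spurious = rng.choice(labels.index, size=max(len(labels) // 10, 4),
                          replace=False)
    noisy.loc[spurious] = "spurious"

    return [
        Labeling(0.5, merged),
        Labeling(1.0, labels.copy()),
        Labeling(2.0, noisy),
    ]


@dataclass
class TracerTruth:
    """Planted tracer enrichment and label distributions."""

    fractional_contribution: dict[str, float]
    label_distributions: dict[str, np.ndarray]
    curve_slope: float
    curve_intercept: float


def simulate_tracer_panel(
    true_fractional_contribution: dict[str, float],
    n_carbons: dict[str, int],
    natural_13c: float = NATURAL_13C,
    noise_cv: float = 0.05,
    n_samples: int = 3,
    total_intensity: float = 1e6,
    internal_standard_counts: float = 2e5,
    protein_mg: float = 0.5,
    curve_slope: float = 5e4,
    curve_intercept: float = 0.0,
    seed: int = 0,
) -> tuple[dict[tuple[str, int], IsotopologueVector], FattyAcidPanel,
           StandardCurve, TracerTruth]:
    """Generate 13C tracing spectra, a fatty-acid panel and a standard curve.

    The planted label distribution of a species with n carbons and
    fractional contribution FC is Binomial(n, FC); the raw spectrum is that
    distribution convolved with binomial natural 13C abundance on the
    unlabeled carbons, scaled to ``total_intensity`` and perturbed by
    multiplicative log-normal noise with CV ``noise_cv``.
    """
    for sp, fc in true_fractional_contribution.items():
        if not 0 <= fc <= 1:
            raise ValueError(f"fractional contribution for {sp!r} outside [0, 1]")
        if n_carbons.get(sp, 0) < 2:
            raise ValueError(f"species {sp!r} needs at least 2 carbons")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))

    def noisy(x):
        if noise_cv == 0:
            return np.asarray(x, dtype=float)
        return x * rng.lognormal(-sigma**2 / 2, sigma, size=np.shape(x))

    label_dists: dict[str, np.ndarray] = {}
    spectra: dict[tuple[str, int], IsotopologueVector] = {}
    for sp, fc in true_fractional_contribution.items():
        n = n_carbons[sp]
        i = np.arange(n + 1)
        from scipy.stats import binom

        x = binom.pmf(i, n, fc)
        label_dists[sp] = x
        M = correction_matrix(n, natural_13c)
        clean = total_intensity * (M @ x)
        for s in range(n_samples):
            spectra[(sp, s)] = IsotopologueVector(
                species=sp, n_carbons=n, intensities=noisy(clean))

    species = list(true_fractional_contribution)
    ion = pd.DataFrame(
        {sp: noisy(np.full(n_samples, total_intensity)) for sp in species},
        index=[f"S{i + 1}" for i in range(n_samples)],
    )
    ion["heptadecanoate"] = noisy(np.full(n_samples, internal_standard_counts))
    panel = FattyAcidPanel(
        ion_counts=ion,
        normalizer=pd.Series(protein_mg, index=ion.index, name="protein_mg"),
    )

    amounts = 20.0 / 2 ** np.arange(9)[::-1]  # nine 2x serial dilutions, ug
    responses = noisy(curve_slope * amounts + curve_intercept)
    curve = StandardCurve(amounts, responses)

    truth = TracerTruth(
        fractional_contribution=dict(true_fractional_contribution),
        label_distributions=label_dists,
        curve_slope=curve_slope,
        curve_intercept=curve_intercept,
    )
    return spectra, panel, curve, truth


def simulate_death_assay(
    baseline_rate: float,
    treatment_effects: dict[str, float],
    n_timepoints: int = 109,
    dt_hours: float = 2.0,
    n_wells: int = 3,
    start_confluence: float = 20.0,
    growth_rate: float = 0.04,
    seed: int = 0,
) -> pd.DataFrame:
    """Dead-cell counts and confluence per well, condition and timepoint.

    Dead counts accumulate Poisson increments with per-timepoint mean
    ``baseline_rate * effect``; confluence follows logistic growth toward
    95%, reduced by the condition's death burden, and stays in (0, 100].
    Conditions are ``control`` (effect 1) plus ``treatment_effects``.
    """
    if baseline_rate < 0 or any(e < 0 for e in treatment_effects.values()):
        raise ValueError("death rates must be non-negative")
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = np.random.default_rng(seed)
    conditions = {"control": 1.0, **treatment_effects}
    hours = np.arange(n_timepoints) * dt_hours
    rows = []
    for cond, effect in conditions.items():
        for w in range(n_wells):
            increments = rng.poisson(baseline_rate * effect, size=n_timepoints)
            dead = np.cumsum(increments)
            t = hours / hours[-1] if hours[-1] > 0 else hours
            logistic = 95.0 / (1 + np.exp(-growth_rate * (hours - hours[-1] / 3)))
            conf = np.maximum(start_confluence, logistic)
            conf = conf / (1 + 0.002 * baseline_rate * effect * t * hours)
            conf = np.clip(conf, 1e-3, 100.0)
            rows.append(pd.DataFrame({
                "well": f"{cond}-W{w + 1}",
                "condition": cond,
                "hours": hours,
                "dead_count": dead,
                "confluence": conf,
            }))
    return pd.concat(rows, ignore_index=True)


def write_counts(adata: AnnData, outdir) -> None:
    """Write a count matrix as MTX with genes/cells TSV sidecars."""
    import scipy.io
    import scipy.sparse as sp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.csr_matrix(adata.X))
    adata.var.rename_axis("gene").reset_index().to_csv(
        outdir / "genes.tsv", sep="\t", index=False)
    adata.obs.rename_axis("cell").reset_index().to_csv(
        outdir / "cells.tsv", sep="\t", index=False)


def read_counts(indir) -> AnnData:
    """Read a count matrix written by :func:`write_counts`."""
    import scipy.io

    indir = Path(indir)
    X = scipy.io.mmread(indir / "matrix.mtx").toarray().astype(np.int64)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell")
    return AnnData(X=X, obs=cells, var=genes)
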