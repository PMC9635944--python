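"""vst standardized variance: oracle agreement and selection rules."""

import numpy as np
import pandas as pd
import pytest

import lipidhet as lh
from lipidhet.variable_genes import loess_fit

from conftest import make_adata


def brute_force_standardized_variance(X, span=0.3):
    """Loop-based oracle: tricube-weighted local quadratic trend on
    log10(var) vs log10(mean), clip standardized values at sqrt(n), report
    their variance with an n-1 denominator."""
    n, g = X.shape
    mean = X.mean(axis=0)
    var = np.array([np.var(X[:, j], ddof=1) for j in range(g)])
    usable = (var > 0) & (mean > 0)
    lx, ly = np.log10(mean[usable]), np.log10(var[usable])
    k = max(int(np.ceil(span * lx.size)), 3)
    fitted = np.empty(lx.size)
    for i, x0 in enumerate(lx):
        d = np.abs(lx - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        w = (1 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(k)
        W = np.diag(np.clip(w, 1e-12, None))
        B = np.vander(lx[idx] - x0, 3, increasing=True)
        beta = np.linalg.solve(B.T @ W @ B, B.T @ W @ ly[idx])
        fitted[i] = beta[0]
    exp_sd = np.sqrt(10.0 ** fitted)
    clip = np.sqrt(n)
    out = np.zeros(g)
    cols = np.flatnonzero(usable)
    for pos, j in enumerate(cols):
        z = (X[:, j] - mean[j]) / exp_sd[pos]
        z = np.minimum(z, clip)
        out[j] = (z**2).sum() / (n - 1)
    return out


def test_matches_brute_force_oracle_with_outlier_cell():
    """50 genes x 100 cells with one extreme outlier cell (clipping active)."""
    rng = np.random.default_rng(7)
    X = rng.poisson(rng.lognormal(0.5, 1.0, size=50), size=(100, 50)).astype(float)
    X[0] += rng.poisson(60, size=50)  # outlier cell triggers the clip
    scores = lh.standardized_variance(make_adata(X))
    oracle = brute_force_standardized_variance(X)
    np.testing.assert_allclose(scores.to_numpy(), oracle, rtol=1e-8, atol=1e-10)


def test_constant_gene_scores_zero_and_monotone_at_fixed_mean():
    rng = np.random.default_rng(1)
    base = rng.poisson(5.0, size=(200, 30)).astype(float)
    base[:, 0] = 4.0  # constant gene
    # genes 1 and 2: equal mean, gene 2 strictly more variable, no clipping
    base[:, 1] = 5.0
    base[:100, 2], base[100:, 2] = 4.0, 6.0
    base[:100, 1], base[100:, 1] = 5.0, 5.0
    scores = lh.standardized_variance(make_adata(base))
    assert scores.iloc[0] == 0.0
    assert scores.iloc[2] > scores.iloc[1]


def test_scores_invariant_to_gene_permutation():
    rng = np.random.default_rng(3)
    X = rng.poisson(rng.lognormal(0, 1, 40), size=(60, 40)).astype(float)
    adata = make_adata(X)
    scores = lh.standardized_variance(adata)
    perm = rng.permutation(40)
    scores_perm = lh.standardized_variance(adata[:, perm].copy())
    np.testing.assert_allclose(
        scores_perm.to_numpy(), scores.to_numpy()[perm], rtol=1e-10)


def test_single_cell_errors_and_all_zero_warns():
    with pytest.raises(ValueError):
        lh.standardized_variance(make_adata(np.ones((1, 5))))
    with pytest.warns(UserWarning, match="constant"):
        scores = lh.standardized_variance(make_adata(np.zeros((5, 4))))
    assert (scores == 0).all()


def test_planted_high_variance_program_tops_ranking():
    """Program genes with planted cross-cluster folds fill the top ranks."""
    hits = 0
    for seed in range(10):
        adata, truth = lh.simulate_counts(_small_cfg(seed))
        scores = lh.standardized_variance(adata)
        planted = set(truth.lipid_program_genes) | {"SCD", "FADS2", "FASN"}
        top = set(lh.rank_genes(scores)["gene"].head(len(planted)))
        hits += len(top & planted) / len(planted)
    assert hits / 10 >= 0.9


def _small_cfg(seed):
    sizes = {name: 60 for name in lh.simulate.PROGRAM_SUBCLUSTERS}
    return lh.SimConfig(
        seed=seed,
        n_cells_per_subcluster=sizes,
        n_genes=400,
        n_mito_genes=10,
        n_category_genes=12,
        n_other_metab_genes=10,
        n_marker_genes=0,
        program_fold=6.0,
    )


def test_selection_rules_mean_window_and_variance_threshold():
    """Mean outside [0.125, 3] or standardized variance <= 0.5 excludes."""
    normalized = pd.DataFrame(
        {
            "low_mean": np.full(10, 0.10),
            "ok_but_flat": np.full(10, 1.0),
            "keeper": np.full(10, 1.0),
            "high_mean": np.full(10, 3.5),
        }
    )
    scores = pd.Series(
        {"low_mean": 5.0, "ok_but_flat": 0.4, "keeper": 2.0, "high_mean": 9.0})
    assert lh.select_variable_genes(normalized, scores) == ["keeper"]


def test_empty_selection_warns():
    normalized = pd.DataFrame({"g": np.full(5, 10.0)})
    with pytest.warns(UserWarning, match="no variable genes"):
        assert lh.select_variable_genes(normalized, pd.Series({"g": 9.0})) == []
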