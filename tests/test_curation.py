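"""Resolution selection by the marker rule and sub-cluster removal rules."""

import numpy as np
import pandas as pd
import pytest

import lipidhet as lh
from lipidhet.curation import CurationParams, Labeling, NoPassingResolution


def qc_frame(n, numi=5000, ngene=1000, prefix="c"):
    return pd.DataFrame(
        {"nUMI": numi, "nGene": ngene}, index=[f"{prefix}{i}" for i in range(n)])


def test_singleton_cluster_removed_with_reason():
    labels = pd.Series(["A"] * 5 + ["B"], index=[f"c{i}" for i in range(6)])
    patients = pd.Series(["P1", "P2", "P3", "P1", "P2", "P1"], index=labels.index)
    surviving, log = lh.curate_subclusters(labels, patients, qc_frame(6))
    assert surviving == ["A"]
    assert log.set_index("cluster").loc["B", "reason"] == "singleton"


def test_patient_dominance_rules():
    """80% single-patient removed; 75% exactly kept; 85% two-patient removed."""
    idx = [f"c{i}" for i in range(60)]
    labels = pd.Series(["A"] * 20 + ["B"] * 20 + ["C"] * 20, index=idx)
    patients = pd.Series(
        ["P1"] * 16 + ["P2", "P3", "P4", "P5"]          # A: 80% one patient
        + ["P1"] * 15 + ["P2", "P3", "P4", "P5", "P6"]  # B: 75% exactly -> kept
        + ["P1"] * 9 + ["P2"] * 8 + ["P3", "P4", "P5"],  # C: top two 85%
        index=idx,
    )
    surviving, log = lh.curate_subclusters(labels, patients, qc_frame(60))
    reasons = log.set_index("cluster")["reason"]
    assert reasons.get("A") == "patient_specific"
    assert reasons.get("C") == "patient_specific"
    assert surviving == ["B"]


def test_low_quality_rule_requires_both_metrics():
    idx = [f"c{i}" for i in range(30)]
    labels = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=idx)
    patients = pd.Series((["P1", "P2", "P3", "P4", "P5"] * 6), index=idx)
    qc = qc_frame(30)
    qc.iloc[20:, 0] = 1000  # C: nUMI well under half of the others' 5000
    qc.iloc[20:, 1] = 300   # and nGene under half of 1000
    surviving, log = lh.curate_subclusters(labels, patients, qc)
    assert surviving == ["A", "B"]
    assert log.set_index("cluster").loc["C", "reason"] == "low_quality"

    qc.iloc[20:, 1] = 800  # nGene no longer low -> cluster kept
    surviving, log = lh.curate_subclusters(labels, patients, qc)
    assert "C" in surviving and log.empty


def test_all_clusters_removed_warns():
    labels = pd.Series(["A", "B"], index=["c0", "c1"])
    patients = pd.Series(["P1", "P1"], index=labels.index)
    with pytest.warns(UserWarning, match="every sub-cluster"):
        surviving, log = lh.curate_subclusters(labels, patients, qc_frame(2))
    assert surviving == [] and len(log) == 2


def test_curation_recovers_planted_removable_set(default_sim):
    adata, truth = default_sim
    qc = lh.compute_cell_qc(adata)
    surviving, log = lh.curate_subclusters(
        truth.cell_subcluster, truth.cell_patient, qc)
    assert sorted(surviving) == sorted(lh.simulate.PROGRAM_SUBCLUSTERS)
    removed = log.set_index("cluster")["reason"].to_dict()
    assert removed == {
        "Singleton": "singleton",
        "PatientSpecific": "patient_specific",
        "LowQuality": "low_quality",
    }


def test_resolution_selection_returns_largest_passing(small_sim):
    """Coarse and true labelings pass the marker rule, the over-clustered
    one (with a spurious mixed cluster) fails; the true labeling (largest
    passing resolution) is selected."""
    adata, truth = small_sim
    candidates = lh.make_candidate_labelings(truth, seed=0)
    prog = adata[adata.obs["subcluster"].isin(lh.simulate.PROGRAM_SUBCLUSTERS)]
    cp = lh.normalize_cp100k(prog.copy())
    chosen, audit = lh.select_resolution(cp, candidates)
    assert chosen.resolution == 1.0
    assert chosen.clusters.equals(candidates[1].clusters)
    by_res = audit.groupby("resolution")["pass"].all()
    assert bool(by_res[0.5]) and bool(by_res[1.0]) and not bool(by_res[2.0])
    spurious = audit[(audit["resolution"] == 2.0)
                     & (audit["cluster"] == "spurious")]
    assert int(spurious["n_markers"].iloc[0]) < 10


def test_single_passing_candidate_returned(small_sim):
    adata, truth = small_sim
    prog = adata[adata.obs["subcluster"].isin(lh.simulate.PROGRAM_SUBCLUSTERS)]
    cp = lh.normalize_cp100k(prog.copy())
    labeling = Labeling(0.8, truth.cell_subcluster[cp.index])
    chosen, _ = lh.select_resolution(cp, [labeling])
    assert chosen is labeling


def test_no_passing_candidate_raises_with_audit(small_sim):
    adata, truth = small_sim
    prog = adata[adata.obs["subcluster"].isin(lh.simulate.PROGRAM_SUBCLUSTERS)]
    cp = lh.normalize_cp100k(prog.copy())
    rng = np.random.default_rng(1)
    shuffled = pd.Series(
        rng.permutation(truth.cell_subcluster[cp.index].to_numpy()),
        index=cp.index,
    )
    with pytest.raises(NoPassingResolution) as excinfo:
        lh.select_resolution(cp, [Labeling(0.2, shuffled)])
    assert not excinfo.value.audit["pass"].any()
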