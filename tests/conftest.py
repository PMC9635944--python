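import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from hypothesis import HealthCheck, settings

import lipidhet as lh

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across read-only tests."""
    return lh.simulate_counts(lh.SimConfig(seed=0))


def small_config(seed=0):
    """A reduced configuration for expensive per-gene tests."""
    sizes = {name: 40 for name in lh.simulate.PROGRAM_SUBCLUSTERS}
    sizes["LowQuality"] = 20
    sizes["PatientSpecific"] = 20
    sizes["Singleton"] = 1
    return lh.SimConfig(
        seed=seed,
        n_cells_per_subcluster=sizes,
        n_genes=320,
        n_mito_genes=10,
        n_category_genes=10,
        n_other_metab_genes=10,
        n_marker_genes=15,
        library_size_mean=2000.0,
    )


@pytest.fixture(scope="session")
def small_sim():
    return lh.simulate_counts(small_config(seed=0))


def make_adata(counts, mito=None, patients=None):
    """AnnData from a dense cell x gene count array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    if patients is not None:
        obs["patient"] = patients
    var = pd.DataFrame(index=[f"g{j}" for j in range(n_genes)])
    var["mito"] = np.zeros(n_genes, bool) if mito is None else np.asarray(mito, bool)
    return AnnData(X=counts.astype(np.int64), obs=obs, var=var)
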