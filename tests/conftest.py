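import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

import ecofinger as ef
from ecofinger.config import GainRegion


def make_adata(X, cell_types=None, **obs_cols):
    """Tiny AnnData with generated ids and optional obs columns."""
    X = np.asarray(X, dtype=float)
    obs = pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    if cell_types is not None:
        obs["cell_type"] = list(cell_types)
    for k, v in obs_cols.items():
        obs[k] = list(v)
    var = pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])])
    return AnnData(X=X, obs=obs, var=var)


@pytest.fixture(scope="session")
def small_cohort():
    """3 patients x 5 regions, modest sizes; default gains planted."""
    cfg = ef.SimulationConfig(
        seed=0,
        n_patients=3,
        n_malignant_per_region=20,
        n_per_celltype=10,
        n_genes=800,
        n_chromosomes=8,
        gain_regions=[
            GainRegion("chr1", 0.5, 1.0, 2.0),
            GainRegion("chr8", 0.5, 1.0, 2.0),
        ],
    )
    return cfg, ef.simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full study conditions: 6 patients, 2000 genes, 2x gains on 10%
    of the genome, fingerprint pairs planted."""
    cfg = ef.SimulationConfig(seed=1)
    return cfg, ef.simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_norm(default_cohort):
    _, adata = default_cohort
    norm = ef.cells.qc_and_normalize(adata, min_genes_per_cell=50)
    return norm


@pytest.fixture(scope="session")
def default_calls(default_norm):
    """CNV inference + malignant calling on the default cohort."""
    cnv = ef.cells.infer_cnv(
        default_norm,
        (default_norm.obs["region"] == "N").to_numpy(),
        window_genes=50,
    )
    meta = ef.cells.call_malignant(cnv, default_norm.obs)
    return cnv, meta


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    _, adata = small_cohort
    norm = ef.cells.qc_and_normalize(adata, min_genes_per_cell=40)
    norm.obs["is_malignant"] = norm.obs["true_malignant"]
    norm.obs["cell_type"] = np.where(
        norm.obs["true_malignant"], "malignant", norm.obs["true_type"]
    )
    return norm
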