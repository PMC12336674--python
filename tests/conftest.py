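import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from gicmp import preprocessing as pp
from gicmp import simulate as sim


def make_adata(counts, mito=None, ribo=None, obs=None, gene_names=None):
    """Small AnnData builder for hand-crafted fixtures."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if gene_names is None:
        gene_names = [f"G{i:04d}" for i in range(n_genes)]
    var = pd.DataFrame(index=gene_names)
    var["mt"] = np.zeros(n_genes, dtype=bool) if mito is None else np.asarray(mito)
    var["ribo"] = np.zeros(n_genes, dtype=bool) if ribo is None else np.asarray(ribo)
    if obs is None:
        obs = pd.DataFrame(
            {
                "sample": ["S0"] * n_cells,
                "cancer_type": ["GC"] * n_cells,
                "major_type": ["Epithelial"] * n_cells,
                "subtype": ["Epithelial"] * n_cells,
            },
            index=[f"c{i:04d}" for i in range(n_cells)],
        )
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 12-sample, 3-cancer-type cohort with planted programs."""
    spec = sim.CohortSpec(seed=1)
    adata, gt = sim.generate_cohort(spec)
    return adata, gt, spec


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    adata, gt, spec = default_cohort
    filtered, report = pp.filter_cells(adata)
    filtered = pp.filter_genes(filtered, report=report)
    norm = pp.normalize(filtered)
    samples = pp.select_samples(norm, report=report)
    return norm, gt, samples, report


@pytest.fixture(scope="session")
def small_spec():
    """A lighter cohort for unit tests that refit NMF."""
    return sim.CohortSpec(
        n_samples=4,
        n_cells_per_sample=(120, 160),
        n_genes=800,
        n_shared_programs=2,
        n_private_programs_per_sample=1,
        active_fraction=0.3,
        seed=7,
    )
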