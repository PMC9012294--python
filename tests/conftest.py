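import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from clonalshift import ClonotypeTable, CohortConfig


def make_table(counts, patient="P01", timepoint="pre", chain="TRB"):
    """Clonotype table with synthetic identities A, B, C... and given counts."""
    rows = []
    for i, c in enumerate(counts):
        letter = chr(ord("A") + i)
        rows.append((f"TRBV{i+1}-1", "TRBJ1-1", f"TGT{letter * 9}TTT", c))
    df = pd.DataFrame(rows, columns=["v_call", "j_call", "junction", "count"])
    return ClonotypeTable(patient, timepoint, chain, df)


@pytest.fixture
def small_adata():
    """6 cells x 4 genes, two clusters, one patient, both timepoints."""
    X = sp.csr_matrix(np.array([
        [5, 0, 3, 2],
        [1, 1, 0, 0],
        [0, 4, 4, 2],
        [2, 2, 2, 2],
        [0, 0, 1, 9],
        [3, 1, 0, 6],
    ]))
    obs = pd.DataFrame({
        "patient_id": ["P01"] * 6,
        "timepoint": ["pre", "pre", "pre", "post", "post", "post"],
        "cluster_id": [0, 0, 1, 0, 1, 1],
    }, index=[f"c{i}" for i in range(6)])
    var = pd.DataFrame(index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"))
    return AnnData(X=X, obs=obs, var=var)


def tiny_cohort_config(seed=0, **overrides):
    """A fast, small cohort for pipeline-level tests."""
    defaults = dict(
        n_patients=4,
        responder_fraction=0.5,
        n_clones=200,
        reads_per_sample=4000,
        n_clusters=4,
        cells_per_sample=240,
        n_genes=80,
        counts_per_cell=400,
        baseline_dirichlet=(40, 30, 20, 12),
        pdc_cluster_index=3,
        innate_cluster_indices=(2, 3),
        t1irg_set_size=10,
        n_marker_genes=4,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)
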