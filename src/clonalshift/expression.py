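"""Single-cell expression statistics for paired pre/post samples.

All statistics run on counts-per-10k, natural-log1p normalized values
(the UMI-count community default).  Cluster labels are taken as input;
no clustering, QC or batch correction happens here.

Core quantities:

* per-sample cluster proportions and their continuity-corrected log2FC;
* per-stratum (patient x timepoint x cluster) pseudobulk mean expression;
* per-gene post-vs-pre log2 fold change on detected genes;
* the disturbance score — the mean of |log2FC| over a cluster's detected
  genes, a scalar summary of how globally perturbed a cluster's
  transcriptome is between the paired samples;
* per-cell pathway mean-expression scores and marker-panel cluster
  annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .genesets import GeneSet, MarkerPanel

logger = logging.getLogger(__name__)

META_COLUMNS = ["patient_id", "timepoint", "cluster_id"]

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_MIN_CELLS = 3


@dataclass
class ClusterLogFC:
    """Per-gene post-vs-pre log2FC for one patient's cluster."""

    patient_id: str
    cluster_id: object
    logfc: pd.Series  # indexed by genes_used
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def genes_used(self) -> pd.Index:
        return self.logfc.index


@dataclass
class DisturbanceRecord:
    """Mean absolute gene-expression log2FC for one patient's cluster."""

    patient_id: str
    cluster_id: object
    score: float
    n_genes: int


def _require_meta(adata: AnnData) -> None:
    missing = [c for c in META_COLUMNS if c not in adata.obs.columns]
    if missing:
        raise ValueError(f"cell metadata lacks column(s) {missing}")


def normalize_cp10k_log(adata: AnnData) -> AnnData:
    """Counts-per-10k, natural-log1p normalization.

    value = ln(1 + 1e4 * count / cell_total).  Cells with zero total count
    are dropped with a warning.  Scale-invariant per cell: multiplying a
    cell's counts by a constant leaves its normalized values unchanged.
    """
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if totals.sum() == 0:
        raise ValueError("all-zero count matrix")
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d zero-count cells", int((~keep).sum()))
        adata = adata[keep].copy()
        X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
        totals = totals[keep]
    X = X.tocsr().astype(np.float64)
    scale = 1e4 / totals
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    out = adata.copy()
    out.X = X.tocsr()
    return out


def cluster_proportions(
    meta: pd.DataFrame, patient_id: str, timepoint: str, clusters=None
) -> pd.Series:
    """Fraction of a sample's cells in each cluster; sums to 1.

    ``clusters`` fixes the cluster universe (absent clusters get 0);
    defaults to the clusters present in ``meta``.
    """
    sel = meta[(meta["patient_id"] == patient_id) & (meta["timepoint"] == timepoint)]
    if sel.empty:
        raise ValueError(f"no cells for patient {patient_id!r} timepoint {timepoint!r}")
    if clusters is None:
        clusters = sorted(meta["cluster_id"].unique())
    counts = sel["cluster_id"].value_counts().reindex(clusters, fill_value=0)
    return counts / counts.sum()


def cluster_cell_counts(
    meta: pd.DataFrame, patient_id: str, timepoint: str, clusters
) -> pd.Series:
    """Per-cluster cell counts for one sample, over a fixed cluster universe."""
    sel = meta[(meta["patient_id"] == patient_id) & (meta["timepoint"] == timepoint)]
    return sel["cluster_id"].value_counts().reindex(clusters, fill_value=0)


def proportion_logfc(pre_counts, post_counts, n_clusters: Optional[int] = None) -> np.ndarray:
    """Continuity-corrected per-cluster log2 fold change of proportions.

    log2[((n_post+0.5)/(N_post+0.5K)) / ((n_pre+0.5)/(N_pre+0.5K))] with a
    Haldane-style 0.5 correction so clusters absent in one sample stay
    finite, and clusters absent in both give exactly 0.
    """
    pre = np.asarray(pre_counts, dtype=float)
    post = np.asarray(post_counts, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post count vectors differ in length")
    if (pre < 0).any() or (post < 0).any():
        raise ValueError("negative cell counts")
    K = n_clusters if n_clusters is not None else pre.size
    p_pre = (pre + 0.5) / (pre.sum() + 0.5 * K)
    p_post = (post + 0.5) / (post.sum() + 0.5 * K)
    return np.log2(p_post / p_pre)


def pseudobulk_mean(
    adata_norm: AnnData,
    patient_id: str,
    timepoint: str,
    cluster_id,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> Optional[pd.Series]:
    """Per-gene mean of normalized expression over one stratum's cells.

    Returns ``None`` (a missing stratum) when fewer than ``min_cells``
    cells fall in the stratum.
    """
    _require_meta(adata_norm)
    obs = adata_norm.obs
    mask = (
        (obs["patient_id"] == patient_id)
        & (obs["timepoint"] == timepoint)
        & (obs["cluster_id"] == cluster_id)
    ).to_numpy()
    n = int(mask.sum())
    if n < min_cells:
        logger.info(
            "stratum (%s, %s, %s) has %d < %d cells; skipped",
            patient_id, timepoint, cluster_id, n, min_cells,
        )
        return None
    X = adata_norm.X[mask]
    means = np.asarray(X.mean(axis=0)).ravel()
    return pd.Series(means, index=adata_norm.var_names, name=f"{patient_id}_{timepoint}_{cluster_id}")


def gene_logfc(
    mean_pre: pd.Series,
    mean_post: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    patient_id: str = "",
    cluster_id=None,
    gene_universe: str = "detected",
) -> ClusterLogFC:
    """Per-gene log2((m_post + c)/(m_pre + c)) between paired pseudobulk means.

    ``gene_universe='detected'`` (default) restricts to genes with nonzero
    mean in pre or post; ``'all'`` keeps every gene.
    """
    if not mean_pre.index.equals(mean_post.index):
        raise ValueError("pre and post mean vectors have misaligned gene lists")
    if gene_universe == "detected":
        used = (mean_pre > 0) | (mean_post > 0)
    elif gene_universe == "all":
        used = pd.Series(True, index=mean_pre.index)
    else:
        raise ValueError(f"unknown gene_universe {gene_universe!r}")
    pre = mean_pre[used].to_numpy(dtype=float)
    post = mean_post[used].to_numpy(dtype=float)
    lfc = np.log2((post + pseudocount) / (pre + pseudocount))
    return ClusterLogFC(
        patient_id=patient_id,
        cluster_id=cluster_id,
        logfc=pd.Series(lfc, index=mean_pre.index[used]),
        pseudocount=pseudocount,
    )


def disturbance_score(logfc: ClusterLogFC) -> DisturbanceRecord:
    """Mean of |log2FC| over the cluster's genes_used."""
    v = logfc.logfc.to_numpy(dtype=float)
    if v.size == 0:
        raise ValueError("empty logFC vector")
    return DisturbanceRecord(
        patient_id=logfc.patient_id,
        cluster_id=logfc.cluster_id,
        score=float(np.mean(np.abs(v))),
        n_genes=int(v.size),
    )


def pathway_mean_score(adata_norm: AnnData, gene_set: GeneSet) -> pd.Series:
    """Per-cell arithmetic mean of normalized expression over a gene set.

    Set genes absent from the matrix are dropped with a logged tally; it is
    an error when none are present.
    """
    present = [g for g in gene_set if g in adata_norm.var_names]
    n_absent = len(gene_set) - len(present)
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    if n_absent:
        logger.warning("set %s: %d/%d genes absent from matrix",
                       gene_set.name, n_absent, len(gene_set))
    idx = adata_norm.var_names.get_indexer(present)
    X = adata_norm.X[:, idx]
    scores = np.asarray(X.mean(axis=1)).ravel()
    return pd.Series(scores, index=adata_norm.obs_names, name=gene_set.name)


def annotate_clusters(
    adata_norm: AnnData, panel: MarkerPanel
) -> Tuple[Dict[object, str], pd.DataFrame]:
    """Assign each cluster the marker-panel label with the highest z-score.

    For every gene, the cluster-mean expression is z-scored across
    clusters; a label's score in a cluster is the mean z over that label's
    marker genes.  Each cluster takes the argmax label, ties broken by
    lexicographic label order.  Returns the assignment and the full
    cluster x label score table.
    """
    _require_meta(adata_norm)
    clusters = sorted(adata_norm.obs["cluster_id"].unique())
    if len(clusters) < 2:
        raise ValueError("cluster annotation requires >= 2 clusters")
    # cluster-mean matrix (clusters x genes)
    means = np.vstack([
        np.asarray(adata_norm.X[(adata_norm.obs["cluster_id"] == c).to_numpy()].mean(axis=0)).ravel()
        for c in clusters
    ])
    sd = means.std(axis=0, ddof=0)
    mu = means.mean(axis=0)
    nondegenerate = sd > 0
    z = np.zeros_like(means)
    z[:, nondegenerate] = (means[:, nondegenerate] - mu[nondegenerate]) / sd[nondegenerate]
    var_names = adata_norm.var_names
    scores = {}
    for label in sorted(panel.labels):
        genes = [g for g in panel[label] if g in var_names]
        if not genes:
            raise ValueError(f"no marker gene of label {label!r} present in the matrix")
        idx = var_names.get_indexer(genes)
        usable = idx[nondegenerate[idx]]
        if usable.size == 0:
            logger.warning("label %s: all markers degenerate across clusters; skipped", label)
            continue
        scores[label] = z[:, usable].mean(axis=1)
    if not scores:
        raise ValueError("every panel label was degenerate; cannot annotate")
    table = pd.DataFrame(scores, index=pd.Index(clusters, name="cluster_id"))
    # idxmax returns the first (lexicographically smallest, given sorted columns) maximum
    assignment = {c: table.loc[c].idxmax() for c in clusters}
    return assignment, table
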