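"""Linking repertoire expansion to innate activation.

Spearman rank correlation with exact small-sample inference: for n <= 9
matched patients the two-sided p-value is computed by full enumeration of
all n! rank permutations (|r_perm| >= |r_obs| counting), otherwise by the
usual t-distribution approximation with n - 2 degrees of freedom.  The
module also builds the diversity-ordered gene-panel signature matrix:
per-patient gene statistics ordered by increasing TCR diversity log2FC,
with each gene's Spearman correlation against the diversity change.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet
from .repertoire import DiversityRecord

logger = logging.getLogger(__name__)

EXACT_N_MAX = 9  # 9! = 362,880 permutations is still feasible


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str  # exact_permutation | t_approximation
    excluded: List[str] = field(default_factory=list)


@dataclass
class SignatureMatrix:
    """Genes x patients statistic matrix with patients ordered by DI logFC."""

    matrix: pd.DataFrame           # columns ordered by increasing di_logfc
    di_logfc: pd.Series            # per patient, same column order
    gene_r: pd.Series              # per-gene Spearman r against di_logfc


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p: share of the n! permutations of one
    rank vector with |r| >= |r_obs|."""
    n = rx.size
    rc = rx - rx.mean()
    denom = math.sqrt(float(np.sum(rc ** 2)) * float(np.sum((ry - ry.mean()) ** 2)))
    perms = np.array(list(itertools.permutations(ry)))
    r_all = (perms - ry.mean()) @ rc / denom
    count = int(np.sum(np.abs(r_all) >= abs(r_obs) - 1e-12))
    return count / math.factorial(n)


def spearman(x, y, method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with exact or t-approximate inference.

    r is the Pearson correlation of (average) ranks.  ``method`` is one of
    ``auto`` (exact for n <= 9), ``exact`` or ``approx``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "approx"
    if method == "exact":
        if n > EXACT_N_MAX:
            raise ValueError(f"exact enumeration limited to n <= {EXACT_N_MAX}")
        # the identity permutation always counts, so p >= 1/n!
        p = _exact_spearman_p(rx, ry, r)
        return CorrelationResult(r, min(p, 1.0), n, "exact_permutation")
    if method == "approx":
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
        return CorrelationResult(r, float(min(p, 1.0)), n, "t_approximation")
    raise ValueError(f"unknown method {method!r}")


def correlate_expansion_with_activation(
    diversity: Sequence[DiversityRecord],
    activation: Mapping[str, float],
    method: str = "auto",
) -> CorrelationResult:
    """Spearman of per-patient DI logFC against an innate-activation scalar
    (pDC proportion logFC or disturbance score), on matched patients.

    Patients missing either value are excluded and reported in the result.
    """
    div = {rec.patient_id: rec.di_logfc for rec in diversity}
    all_ids = sorted(set(div) | set(activation))
    matched = [p for p in all_ids if p in div and p in activation
               and np.isfinite(div[p]) and np.isfinite(activation[p])]
    excluded = [p for p in all_ids if p not in matched]
    if excluded:
        logger.warning("excluding %d unmatched patient(s): %s", len(excluded), excluded)
    if len(matched) < 3:
        raise ValueError(f"only {len(matched)} matched patients (< 3)")
    x = np.array([div[p] for p in matched])
    y = np.array([activation[p] for p in matched])
    res = spearman(x, y, method=method)
    res.excluded = excluded
    return res


def signature_panel(
    stat_matrix: pd.DataFrame,
    diversity: Sequence[DiversityRecord],
    panel_genes: GeneSet,
) -> SignatureMatrix:
    """Diversity-ordered signature matrix for a gene panel.

    ``stat_matrix`` is genes x patients (any per-patient gene statistic,
    e.g. cross-cluster mean post-vs-pre logFC).  Columns are reordered by
    increasing DI logFC; per-gene Spearman r against DI logFC marks genes
    tracking clonal expansion (negative r) or its absence (positive r).
    """
    div = {rec.patient_id: rec.di_logfc for rec in diversity}
    patients = [p for p in stat_matrix.columns if p in div]
    if len(patients) < 3:
        raise ValueError("fewer than 3 patients shared between matrix and diversity")
    genes = [g for g in panel_genes if g in stat_matrix.index]
    if not genes:
        raise ValueError(f"no gene of panel {panel_genes.name!r} present in the matrix")
    order = sorted(patients, key=lambda p: div[p])
    sub = stat_matrix.loc[genes, order]
    di = pd.Series([div[p] for p in order], index=order, name="di_logfc")
    di_ranks = stats.rankdata(di.to_numpy())
    r_vals = {}
    for g in genes:
        v = sub.loc[g].to_numpy(dtype=float)
        if np.all(v == v[0]):
            r_vals[g] = np.nan
        else:
            r_vals[g] = float(np.corrcoef(stats.rankdata(v), di_ranks)[0, 1])
    return SignatureMatrix(matrix=sub, di_logfc=di,
                           gene_r=pd.Series(r_vals, name="spearman_r"))
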