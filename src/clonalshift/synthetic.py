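"""Synthetic paired pre/post-treatment immune cohorts with known ground truth.

The generator emulates the statistical structure the analysis modules
assume, at desk scale:

* **Repertoires** — clone abundances follow a Zipf power law
  (p_i ~ i^-a); each sample is a multinomial read draw.  In responder
  patients the post-treatment draw reweights the top fraction of clones
  by a multiplicative expansion factor, concentrating mass into the most
  abundant clones and driving the Simpson-diversity log2FC negative.
* **Expression** — cells are assigned to clusters from a Dirichlet
  proportion prior; counts are negative-binomial around cluster-specific
  gene means built from a shared base profile plus per-cluster marker
  genes.  Responders' post samples (i) upregulate a planted
  interferon-response gene module in designated innate clusters,
  (ii) shift the pDC-like cluster's proportion, and (iii) perturb every
  gene's mean by a random log2FC of configurable scale — the source of a
  nonzero disturbance score.
* **Coupling** — one per-patient responder-strength scalar jointly scales
  the expansion factor, the pDC shift, the module effect and the
  disturbance scale, so clonal expansion and dendritic-cell activation
  co-vary across patients.  With ``couple_effects=False`` the repertoire
  and expression arms draw independent responder flags and strengths,
  giving a calibration null for the linking analysis.

One master seed; per-patient substreams are spawned from fixed
``SeedSequence`` keys so patients are independent and individually
reproducible.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from anndata import AnnData
from scipy.io import mmwrite

from .genesets import GeneSet, MarkerPanel, write_gmt
from .repertoire import ClonotypeTable, write_clonotypes

logger = logging.getLogger(__name__)

# SeedSequence spawn-key stream ids
_STREAM_GENES = 0
_STREAM_COHORT = 1
_STREAM_REPERTOIRE = 2
_STREAM_EXPRESSION = 3

_DEFAULT_LABELS = {
    0: "T_CD4", 1: "T_CD8", 2: "B_cell", 3: "NK_isg",
    4: "Mono_classical", 5: "Mono_isg", 6: "cDC", 7: "pDC",
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic paired cohort.

    Defaults describe a 12-patient cohort with 9 responders, 2,000-clone
    Zipf(1.2) repertoires sequenced to 50,000 reads, a five-fold
    expansion of the top 1% of clones in responders, and an
    8-cluster / 800-cells-per-sample / 400-gene expression layer with a
    40-gene interferon-response module planted at one log2 unit in the
    innate clusters.
    """

    n_patients: int = 12
    responder_fraction: float = 0.75
    # repertoire layer
    n_clones: int = 2000
    zipf_exponent: float = 1.2
    reads_per_sample: int = 50000
    expansion_factor: float = 5.0
    expansion_top_fraction: float = 0.01
    # expression layer
    n_clusters: int = 8
    cells_per_sample: int = 800
    n_genes: int = 400
    counts_per_cell: int = 2000
    baseline_dirichlet: Tuple[float, ...] = (88, 72, 56, 48, 40, 32, 24, 20)
    pdc_cluster_index: int = 7
    innate_cluster_indices: Tuple[int, ...] = (3, 5, 7)
    pdc_shift: float = 1.0
    t1irg_set_size: int = 40
    t1irg_effect: float = 1.0
    disturbance_sd: float = 0.7
    nb_dispersion: float = 2.0
    n_marker_genes: int = 8
    # coupling
    couple_effects: bool = True
    strength_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_patients, self.n_clones, self.n_clusters,
               self.cells_per_sample, self.n_genes, self.t1irg_set_size) <= 0:
            raise ValueError("all counts must be positive")
        if not (0 <= self.responder_fraction <= 1):
            raise ValueError("responder_fraction must lie in [0, 1]")
        if not (0 <= self.expansion_top_fraction <= 1):
            raise ValueError("expansion_top_fraction must lie in [0, 1]")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if self.zipf_exponent <= 0 or self.nb_dispersion <= 0:
            raise ValueError("zipf_exponent and nb_dispersion must be positive")
        if self.disturbance_sd < 0:
            raise ValueError("disturbance_sd must be nonnegative")
        if len(self.baseline_dirichlet) != self.n_clusters:
            raise ValueError("baseline_dirichlet length must equal n_clusters")
        if any(a <= 0 for a in self.baseline_dirichlet):
            raise ValueError("baseline_dirichlet entries must be positive")
        if not (0 <= self.pdc_cluster_index < self.n_clusters):
            raise ValueError("pdc_cluster_index out of range")
        if any(not 0 <= i < self.n_clusters for i in self.innate_cluster_indices):
            raise ValueError("innate_cluster_indices out of range")
        if self.t1irg_set_size + self.n_clusters * self.n_marker_genes > self.n_genes:
            raise ValueError("n_genes too small for markers plus interferon module")


@dataclass
class PatientTruth:
    patient_id: str
    responder: bool
    realized_expansion: float
    expression_responder: bool
    realized_pdc_shift: float
    realized_t1irg_effect: float
    realized_disturbance_sd: float


@dataclass
class CohortGroundTruth:
    patients: List[PatientTruth]
    t1irg_gene_ids: Tuple[str, ...]
    planted_cluster_labels: Dict[int, str]
    marker_panel: MarkerPanel = field(repr=False)


@dataclass
class PatientRecord:
    patient_id: str
    repertoire_pre: ClonotypeTable
    repertoire_post: ClonotypeTable
    expression_pre: AnnData
    expression_post: AnnData


def _rng(config: CohortConfig, stream: int, patient_index: int = -1) -> np.random.Generator:
    key = (stream,) if patient_index < 0 else (stream, patient_index)
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def patient_id(patient_index: int) -> str:
    return f"P{patient_index + 1:02d}"


# --------------------------------------------------------------------------
# repertoire layer
# --------------------------------------------------------------------------

_NT = np.array(list("ACGT"))
_STREAM_IDENTITY = 4


@functools.lru_cache(maxsize=64)
def _clone_identities(seed: int, patient_index: int, n_clones: int) -> tuple:
    """Deterministic (v_call, j_call, junction) per clone rank of a patient.

    Drawn from a dedicated substream keyed on (seed, patient), so identity
    i is a pure function of (seed, patient_index, i).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM_IDENTITY, patient_index)))
    v_fam = rng.integers(1, 31, size=n_clones)
    v_al = rng.integers(1, 4, size=n_clones)
    j_fam = rng.integers(1, 3, size=n_clones)
    j_al = rng.integers(1, 8, size=n_clones)
    lengths = 30 + 3 * rng.integers(0, 6, size=n_clones)  # 30..45 nt, in-frame
    codes = rng.integers(0, 4, size=(n_clones, 39))
    chars = _NT[codes]
    out = []
    for i in range(n_clones):
        core = "".join(chars[i, : lengths[i] - 6])
        out.append((
            f"TRBV{v_fam[i]}-{v_al[i]}",
            f"TRBJ{j_fam[i]}-{j_al[i]}",
            "TGT" + core + "TTT",
        ))
    return tuple(out)


def zipf_probabilities(n_clones: int, exponent: float) -> np.ndarray:
    """Zipf-law clone probabilities p_i ~ i^-a, i = 1..n_clones."""
    ranks = np.arange(1, n_clones + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def simulate_repertoire_pair(
    config: CohortConfig,
    patient_index: int,
    responder: bool,
    expansion_factor: Optional[float] = None,
    chain: str = "TRB",
) -> Tuple[ClonotypeTable, ClonotypeTable]:
    """Paired pre/post clonotype tables for one patient.

    Pre is a multinomial read draw over Zipf clone probabilities; post
    reweights the top ``ceil(expansion_top_fraction * n_clones)`` clones
    by the expansion factor in responders (then renormalizes) before
    drawing.  Clone identities are deterministic in (seed, patient, rank).
    """
    if patient_index >= config.n_patients:
        raise ValueError("patient_index out of range")
    if config.reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be positive")
    gamma = config.expansion_factor if expansion_factor is None else expansion_factor
    n_top = math.ceil(config.expansion_top_fraction * config.n_clones)
    if responder and n_top == 0:
        logger.warning("expansion_top_fraction=0: responder patient %d degenerates "
                       "to non-responder", patient_index)
        responder = False
    rng = _rng(config, _STREAM_REPERTOIRE, patient_index)
    p = zipf_probabilities(config.n_clones, config.zipf_exponent)
    pre_counts = rng.multinomial(config.reads_per_sample, p)
    if responder:
        w = p.copy()
        w[:n_top] *= gamma
        w /= w.sum()
    else:
        w = p
    post_counts = rng.multinomial(config.reads_per_sample, w)
    pid = patient_id(patient_index)
    identities = _clone_identities(config.seed, patient_index, config.n_clones)
    tables = []
    for tp, counts in (("pre", pre_counts), ("post", post_counts)):
        nz = np.nonzero(counts)[0]
        rows = [identities[int(i)] for i in nz]
        df = pd.DataFrame(rows, columns=["v_call", "j_call", "junction"])
        df["count"] = counts[nz]
        tables.append(ClonotypeTable(pid, tp, chain, df))
    return tables[0], tables[1]


# --------------------------------------------------------------------------
# expression layer
# --------------------------------------------------------------------------

@dataclass
class _GeneModel:
    genes: List[str]
    weights: np.ndarray            # clusters x genes, rows sum to 1
    t1irg_genes: Tuple[str, ...]
    t1irg_idx: np.ndarray
    marker_panel: MarkerPanel
    cluster_labels: Dict[int, str]


def _gene_model(config: CohortConfig) -> _GeneModel:
    """Cohort-level gene structure: base profile, markers, interferon module."""
    rng = _rng(config, _STREAM_GENES)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    base = rng.gamma(0.5, 1.0, size=config.n_genes) + 1e-3
    order = rng.permutation(config.n_genes)
    labels = {
        k: _DEFAULT_LABELS.get(k, f"C{k}") if config.n_clusters == 8 else f"C{k}"
        for k in range(config.n_clusters)
    }
    if config.n_clusters == 8:
        labels[config.pdc_cluster_index] = "pDC"
    weights = np.tile(base, (config.n_clusters, 1))
    panel_sets = {}
    pos = 0
    for k in range(config.n_clusters):
        idx = order[pos:pos + config.n_marker_genes]
        pos += config.n_marker_genes
        weights[k, idx] *= 8.0
        panel_sets[labels[k]] = GeneSet(labels[k], tuple(genes[i] for i in idx))
    t1_idx = np.sort(order[pos:pos + config.t1irg_set_size])
    # give the module a solid baseline so its upregulation is detectable
    weights[:, t1_idx] = np.maximum(weights[:, t1_idx], 0.2)
    weights /= weights.sum(axis=1, keepdims=True)
    return _GeneModel(
        genes=genes,
        weights=weights,
        t1irg_genes=tuple(genes[i] for i in t1_idx),
        t1irg_idx=t1_idx,
        marker_panel=MarkerPanel(panel_sets),
        cluster_labels=labels,
    )


def t1irg_gene_set(config: CohortConfig) -> GeneSet:
    """The planted interferon-response gene module as a GeneSet."""
    return GeneSet("T1IRG_module", _gene_model(config).t1irg_genes)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts (var = mu + mu^2/theta) drawn as the
    equivalent gamma-Poisson mixture, which vectorizes better."""
    lam = rng.gamma(dispersion, np.asarray(mean) / dispersion)
    return rng.poisson(lam)


def _sample_cells(rng, config, model, props, weight_matrix, pid, timepoint):
    """Draw one sample's cells: cluster assignment + NB counts -> AnnData."""
    n_per_cluster = rng.multinomial(config.cells_per_sample, props)
    blocks, cluster_col = [], []
    for k, n_k in enumerate(n_per_cluster):
        if n_k == 0:
            continue
        mu = config.counts_per_cell * weight_matrix[k]
        blocks.append(_nb_draw(rng, np.broadcast_to(mu, (n_k, config.n_genes)),
                               config.nb_dispersion))
        cluster_col.extend([k] * n_k)
    X = sp.csr_matrix(np.vstack(blocks))
    obs = pd.DataFrame({
        "patient_id": pid,
        "timepoint": timepoint,
        "cluster_id": pd.array(cluster_col, dtype=int),
    })
    obs.index = [f"{pid}_{timepoint}_{i}" for i in range(len(obs))]
    var = pd.DataFrame(index=pd.Index(model.genes, name="gene_id"))
    return AnnData(X=X, obs=obs, var=var)


def simulate_expression_pair(
    config: CohortConfig,
    patient_index: int,
    responder: bool,
    pdc_shift: Optional[float] = None,
    t1irg_effect: Optional[float] = None,
    disturbance_sd: Optional[float] = None,
) -> Tuple[AnnData, AnnData]:
    """Paired pre/post cell-by-gene count matrices for one patient.

    Cell metadata (patient_id, timepoint, cluster_id) rides along in
    ``.obs``.  Responder post samples shift the pDC-like cluster's
    proportion by ``2**pdc_shift``, multiply the interferon-module means
    in innate clusters by ``2**t1irg_effect``, and jitter every gene's
    mean by a random per-gene log2FC of scale ``disturbance_sd``.
    """
    if config.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if config.cells_per_sample < config.n_clusters:
        raise ValueError("cells_per_sample must be >= n_clusters")
    shift = config.pdc_shift if pdc_shift is None else pdc_shift
    effect = config.t1irg_effect if t1irg_effect is None else t1irg_effect
    dist_sd = config.disturbance_sd if disturbance_sd is None else disturbance_sd
    model = _gene_model(config)
    rng = _rng(config, _STREAM_EXPRESSION, patient_index)
    pid = patient_id(patient_index)
    baseline = rng.dirichlet(np.asarray(config.baseline_dirichlet, dtype=float))
    pre = _sample_cells(rng, config, model, baseline, model.weights, pid, "pre")
    if responder:
        props_post = baseline.copy()
        props_post[config.pdc_cluster_index] *= 2.0 ** shift
        props_post /= props_post.sum()
        w_post = model.weights.copy()
        for k in config.innate_cluster_indices:
            w_post[k, model.t1irg_idx] *= 2.0 ** effect
        if dist_sd > 0:
            delta = rng.normal(0.0, dist_sd, size=config.n_genes)
            w_post *= 2.0 ** delta
    else:
        props_post = baseline
        w_post = model.weights
    post = _sample_cells(rng, config, model, props_post, w_post, pid, "post")
    return pre, post


# --------------------------------------------------------------------------
# whole cohort
# --------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> Tuple[List[PatientRecord], CohortGroundTruth]:
    """A full paired cohort plus its planted ground truth.

    ``ceil(responder_fraction * n_patients)`` patients are responders.
    Per-patient responder strengths are drawn with narrow jitter around 1
    and jointly scale the expansion factor, pDC shift, interferon-module
    effect and disturbance scale (unless ``couple_effects=False``, in
    which case the repertoire and expression arms are independent).
    """
    rng = _rng(config, _STREAM_COHORT)
    n = config.n_patients
    k = math.ceil(config.responder_fraction * n)
    rep_flags = np.zeros(n, dtype=bool)
    rep_flags[rng.choice(n, size=k, replace=False)] = True

    def strengths(flags):
        s = np.clip(rng.normal(1.0, config.strength_jitter, size=n), 0.25, 2.0)
        return np.where(flags, s, 0.0)

    s_rep = strengths(rep_flags)
    if config.couple_effects:
        expr_flags, s_expr = rep_flags, s_rep
    else:
        expr_flags = np.zeros(n, dtype=bool)
        expr_flags[rng.choice(n, size=k, replace=False)] = True
        s_expr = strengths(expr_flags)

    model = _gene_model(config)
    records, truths = [], []
    for i in range(n):
        gamma_i = 1.0 + (config.expansion_factor - 1.0) * s_rep[i]
        shift_i = config.pdc_shift * s_expr[i]
        effect_i = config.t1irg_effect * s_expr[i]
        sd_i = config.disturbance_sd * s_expr[i]
        rep_pre, rep_post = simulate_repertoire_pair(
            config, i, bool(rep_flags[i]), expansion_factor=gamma_i)
        exp_pre, exp_post = simulate_expression_pair(
            config, i, bool(expr_flags[i]), pdc_shift=shift_i,
            t1irg_effect=effect_i, disturbance_sd=sd_i)
        records.append(PatientRecord(patient_id(i), rep_pre, rep_post, exp_pre, exp_post))
        truths.append(PatientTruth(
            patient_id=patient_id(i),
            responder=bool(rep_flags[i]),
            realized_expansion=float(gamma_i),
            expression_responder=bool(expr_flags[i]),
            realized_pdc_shift=float(shift_i),
            realized_t1irg_effect=float(effect_i),
            realized_disturbance_sd=float(sd_i),
        ))
    truth = CohortGroundTruth(
        patients=truths,
        t1irg_gene_ids=model.t1irg_genes,
        planted_cluster_labels=model.cluster_labels,
        marker_panel=model.marker_panel,
    )
    return records, truth


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def config_to_dict(config: CohortConfig) -> dict:
    """Config as a plain-YAML-serializable dict (tuples become lists)."""
    d = asdict(config)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    for key in ("baseline_dirichlet", "innate_cluster_indices"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return CohortConfig(**d)

def write_cohort(records: Sequence[PatientRecord], truth: CohortGroundTruth,
                 config: CohortConfig, outdir) -> Dict[str, Path]:
    """Write a cohort to disk: AIRR TSV repertoires, one combined MTX
    expression matrix with genes/cells sidecars, metadata TSV, ground
    truth TSV, gene sets as GMT and the config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    rep_dir = outdir / "repertoires"
    rep_dir.mkdir(exist_ok=True)
    for rec in records:
        for table in (rec.repertoire_pre, rec.repertoire_post):
            p = rep_dir / f"{table.patient_id}_{table.timepoint}_{table.chain}.airr.tsv"
            write_clonotypes(table, p)
            paths[f"repertoire/{p.name}"] = p
    import anndata as ad
    adatas = []
    for rec in records:
        adatas.append(rec.expression_pre)
        adatas.append(rec.expression_post)
    combined = ad.concat(adatas, join="outer", merge="same")
    mtx_path = outdir / "matrix.mtx"
    mmwrite(str(mtx_path), sp.csr_matrix(combined.X).astype(int))
    pd.Series(combined.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                         index=False, header=False)
    pd.Series(combined.obs_names).to_csv(outdir / "cells.tsv", sep="\t",
                                         index=False, header=False)
    meta = combined.obs.reset_index(names="cell_id")
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame([asdict(t) for t in truth.patients])
    truth_df.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    sets = [GeneSet("T1IRG_module", truth.t1irg_gene_ids)]
    write_gmt(sets, outdir / "gene_sets.gmt")
    write_gmt([gs for _, gs in sorted(truth.marker_panel.items())],
              outdir / "marker_panel.gmt")
    with open(outdir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    for name in ("matrix.mtx", "genes.tsv", "cells.tsv", "metadata.tsv",
                 "ground_truth.tsv", "gene_sets.gmt", "marker_panel.gmt",
                 "cohort_config.yaml"):
        paths[name] = outdir / name
    return paths


def read_expression_mtx(mtx_path, genes_path, cells_path, metadata_path) -> AnnData:
    """Load a Matrix-Market cell-by-gene matrix with sidecars into AnnData."""
    from scipy.io import mmread
    X = sp.csr_matrix(mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str)
    if X.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {X.shape} does not match {len(cells)} cells x {len(genes)} genes")
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("cell_id", "patient_id", "timepoint", "cluster_id"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    meta = meta.set_index("cell_id")
    missing = [c for c in cells if c not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} cells lack metadata rows (e.g. {missing[0]})")
    obs = meta.loc[cells, ["patient_id", "timepoint", "cluster_id"]]
    obs.index.name = None
    return AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
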