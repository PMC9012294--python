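"""End-to-end orchestration of the paired-cohort analysis.

``run_cohort_analysis`` simulates or ingests a cohort, then runs the
repertoire, expression, enrichment and linking stages in order and writes
a reproducible report bundle: tidy TSV tables plus a JSON manifest
recording every resolved parameter and the SHA-256 of every file.  In
simulate mode the bundle is byte-identical across runs for one seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import expression as expr
from . import linking
from . import repertoire as rep
from .enrichment import preranked_gsea, rank_by_logfc
from .genesets import GeneSet, read_gmt
from .synthetic import (
    CohortConfig,
    PatientRecord,
    config_from_dict,
    config_to_dict,
    read_expression_mtx,
    simulate_cohort,
    t1irg_gene_set,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one end-to-end run."""

    mode: str = "simulate"                     # simulate | files
    cohort: CohortConfig = field(default_factory=CohortConfig)
    paths: Dict[str, str] = field(default_factory=dict)
    outdir: str = "report"
    # analysis parameters
    di_variant: str = "gini_simpson"
    epsilon: float = rep.DEFAULT_EPSILON
    n_top: int = 200
    pseudocount: float = expr.DEFAULT_PSEUDOCOUNT
    min_cells: int = expr.DEFAULT_MIN_CELLS
    gene_universe: str = "detected"
    gsea_n_perm: int = 200
    gsea_weight_p: float = 1.0
    correlation_method: str = "auto"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = config_to_dict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = config_from_dict(d["cohort"])
        return cls(**d)


@dataclass
class ReportBundle:
    outdir: Path
    diversity: pd.DataFrame
    expansion: pd.DataFrame
    proportions: pd.DataFrame
    proportion_logfc: pd.DataFrame
    disturbance: pd.DataFrame
    pathway_scores: Optional[pd.DataFrame]
    enrichment: Optional[pd.DataFrame]
    correlations: pd.DataFrame
    signature: Optional[pd.DataFrame]
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _CohortInputs:
    """Paired per-patient inputs, whatever their origin."""

    def __init__(self):
        self.repertoires: Dict[str, Dict[str, rep.ClonotypeTable]] = {}
        self.adata = None           # combined counts AnnData
        self.gene_sets: List[GeneSet] = []
        self.panel_sets: List[GeneSet] = []

    @property
    def paired_repertoire_patients(self) -> List[str]:
        return sorted(p for p, d in self.repertoires.items()
                      if "pre" in d and "post" in d)

    @property
    def paired_expression_patients(self) -> List[str]:
        if self.adata is None:
            return []
        obs = self.adata.obs
        out = []
        for p in sorted(obs["patient_id"].unique()):
            tps = set(obs.loc[obs["patient_id"] == p, "timepoint"])
            if {"pre", "post"} <= tps:
                out.append(p)
        return out


def _inputs_from_simulation(config: RunConfig) -> _CohortInputs:
    import anndata as ad

    records, truth = simulate_cohort(config.cohort)
    inputs = _CohortInputs()
    for r in records:
        inputs.repertoires[r.patient_id] = {
            "pre": r.repertoire_pre, "post": r.repertoire_post}
    adatas = []
    for r in records:
        adatas.extend([r.expression_pre, r.expression_post])
    inputs.adata = ad.concat(adatas, join="outer", merge="same")
    inputs.gene_sets = [t1irg_gene_set(config.cohort)]
    inputs.panel_sets = [gs for _, gs in sorted(truth.marker_panel.items())]
    return inputs


def _inputs_from_files(config: RunConfig) -> _CohortInputs:
    paths = config.paths
    inputs = _CohortInputs()
    for spec_ in paths.get("repertoires", []):
        pid, tp = spec_["patient_id"], spec_["timepoint"]
        chain = spec_.get("chain", "TRB")
        table = rep.read_clonotypes(spec_["path"], pid, tp, chain)
        inputs.repertoires.setdefault(pid, {})[tp] = table
    for key in ("mtx", "genes", "cells", "metadata"):
        if key not in paths:
            raise ValueError(f"files mode requires path {key!r}")
    inputs.adata = read_expression_mtx(
        paths["mtx"], paths["genes"], paths["cells"], paths["metadata"])
    if "gene_sets" in paths:
        inputs.gene_sets = read_gmt(paths["gene_sets"])
    if "marker_panel" in paths:
        inputs.panel_sets = read_gmt(paths["marker_panel"])
    return inputs


def run_cohort_analysis(config: RunConfig) -> ReportBundle:
    """Run every analysis stage on a simulated or file-based cohort and
    write the report bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.mode == "simulate":
        inputs = _inputs_from_simulation(config)
    elif config.mode == "files":
        inputs = _inputs_from_files(config)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # ---- repertoire stage -------------------------------------------------
    rep_patients = inputs.paired_repertoire_patients
    unpaired = sorted(set(inputs.repertoires) - set(rep_patients))
    if unpaired:
        logger.warning("excluding unpaired repertoire patient(s): %s", unpaired)
    if not rep_patients:
        raise ValueError("no patient has both pre and post repertoires")
    div_records, div_rows, exp_rows = [], [], []
    for pid in rep_patients:
        pre = inputs.repertoires[pid]["pre"]
        post = inputs.repertoires[pid]["post"]
        record = rep.di_logfc(pre, post, variant=config.di_variant,
                              epsilon=config.epsilon)
        div_records.append(record)
        div_rows.append({
            "patient_id": pid, "chain": record.chain,
            "di_pre": record.di_pre, "di_post": record.di_post,
            "di_logfc": record.di_logfc, "variant": record.variant,
            "expansion": record.expansion,
        })
        profile = rep.top_clone_mass(pre, post, n_top=config.n_top)
        for rank, (_, row) in enumerate(profile.per_clone.iterrows(), 1):
            exp_rows.append({
                "patient_id": pid, "rank": rank, "v_call": row["v_call"],
                "j_call": row["j_call"], "junction": row["junction"],
                "p_pre": row["p_pre"], "p_post": row["p_post"],
            })
        exp_rows.append({
            "patient_id": pid, "rank": 0, "v_call": "TOTAL", "j_call": "",
            "junction": "", "p_pre": profile.mass_pre, "p_post": profile.mass_post,
        })
    diversity = pd.DataFrame(div_rows)
    expansion = pd.DataFrame(exp_rows)

    # ---- expression stage -------------------------------------------------
    adata = inputs.adata
    norm = expr.normalize_cp10k_log(adata)
    clusters = sorted(adata.obs["cluster_id"].unique())
    expr_patients = inputs.paired_expression_patients
    if not expr_patients:
        raise ValueError("no patient has both pre and post expression samples")
    prop_rows, plfc_rows, dist_rows = [], [], []
    logfc_by_patient_cluster: Dict[tuple, expr.ClusterLogFC] = {}
    for pid in expr_patients:
        counts = {tp: expr.cluster_cell_counts(adata.obs, pid, tp, clusters)
                  for tp in ("pre", "post")}
        for tp in ("pre", "post"):
            p = counts[tp] / counts[tp].sum()
            for c in clusters:
                prop_rows.append({"patient_id": pid, "timepoint": tp,
                                  "cluster_id": c, "proportion": p[c]})
        lfc = expr.proportion_logfc(counts["pre"].to_numpy(),
                                    counts["post"].to_numpy(), len(clusters))
        for c, v in zip(clusters, lfc):
            plfc_rows.append({"patient_id": pid, "cluster_id": c,
                              "proportion_logfc": v})
        for c in clusters:
            m_pre = expr.pseudobulk_mean(norm, pid, "pre", c, config.min_cells)
            m_post = expr.pseudobulk_mean(norm, pid, "post", c, config.min_cells)
            if m_pre is None or m_post is None:
                dist_rows.append({"patient_id": pid, "cluster_id": c,
                                  "n_genes": 0, "disturbance": np.nan,
                                  "status": "missing"})
                continue
            clfc = expr.gene_logfc(m_pre, m_post, config.pseudocount,
                                   patient_id=pid, cluster_id=c,
                                   gene_universe=config.gene_universe)
            logfc_by_patient_cluster[(pid, c)] = clfc
            score = expr.disturbance_score(clfc)
            dist_rows.append({"patient_id": pid, "cluster_id": c,
                              "n_genes": score.n_genes,
                              "disturbance": score.score, "status": "ok"})
    proportions = pd.DataFrame(prop_rows)
    proportion_lfc = pd.DataFrame(plfc_rows)
    disturbance = pd.DataFrame(dist_rows)

    # pathway survey over supplied gene sets
    pathway_scores = None
    if inputs.gene_sets:
        path_rows = []
        for gs in inputs.gene_sets:
            scores = expr.pathway_mean_score(norm, gs)
            df = norm.obs[["patient_id", "timepoint", "cluster_id"]].copy()
            df["score"] = scores.to_numpy()
            summary = (df.groupby(["patient_id", "timepoint", "cluster_id"],
                                  observed=True)["score"]
                       .mean().reset_index())
            summary.insert(0, "gene_set", gs.name)
            path_rows.append(summary)
        pathway_scores = pd.concat(path_rows, ignore_index=True)

    # ---- enrichment stage -------------------------------------------------
    enrichment_df = None
    if inputs.gene_sets:
        gsea_rows = []
        for c in clusters:
            per_patient = [logfc_by_patient_cluster[(p, c)].logfc
                           for p in expr_patients
                           if (p, c) in logfc_by_patient_cluster]
            if not per_patient:
                continue
            mean_lfc = pd.concat(per_patient, axis=1).mean(axis=1).dropna()
            if mean_lfc.empty:
                continue
            ranked = rank_by_logfc(mean_lfc)
            try:
                results = preranked_gsea(
                    ranked, inputs.gene_sets, n_perm=config.gsea_n_perm,
                    seed=config.cohort.seed, weight_p=config.gsea_weight_p)
            except ValueError as e:
                logger.warning("GSEA skipped for cluster %s: %s", c, e)
                continue
            for r in results:
                gsea_rows.append({"cluster_id": c, "gene_set": r.set_name,
                                  "es": r.es, "nes": r.nes, "p_value": r.p_value,
                                  "fdr": r.fdr, "n_hits": r.n_hits})
        if gsea_rows:
            enrichment_df = pd.DataFrame(gsea_rows)

    # ---- linking stage ----------------------------------------------------
    pdc_idx = (config.cohort.pdc_cluster_index
               if config.mode == "simulate" else config.paths.get("pdc_cluster"))
    corr_rows = []
    matched_div = [r for r in div_records if r.patient_id in expr_patients]
    if pdc_idx is not None and pdc_idx in clusters:
        pdc_prop = {row["patient_id"]: row["proportion_logfc"]
                    for _, row in proportion_lfc.iterrows()
                    if row["cluster_id"] == pdc_idx}
        ok_dist = disturbance[(disturbance["cluster_id"] == pdc_idx)
                              & (disturbance["status"] == "ok")]
        pdc_dist = dict(zip(ok_dist["patient_id"], ok_dist["disturbance"]))
        for name, activation in (("pdc_proportion_logfc", pdc_prop),
                                 ("pdc_disturbance", pdc_dist)):
            try:
                res = linking.correlate_expansion_with_activation(
                    matched_div, activation, method=config.correlation_method)
                corr_rows.append({"activation": name, "r": res.r,
                                  "p_value": res.p_value, "n": res.n,
                                  "method": res.method,
                                  "excluded": ";".join(res.excluded)})
            except ValueError as e:
                logger.warning("correlation %s skipped: %s", name, e)
    correlations = pd.DataFrame(corr_rows)

    signature_df = None
    if inputs.panel_sets:
        # per-patient statistic: cross-cluster mean gene logFC
        stat = {}
        for pid in expr_patients:
            vecs = [logfc_by_patient_cluster[(pid, c)].logfc for c in clusters
                    if (pid, c) in logfc_by_patient_cluster]
            if vecs:
                stat[pid] = pd.concat(vecs, axis=1).mean(axis=1)
        if stat:
            stat_matrix = pd.DataFrame(stat)
            panel_union = GeneSet(
                "panel", tuple(g for gs in inputs.panel_sets for g in gs))
            try:
                sig = linking.signature_panel(stat_matrix, div_records, panel_union)
                signature_df = sig.matrix.copy()
                signature_df.insert(0, "spearman_r", sig.gene_r)
                signature_df.index.name = "gene_id"
                signature_df = signature_df.reset_index()
            except ValueError as e:
                logger.warning("signature panel skipped: %s", e)

    # ---- write bundle -----------------------------------------------------
    tables = {
        "diversity.tsv": diversity,
        "expansion_profiles.tsv": expansion,
        "cluster_proportions.tsv": proportions,
        "proportion_logfc.tsv": proportion_lfc,
        "disturbance.tsv": disturbance,
        "pathway_scores.tsv": pathway_scores,
        "enrichment.tsv": enrichment_df,
        "correlations.tsv": correlations,
        "signature_matrix.tsv": signature_df,
    }
    files = {}
    sections = {}
    for name, df in tables.items():
        if df is None or df.empty:
            sections[name] = "absent"
            continue
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        files[name] = path
        sections[name] = "present"
    manifest = {
        "package": "clonalshift",
        "version": __version__,
        "config": config.to_dict(),
        "sections": sections,
        "files": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ReportBundle(
        outdir=outdir, diversity=diversity, expansion=expansion,
        proportions=proportions, proportion_logfc=proportion_lfc,
        disturbance=disturbance, pathway_scores=pathway_scores,
        enrichment=enrichment_df, correlations=correlations,
        signature=signature_df, manifest=manifest,
    )
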