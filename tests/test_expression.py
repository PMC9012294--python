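"""Normalization, cluster proportions, pseudobulk logFC, disturbance,
pathway scores and marker-based cluster annotation."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from clonalshift import expression as expr
from clonalshift.genesets import GeneSet, panel_from_sets


def dense(adata):
    return np.asarray(adata.X.todense() if sp.issparse(adata.X) else adata.X)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_zero_count_stays_zero(self, small_adata):
        norm = expr.normalize_cp10k_log(small_adata)
        raw = dense(small_adata)
        out = dense(norm)
        assert np.all(out[raw == 0] == 0.0)

    def test_direct_arithmetic(self):
        X = sp.csr_matrix(np.array([[10, 9990]]))
        ad = AnnData(X=X, obs=pd.DataFrame(index=["c0"]),
                     var=pd.DataFrame(index=["g1", "g2"]))
        out = dense(expr.normalize_cp10k_log(ad))
        assert out[0, 0] == pytest.approx(math.log(11), abs=1e-12)

    def test_scale_invariance_per_cell(self, small_adata):
        doubled = small_adata.copy()
        doubled.X = small_adata.X * 2
        a = dense(expr.normalize_cp10k_log(small_adata))
        b = dense(expr.normalize_cp10k_log(doubled))
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_cells_dropped(self, small_adata):
        X = dense(small_adata)
        X[1] = 0
        ad = AnnData(X=sp.csr_matrix(X), obs=small_adata.obs.copy(),
                     var=small_adata.var.copy())
        out = expr.normalize_cp10k_log(ad)
        assert out.n_obs == small_adata.n_obs - 1

    def test_all_zero_matrix_errors(self, small_adata):
        ad = AnnData(X=sp.csr_matrix(np.zeros((3, 4))),
                     obs=pd.DataFrame(index=list("abc")),
                     var=small_adata.var.copy())
        with pytest.raises(ValueError):
            expr.normalize_cp10k_log(ad)

    def test_matches_scanpy(self, small_adata):
        import scanpy as sc
        ours = dense(expr.normalize_cp10k_log(small_adata))
        ref = small_adata.copy()
        sc.pp.normalize_total(ref, target_sum=1e4)
        sc.pp.log1p(ref)
        assert np.allclose(ours, dense(ref), atol=1e-10)


# ---------------------------------------------------------------------------
# cluster proportions and their logFC
# ---------------------------------------------------------------------------

class TestProportions:
    def test_direct_counting(self):
        meta = pd.DataFrame({
            "patient_id": ["P01"] * 6,
            "timepoint": ["pre"] * 6,
            "cluster_id": [0, 0, 0, 1, 1, 2],
        })
        p = expr.cluster_proportions(meta, "P01", "pre")
        assert np.allclose(p.to_numpy(), [0.5, 1 / 3, 1 / 6])
        assert p.sum() == pytest.approx(1.0)

    def test_all_in_one_cluster(self):
        meta = pd.DataFrame({"patient_id": ["P01"] * 3, "timepoint": ["pre"] * 3,
                             "cluster_id": [2] * 3})
        p = expr.cluster_proportions(meta, "P01", "pre", clusters=[0, 1, 2])
        assert p.tolist() == [0.0, 0.0, 1.0]

    def test_unknown_sample_errors(self):
        meta = pd.DataFrame({"patient_id": ["P01"], "timepoint": ["pre"],
                             "cluster_id": [0]})
        with pytest.raises(ValueError):
            expr.cluster_proportions(meta, "P01", "post")

    def test_logfc_identical_counts_zero(self):
        lfc = expr.proportion_logfc([10, 20, 5], [10, 20, 5])
        assert np.allclose(lfc, 0.0)

    def test_logfc_direct_arithmetic(self):
        lfc = expr.proportion_logfc([10, 90], [40, 160], 2)
        expected = math.log2((40.5 / 201) / (10.5 / 101))
        assert lfc[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.954, abs=1e-3)

    def test_cluster_absent_both_gives_zero(self):
        # the continuity correction cancels exactly when sample totals match
        lfc = expr.proportion_logfc([0, 50], [0, 50], 2)
        assert lfc[0] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 40, size=6)
        b = rng.integers(0, 40, size=6)
        assert np.allclose(expr.proportion_logfc(a, b),
                           -expr.proportion_logfc(b, a), atol=1e-12)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            expr.proportion_logfc([-1, 2], [1, 2])


# ---------------------------------------------------------------------------
# pseudobulk, gene logFC, disturbance
# ---------------------------------------------------------------------------

class TestPseudobulk:
    def test_mean_matches_direct_recomputation(self, small_adata):
        norm = expr.normalize_cp10k_log(small_adata)
        m = expr.pseudobulk_mean(norm, "P01", "post", 1, min_cells=2)
        raw = dense(norm)
        expected = raw[[4, 5]].mean(axis=0)
        assert np.allclose(m.to_numpy(), expected, atol=1e-12)

    def test_small_stratum_is_missing(self, small_adata):
        norm = expr.normalize_cp10k_log(small_adata)
        assert expr.pseudobulk_mean(norm, "P01", "post", 0, min_cells=3) is None


class TestGeneLogfc:
    def setup_method(self):
        self.idx = pd.Index(["g1", "g2", "g3"])

    def test_equal_means_give_zero(self):
        m = pd.Series([1.0, 2.0, 0.5], index=self.idx)
        lfc = expr.gene_logfc(m, m.copy())
        assert np.allclose(lfc.logfc.to_numpy(), 0.0)

    def test_direct_arithmetic(self):
        pre = pd.Series([1.0, 0.0, 0.0], index=self.idx)
        post = pd.Series([2.0, 0.0, 1.0], index=self.idx)
        lfc = expr.gene_logfc(pre, post, pseudocount=0.01)
        assert lfc.logfc["g1"] == pytest.approx(math.log2(2.01 / 1.01), abs=1e-12)
        assert lfc.logfc["g1"] == pytest.approx(0.9928, abs=1e-4)

    def test_undetected_gene_excluded(self):
        pre = pd.Series([1.0, 0.0, 0.0], index=self.idx)
        post = pd.Series([2.0, 0.0, 1.0], index=self.idx)
        lfc = expr.gene_logfc(pre, post)
        assert list(lfc.genes_used) == ["g1", "g3"]
        lfc_all = expr.gene_logfc(pre, post, gene_universe="all")
        assert list(lfc_all.genes_used) == ["g1", "g2", "g3"]

    def test_misaligned_genes_error(self):
        pre = pd.Series([1.0], index=pd.Index(["g1"]))
        post = pd.Series([1.0], index=pd.Index(["g2"]))
        with pytest.raises(ValueError):
            expr.gene_logfc(pre, post)


class TestDisturbance:
    def _clfc(self, values):
        return expr.ClusterLogFC("P01", 0, pd.Series(
            values, index=[f"g{i}" for i in range(len(values))]))

    def test_zero_vector(self):
        assert expr.disturbance_score(self._clfc([0.0, 0.0])).score == 0.0

    def test_direct_arithmetic(self):
        assert expr.disturbance_score(
            self._clfc([1.0, -1.0, 0.0])).score == pytest.approx(2 / 3)

    def test_homogeneity(self):
        v = [0.2, -1.3, 0.7]
        base = expr.disturbance_score(self._clfc(v)).score
        scaled = expr.disturbance_score(self._clfc([-2.5 * x for x in v])).score
        assert scaled == pytest.approx(2.5 * base)

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            expr.disturbance_score(self._clfc([]))

    def test_zero_iff_identical_means(self, small_adata):
        norm = expr.normalize_cp10k_log(small_adata)
        m = expr.pseudobulk_mean(norm, "P01", "pre", 0, min_cells=1)
        lfc = expr.gene_logfc(m, m.copy())
        assert expr.disturbance_score(lfc).score == 0.0


# ---------------------------------------------------------------------------
# pathway scores and annotation
# ---------------------------------------------------------------------------

class TestPathwayScore:
    def test_full_set_equals_cell_mean(self, small_adata):
        norm = expr.normalize_cp10k_log(small_adata)
        gs = GeneSet("all", tuple(norm.var_names))
        s = expr.pathway_mean_score(norm, gs)
        assert np.allclose(s.to_numpy(), dense(norm).mean(axis=1), atol=1e-12)

    def test_zero_count_cell_scores_zero(self, small_adata):
        norm = expr.normalize_cp10k_log(small_adata)
        # cell c1 has zero counts in g3 and g4
        gs = GeneSet("pair", ("g3", "g4"))
        s = expr.pathway_mean_score(norm, gs)
        assert s["c1"] == 0.0

    def test_matches_direct_recomputation(self, small_adata):
        norm = expr.normalize_cp10k_log(small_adata)
        gs = GeneSet("two", ("g1", "g4", "absent_gene"))
        s = expr.pathway_mean_score(norm, gs)
        raw = dense(norm)
        expected = raw[:, [0, 3]].mean(axis=1)
        assert np.allclose(s.to_numpy(), expected, atol=1e-12)

    def test_all_absent_errors(self, small_adata):
        norm = expr.normalize_cp10k_log(small_adata)
        with pytest.raises(ValueError):
            expr.pathway_mean_score(norm, GeneSet("none", ("nope",)))


class TestAnnotateClusters:
    def _adata(self):
        # 3 clusters, each expressing exactly its own marker gene
        X = np.zeros((9, 3))
        clusters = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        for i, c in enumerate(clusters):
            X[i, c] = 50
            X[i, (c + 1) % 3] = 1  # keep cell totals nonzero everywhere
        obs = pd.DataFrame({"patient_id": "P01", "timepoint": "pre",
                            "cluster_id": clusters},
                           index=[f"c{i}" for i in range(9)])
        var = pd.DataFrame(index=pd.Index(["m0", "m1", "m2"], name="gene_id"))
        return AnnData(X=sp.csr_matrix(X), obs=obs, var=var)

    def test_perfect_assignment(self):
        norm = expr.normalize_cp10k_log(self._adata())
        panel = panel_from_sets({"alpha": ["m0"], "beta": ["m1"], "gamma": ["m2"]})
        assignment, table = expr.annotate_clusters(norm, panel)
        assert assignment == {0: "alpha", 1: "beta", 2: "gamma"}
        assert set(table.columns) == {"alpha", "beta", "gamma"}

    def test_tie_broken_lexicographically(self):
        norm = expr.normalize_cp10k_log(self._adata())
        panel = panel_from_sets({"zeta": ["m0"], "alpha": ["m0"]})
        assignment, _ = expr.annotate_clusters(norm, panel)
        assert assignment[0] == "alpha"

    def test_absent_panel_set_errors(self):
        norm = expr.normalize_cp10k_log(self._adata())
        panel = panel_from_sets({"alpha": ["nope"]})
        with pytest.raises(ValueError):
            expr.annotate_clusters(norm, panel)


# ---------------------------------------------------------------------------
# oracle equivalence on a random dense fixture
# ---------------------------------------------------------------------------

def test_oracle_equivalence_random_fixtures():
    """All expression statistics match dense-arithmetic recomputation."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        n_cells = int(rng.integers(6, 30))
        n_genes = int(rng.integers(3, 15))
        X = rng.poisson(2.0, size=(n_cells, n_genes))
        X[rng.integers(n_cells)] += 1  # avoid all-zero matrix edge
        obs = pd.DataFrame({
            "patient_id": "P01",
            "timepoint": rng.choice(["pre", "post"], size=n_cells),
            "cluster_id": rng.integers(0, 3, size=n_cells),
        }, index=[f"c{i}" for i in range(n_cells)])
        var = pd.DataFrame(index=pd.Index([f"g{j}" for j in range(n_genes)]))
        ad = AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
        norm = expr.normalize_cp10k_log(ad)
        totals = X.sum(axis=1)
        kept = totals > 0
        ref = np.log1p(1e4 * X[kept] / totals[kept, None])
        assert np.allclose(dense(norm), ref, atol=1e-10)
        # pseudobulk + logFC + disturbance for one stratum pair
        obs_k = norm.obs
        pre_mask = ((obs_k["timepoint"] == "pre") & (obs_k["cluster_id"] == 0)).to_numpy()
        post_mask = ((obs_k["timepoint"] == "post") & (obs_k["cluster_id"] == 0)).to_numpy()
        if pre_mask.sum() >= 1 and post_mask.sum() >= 1:
            m_pre = expr.pseudobulk_mean(norm, "P01", "pre", 0, min_cells=1)
            m_post = expr.pseudobulk_mean(norm, "P01", "post", 0, min_cells=1)
            ref_pre = dense(norm)[pre_mask].mean(axis=0)
            ref_post = dense(norm)[post_mask].mean(axis=0)
            assert np.allclose(m_pre.to_numpy(), ref_pre, atol=1e-10)
            used = (ref_pre > 0) | (ref_post > 0)
            if used.any():
                lfc = expr.gene_logfc(m_pre, m_post)
                ref_lfc = np.log2((ref_post[used] + 0.01) / (ref_pre[used] + 0.01))
                assert np.allclose(lfc.logfc.to_numpy(), ref_lfc, atol=1e-10)
                assert expr.disturbance_score(lfc).score == pytest.approx(
                    np.mean(np.abs(ref_lfc)), abs=1e-10)
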