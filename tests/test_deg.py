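"""Differential expression, DEG clustering and scoring."""

import numpy as np
import pandas as pd
import pytest

from binsig import deg, sc, synth
from binsig.errors import AnalysisError
from conftest import make_adata


def brute_force_bh(pvals):
    """Textbook Benjamini-Hochberg: monotonized p * m / rank."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adj[i] = running_min
    return adj


def _two_group_adata(values_a, values_b, genes=None):
    """log-scale AnnData from per-group genes x cells arrays."""
    va, vb = np.asarray(values_a, float), np.asarray(values_b, float)
    values = np.hstack([va, vb])
    cells = [f"a{j}" for j in range(va.shape[1])] + [f"b{j}" for j in range(vb.shape[1])]
    adata = make_adata(values, genes=genes, cells=cells, layer="log2_cpm")
    mask_a = np.array([c.startswith("a") for c in cells])
    return adata, mask_a, ~mask_a


class TestDifferentialExpression:
    def test_low_expressing_gene_not_tested(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 5, size=(2, 100))
        b = rng.uniform(1, 5, size=(2, 100))
        a[1, 9:] = 0.0  # expressed in 9% of group A only
        adata, ma, mb = _two_group_adata(a, b)
        table = deg.differential_expression(adata, ma, mb)
        assert "G0" in table.index and "G1" not in table.index

    def test_fdr_matches_brute_force_bh(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5, 1, size=(120, 30))
        b = rng.normal(5, 1, size=(120, 30))
        adata, ma, mb = _two_group_adata(a, b)
        table = deg.differential_expression(adata, ma, mb, min_frac=0.0)
        expected = brute_force_bh(table["p_value"].to_numpy())
        assert np.allclose(table["fdr"].to_numpy(), np.minimum(expected, 1.0),
                           atol=1e-12)

    def test_welch_t_matches_scipy_per_gene(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a = rng.normal(4, 1, size=(10, 20))
        b = rng.normal(5, 2, size=(10, 25))
        adata, ma, mb = _two_group_adata(a, b)
        table = deg.differential_expression(adata, ma, mb, min_frac=0.0)
        for i, g in enumerate(table.index):
            t, p = stats.ttest_ind(a[i], b[i], equal_var=False)
            assert table.loc[g, "p_value"] == pytest.approx(p, abs=1e-12)

    def test_thresholds_inclusive(self):
        # group means differ by exactly 1.0 with tiny symmetric spread:
        # lfc == 1.0 must qualify as differential
        a = np.tile([6.0 - 0.25, 6.0 + 0.25], (1, 10))
        b = np.tile([5.0 - 0.25, 5.0 + 0.25], (1, 10))
        adata, ma, mb = _two_group_adata(a, b)
        table = deg.differential_expression(adata, ma, mb, min_frac=0.0)
        assert table["log2_fold_change"].iloc[0] == pytest.approx(1.0, abs=0)
        assert bool(table["is_deg"].iloc[0])

    def test_overlapping_groups_rejected(self, sc_dataset):
        adata, _ = sc_dataset
        logc = sc.log2_cpm(adata)
        mask = np.zeros(adata.n_obs, dtype=bool)
        mask[:10] = True
        with pytest.raises(AnalysisError):
            deg.differential_expression(logc, mask, mask)

    def test_requires_log_layer(self, sc_dataset):
        adata, _ = sc_dataset
        mask = np.arange(adata.n_obs) < 50
        with pytest.raises(AnalysisError):
            deg.differential_expression(adata, mask, ~mask)

    def test_null_permutation_controls_fdr(self):
        """Splitting one homogeneous population in half yields ~no DEGs."""
        fracs = []
        for seed in range(5):
            cfg = synth.SynthConfig(seed=seed, n_cells_per_group=60,
                                    n_genes=500, planted_deg_frac=0.0,
                                    qc_fail_frac=0.0)
            adata, _ = synth.make_sc_dataset(cfg)
            tonsil = adata[adata.obs["tissue"] == "tonsil"].copy()
            tonsil.uns["layer"] = "raw_counts"
            logc = sc.log2_cpm(tonsil)
            half = np.arange(logc.n_obs) % 2 == 0
            table = deg.differential_expression(logc, half, ~half)
            fracs.append(table["is_deg"].mean())
        assert np.mean(fracs) <= 0.005


class TestDegUnion:
    @staticmethod
    def _table(genes, flags):
        return pd.DataFrame({"is_deg": flags}, index=genes)

    def test_disjoint_sets_sum(self):
        t1 = self._table(["a", "b", "c"], [True] * 3)
        t2 = self._table(["d", "e", "f", "g"], [True] * 4)
        assert len(deg.deg_union([t1, t2])) == 7

    def test_idempotent(self):
        t = self._table(["a", "b"], [True, True])
        assert deg.deg_union([t, t]) == ["a", "b"]

    def test_non_deg_rows_excluded(self):
        t = self._table(["a", "b"], [True, False])
        assert deg.deg_union([t]) == ["a"]

    def test_four_comparison_union_covers_planted_degs(self, sc_dataset,
                                                       small_config):
        adata, truth = sc_dataset
        _, kept = sc.qc_filter(adata, synth.default_qc_config(small_config))
        logc = sc.log2_cpm(kept)
        iso = sc.assign_isotype(kept)
        logc.obs = logc.obs.join(iso)
        obs = logc.obs
        pops = {
            (t, s): ((obs["tissue"] == t) & (obs["switch_state"] == s)).to_numpy()
            for t in ("kidney", "tonsil") for s in ("switched", "unswitched")
        }
        tables = [
            deg.differential_expression(
                logc, pops[("kidney", s)], pops[("tonsil", s)])
            for s in ("switched", "unswitched")
        ]
        union = deg.deg_union(tables)
        brute = set()
        for t in tables:
            brute |= {g for g in t.index if t.loc[g, "is_deg"]}
        assert union == sorted(brute)
        # recovered genes are planted ones (no spurious calls at this scale)
        assert set(union) <= set(truth.deg_genes)


class TestClusterDegs:
    def test_anticorrelated_blocks_separate(self):
        up = np.tile([1.0, 1.0, 8.0, 8.0], (5, 1))
        down = np.tile([8.0, 8.0, 1.0, 1.0], (4, 1))
        values = np.vstack([up, down])  # genes x 4 "cells"
        genes = [f"U{i}" for i in range(5)] + [f"D{i}" for i in range(4)]
        adata = make_adata(values, genes=genes, layer="log2_cpm")
        pops = {f"p{j}": np.arange(4) == j for j in range(4)}
        out = deg.cluster_degs(adata, genes, pops, k=2)
        cl = out["clusters"]
        assert cl[[f"U{i}" for i in range(5)]].nunique() == 1
        assert cl[[f"D{i}" for i in range(4)]].nunique() == 1
        assert cl["U0"] != cl["D0"]
        # deterministic relabeling: larger block is cluster 1
        assert cl["U0"] == 1 and cl["D0"] == 2

    def test_single_cluster(self):
        adata = make_adata(np.random.default_rng(0).normal(5, 1, (6, 4)),
                           layer="log2_cpm")
        pops = {f"p{j}": np.arange(4) == j for j in range(4)}
        out = deg.cluster_degs(adata, list(adata.var_names), pops, k=1)
        assert out["clusters"].nunique() == 1

    def test_constant_gene_flagged_zero_row(self):
        values = np.vstack([np.full((1, 4), 3.0),
                            np.array([[1.0, 2.0, 3.0, 4.0]])])
        adata = make_adata(values, genes=["const", "var"], layer="log2_cpm")
        pops = {f"p{j}": np.arange(4) == j for j in range(4)}
        out = deg.cluster_degs(adata, ["const", "var"], pops, k=2)
        assert bool(out["constant"]["const"])
        assert np.allclose(out["z"].loc["const"], 0.0)

    def test_k_exceeding_genes_rejected(self):
        adata = make_adata(np.ones((2, 4)), layer="log2_cpm")
        pops = {f"p{j}": np.arange(4) == j for j in range(4)}
        with pytest.raises(AnalysisError):
            deg.cluster_degs(adata, list(adata.var_names), pops, k=5)


class TestZscore:
    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(0, 5, size=(40, 7)))
        z, constant = deg.zscore_rows(df)
        assert not constant.any()
        assert np.abs(z.sum(axis=1)).max() < 1e-9
        assert np.allclose(z.std(axis=1, ddof=0), 1.0)


class TestScores:
    def test_geneset_score_matches_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(10, 3, size=(30, 10)),
                          index=[f"g{i}" for i in range(30)])
        members = [f"g{i}" for i in range(0, 30, 3)]
        scores, missing = deg.geneset_score(df, members)
        assert missing == []
        for col in df.columns:
            expected = sum(
                (df.loc[g, col] - df.loc[g].mean()) / df.loc[g].std(ddof=0)
                for g in members
            )
            assert scores[col] == pytest.approx(expected, abs=1e-12)

    def test_identical_samples_score_zero(self):
        df = pd.DataFrame(np.tile([[4.0]], (5, 8)),
                          index=[f"g{i}" for i in range(5)])
        scores, _ = deg.geneset_score(df, list(df.index))
        assert np.allclose(scores, 0.0)

    def test_single_gene_set_equals_its_z(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        scores, _ = deg.geneset_score(df, ["g"])
        z = (df.loc["g"] - df.loc["g"].mean()) / df.loc["g"].std(ddof=0)
        assert np.allclose(scores, z)

    def test_absent_geneset_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g"])
        with pytest.raises(AnalysisError):
            deg.geneset_score(df, ["missing"])

    def test_dn_score_cancels_when_sets_equal(self, sc_dataset):
        adata, _ = sc_dataset
        logc = sc.log2_cpm(adata)
        genes = list(logc.var_names[:5])
        scores = deg.dn_score(logc, genes, genes)
        assert np.allclose(scores, 0.0, atol=1e-9)


class TestPopulationCorrelation:
    def test_population_against_itself_is_one(self, sc_dataset):
        adata, _ = sc_dataset
        logc = sc.log2_cpm(adata)
        kidney = (logc.obs["tissue"] == "kidney").to_numpy()
        out = deg.population_correlation(
            logc, {"k1": kidney, "k2": kidney}, n_hv=100)
        assert out.loc["k1", "k2"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(out, out.T)
        assert np.allclose(np.diag(out), 1.0)

    def test_tissues_less_correlated_than_halves(self):
        cfg = synth.SynthConfig(seed=11, n_cells_per_group=80, n_genes=400,
                                planted_deg_frac=0.3, planted_log2fc=3.0,
                                qc_fail_frac=0.0)
        adata, _ = synth.make_sc_dataset(cfg)
        logc = sc.log2_cpm(adata)
        kid = (logc.obs["tissue"] == "kidney").to_numpy()
        halves = np.arange(logc.n_obs) % 2 == 0
        out = deg.population_correlation(
            logc,
            {"kid": kid, "ton": ~kid, "h1": kid & halves, "h2": kid & ~halves},
            n_hv=200,
        )
        assert out.loc["h1", "h2"] > out.loc["kid", "ton"]


class TestClusterScoresOnAtlas:
    def test_planted_block_scores_highest_in_pc_subsets(self, atlas_bundle):
        atlas, smap, orth, truth = atlas_bundle
        mapped_block = orth[orth["mouse_gene"].isin(truth.block_genes)]
        clusters = pd.Series(
            1, index=mapped_block["human_gene"].unique(), name="cluster")
        mat, empty = deg.cluster_scores_on_atlas(atlas, smap, clusters, orth)
        assert empty == []
        top_subset = mat.loc[1].idxmax()
        assert top_subset.endswith(".PC")

    def test_replicate_permutation_invariant(self, atlas_bundle):
        atlas, smap, orth, truth = atlas_bundle
        clusters = pd.Series(1, index=["GENE0100", "GENE0101"])
        mat1, _ = deg.cluster_scores_on_atlas(atlas, smap, clusters, orth)
        perm = atlas[atlas.columns[::-1]]
        mat2, _ = deg.cluster_scores_on_atlas(perm, smap, clusters, orth)
        pd.testing.assert_frame_equal(mat1, mat2[mat1.columns])

    def test_unmappable_cluster_reported_not_dropped(self, atlas_bundle):
        atlas, smap, orth, _ = atlas_bundle
        clusters = pd.Series([1, 2], index=["GENE0100", "NOSUCHGENE"])
        mat, empty = deg.cluster_scores_on_atlas(atlas, smap, clusters, orth)
        assert empty == [2]
        assert mat.loc[2].isna().all()
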