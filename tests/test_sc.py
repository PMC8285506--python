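"""Expression I/O, log2-CPM, QC filters, isotype and plasma calls."""

import numpy as np
import pandas as pd
import pytest

from binsig import sc, synth
from binsig.errors import AnalysisError, ConfigError, FormatError
from conftest import make_adata


class TestLoadMatrix:
    def test_tsv_round_trip(self, tmp_path):
        adata = make_adata([[1, 2], [0, 3], [5, 0]],
                           genes=["A", "B", "ERCC-1"])
        sc.write_matrix(adata, tmp_path / "m.tsv")
        back = sc.load_matrix(tmp_path / "m.tsv", fmt="tsv")
        assert back.shape == (2, 3)
        assert np.array_equal(back.X, adata.X)
        assert list(back.var["is_spikein"]) == [False, False, True]

    def test_mtx_round_trip(self, tmp_path):
        adata = make_adata([[1, 0], [2, 3]])
        sc.write_matrix(adata, tmp_path / "mtx", fmt="mtx")
        back = sc.load_matrix(tmp_path / "mtx", fmt="mtx")
        assert np.array_equal(back.X, adata.X)

    def test_mtx_barcode_mismatch_rejected(self, tmp_path):
        adata = make_adata([[1, 0], [2, 3]])
        sc.write_matrix(adata, tmp_path / "mtx", fmt="mtx")
        (tmp_path / "mtx" / "barcodes.tsv").write_text("C0\nC1\nC2\n")
        with pytest.raises(FormatError):
            sc.load_matrix(tmp_path / "mtx", fmt="mtx")

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene_id\tC0\nA\t1\nA\t2\n")
        with pytest.raises(FormatError):
            sc.load_matrix(tmp_path / "m.tsv")


class TestLog2Cpm:
    def test_single_count_in_million_library(self):
        # one gene at count 1 within a 10^6 library -> log2(1 + 1) = 1
        values = np.zeros((2, 1))
        values[0, 0] = 1.0
        values[1, 0] = 1e6 - 1
        adata = make_adata(values)
        out = sc.log2_cpm(adata, exclude_spikeins=False)
        assert out.X[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_cell_error_names_cell(self):
        adata = make_adata([[1, 0], [2, 0]], cells=["good", "empty"])
        with pytest.raises(AnalysisError, match="empty"):
            sc.log2_cpm(adata)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 40, size=(50, 20)).astype(float)
        counts[:, counts.sum(axis=0) == 0] += 1.0
        adata = make_adata(counts)
        out = sc.log2_cpm(adata, exclude_spikeins=False)
        for j in range(20):
            lib = counts[:, j].sum()
            for i in range(50):
                expected = np.log2(1 + 1e6 * counts[i, j] / lib)
                assert out.X[j, i] == pytest.approx(expected, abs=1e-12)

    def test_monotone_within_cell(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 100, size=(30, 5)).astype(float) + 1
        adata = make_adata(counts)
        out = sc.log2_cpm(adata, exclude_spikeins=False)
        for j in range(5):
            order_counts = np.argsort(counts[:, j])
            transformed = out.X[j, order_counts]
            assert (np.diff(transformed) >= 0).all()

    def test_spikeins_excluded_from_library(self):
        adata = make_adata([[10, 10], [90, 90], [900, 0]],
                           genes=["A", "B", "ERCC-1"])
        out = sc.log2_cpm(adata, exclude_spikeins=True)
        # library = 100 for both cells despite unequal spike-in content
        assert out.X[0, 0] == pytest.approx(out.X[1, 0], abs=1e-12)


class TestQcFilter:
    def _matrix_with_gene_counts(self, n_expressed_per_cell, n_genes=4000):
        """Cells expressing exactly the requested number of genes, plus an
        IGHM row keeping the Ig filter satisfied."""
        n_cells = len(n_expressed_per_cell)
        values = np.zeros((n_genes, n_cells))
        for j, k in enumerate(n_expressed_per_cell):
            values[:k, j] = 5.0
        ig = np.full((1, n_cells), 1000.0)
        all_vals = np.vstack([values, ig])
        return make_adata(all_vals,
                          genes=[f"G{i}" for i in range(n_genes)] + ["IGHM"])

    def test_gene_count_boundary_is_exclusive(self):
        # 2,999 expressed genes fails a 3,000-gene minimum; exactly 3,000 passes
        adata = self._matrix_with_gene_counts([2999 - 1, 3000 - 1])  # +IGHM row
        cfg = sc.QCConfig(min_genes=3000, max_genes=15000, ig_logcpm_min=1.0)
        ann, _ = sc.qc_filter(adata, cfg)
        assert not ann["qc_pass"].iloc[0]
        assert "low_gene_count" in ann["fail_reasons"].iloc[0]
        assert ann["qc_pass"].iloc[1]

    def test_ig_filter_reason_recorded(self):
        values = np.zeros((20, 1))
        values[:15, 0] = 5.0
        adata = make_adata(np.vstack([values, [[0.0]]]),
                           genes=[f"G{i}" for i in range(20)] + ["IGHM"])
        cfg = sc.QCConfig(min_genes=5, max_genes=100, ig_logcpm_min=5.0)
        ann, kept = sc.qc_filter(adata, cfg)
        assert not ann["qc_pass"].iloc[0]
        assert ann["fail_reasons"].iloc[0] == "low_ig_expression"
        assert kept.n_obs == 0

    def test_filter_order_independent(self, sc_dataset, small_config):
        adata, _ = sc_dataset
        qc = synth.default_qc_config(small_config)
        ann_both, _ = sc.qc_filter(adata, qc)
        only_genes = sc.QCConfig(min_genes=qc.min_genes, max_genes=qc.max_genes,
                                 ig_logcpm_min=-np.inf)
        only_ig = sc.QCConfig(min_genes=0, max_genes=10 ** 9,
                              ig_logcpm_min=qc.ig_logcpm_min)
        for first, second in [(only_genes, only_ig), (only_ig, only_genes)]:
            ann1, kept1 = sc.qc_filter(adata, first)
            ann2, kept2 = sc.qc_filter(kept1, second)
            assert set(kept2.obs_names) == set(ann_both.index[ann_both["qc_pass"]])

    def test_matches_generator_truth_exactly(self, sc_dataset, small_config):
        adata, truth = sc_dataset
        ann, _ = sc.qc_filter(adata, synth.default_qc_config(small_config))
        assert set(ann.index[~ann["qc_pass"]]) == set(truth.qc_fail_cells)

    def test_empty_matrix_rejected(self):
        adata = make_adata(np.zeros((3, 1)))[:0]
        with pytest.raises(AnalysisError):
            sc.qc_filter(adata, sc.QCConfig())

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            sc.QCConfig(min_genes=100, max_genes=100)


class TestAssignIsotype:
    def test_switched_and_unswitched_calls(self):
        genes = ["IGHM", "IGHD", "IGHG1"]
        adata = make_adata([[10, 50, 0], [5, 0, 0], [100, 10, 0]], genes=genes)
        out = sc.assign_isotype(adata, genes)
        assert list(out["isotype"]) == ["IGHG1", "IGHM", "undetermined"]
        assert list(out["switch_state"]) == ["switched", "unswitched",
                                             "undetermined"]

    def test_tie_resolves_to_precedence_order_and_flags(self):
        genes = ["IGHM", "IGHA1"]
        adata = make_adata([[7.0], [7.0]], genes=genes)
        out = sc.assign_isotype(adata, genes)
        assert out["isotype"].iloc[0] == "IGHM"
        assert bool(out["isotype_tie"].iloc[0])

    def test_row_order_invariant_without_ties(self, sc_dataset):
        adata, _ = sc_dataset
        order = list(sc.IGH_CONSTANT_GENES)
        out1 = sc.assign_isotype(adata, order)
        shuffled = adata[:, ::-1].copy()
        shuffled.uns["layer"] = adata.uns["layer"]
        out2 = sc.assign_isotype(shuffled, order)
        no_tie = ~out1["isotype_tie"]
        assert (out1.loc[no_tie, "isotype"] == out2.loc[no_tie, "isotype"]).all()

    def test_matches_generator_truth(self, sc_dataset, small_config):
        adata, truth = sc_dataset
        _, kept = sc.qc_filter(adata, synth.default_qc_config(small_config))
        out = sc.assign_isotype(kept)
        for cell in kept.obs_names:
            assert out.loc[cell, "isotype"] == truth.isotype[cell]


class TestFlagPlasma:
    def test_clear_marker_cluster_flagged(self):
        adata = make_adata([[10, 10, 0.1, 0.0]], genes=["PRDM1"])
        labels = pd.Series(["p", "p", "b", "b"], index=adata.obs_names)
        out = sc.flag_plasma(adata, labels)
        assert list(out["is_plasma"]) == [True, True, False, False]

    def test_equal_cluster_means_not_flagged(self):
        adata = make_adata([[5, 5, 5, 5]], genes=["PRDM1"])
        labels = pd.Series(["a", "a", "b", "b"], index=adata.obs_names)
        out = sc.flag_plasma(adata, labels)
        assert not out["is_plasma"].any()

    def test_missing_marker_rejected(self):
        adata = make_adata([[1, 2]], genes=["OTHER"])
        with pytest.raises(AnalysisError):
            sc.flag_plasma(adata, pd.Series(["a", "b"], index=adata.obs_names))

    def test_matches_planted_plasma_cluster(self, sc_dataset, small_config):
        adata, truth = sc_dataset
        _, kept = sc.qc_filter(adata, synth.default_qc_config(small_config))
        logc = sc.log2_cpm(kept)
        out = sc.flag_plasma(logc)
        expected = set(truth.plasma_cells) & set(kept.obs_names)
        assert set(out.index[out["is_plasma"]]) == expected
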