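"""GWAS-catalogue batch mode: parsing, matrix assembly, clustering, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet

import snpenrich as se
from snpenrich.catalogue import PhenotypeMatrix, phenotype_seed
from snpenrich.errors import InputFormatError, SnpEnrichError

from .oracles import naive_complete_linkage_cophenetic


def write_catalogue(tmp_path, rows, name="cat.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=["DISEASE/TRAIT", "SNPS", "PUBMEDID"]) \
        .to_csv(path, sep="\t", index=False)
    return path


class TestParseCatalogue:
    def test_minimum_snp_filter_keeps_only_large_traits(self, tmp_path):
        rows = [("A", f"rs{i}", "1") for i in range(1, 7)] + \
               [("B", f"rs{i}", "1") for i in range(10, 14)]
        path = write_catalogue(tmp_path, rows)
        pheno = se.parse_gwas_catalogue(path, min_snps=5)
        assert set(pheno) == {"A"}
        assert pheno["A"] == [f"rs{i}" for i in range(1, 7)]

    def test_duplicate_rsids_deduplicated_in_first_seen_order(self, tmp_path):
        rows = [("A", "rs2", "1"), ("A", "rs1", "1"), ("A", "rs2", "1"),
                ("A", "rs3", "1"), ("A", "rs4", "1"), ("A", "rs5", "1")]
        pheno = se.parse_gwas_catalogue(write_catalogue(tmp_path, rows),
                                        min_snps=5)
        assert pheno["A"] == ["rs2", "rs1", "rs3", "rs4", "rs5"]

    def test_multi_snp_cells_split_on_catalogue_separators(self, tmp_path):
        rows = [("A", "rs1; rs2", "1"), ("A", "rs3 x rs4", "1"),
                ("A", "rs5", "1")]
        pheno = se.parse_gwas_catalogue(write_catalogue(tmp_path, rows),
                                        min_snps=5)
        assert pheno["A"] == ["rs1", "rs2", "rs3", "rs4", "rs5"]

    def test_malformed_tokens_dropped(self, tmp_path):
        rows = [("A", "rs1", "1"), ("A", "chr1:123", "1"), ("A", "rs2", "1"),
                ("A", "rs3; kgp123", "1"), ("A", "rs4; rs5", "1")]
        pheno = se.parse_gwas_catalogue(write_catalogue(tmp_path, rows),
                                        min_snps=5)
        assert pheno["A"] == ["rs1", "rs2", "rs3", "rs4", "rs5"]

    def test_missing_required_column_is_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"TRAIT": ["A"], "SNPS": ["rs1"]}).to_csv(
            path, sep="\t", index=False)
        with pytest.raises(InputFormatError, match="DISEASE/TRAIT"):
            se.parse_gwas_catalogue(path)

    def test_snp_counts_bounded_by_valid_tokens(self, tmp_path):
        rows = [("A", "rs1; rs2", "1"), ("B", "rs1; bad", "1")]
        pheno = se.parse_gwas_catalogue(write_catalogue(tmp_path, rows),
                                        min_snps=1)
        assert sum(len(v) for v in pheno.values()) <= 3


class TestRunBatch:
    def phenotypes(self, bundle):
        uni, gt = bundle["universe"], bundle["ground_truth"]
        return {
            "trait one": se.simulate_input_set(uni, gt, 2, 30, 0.8, seed=61),
            "trait two": se.simulate_input_set(uni, gt, 5, 30, 0.0, seed=62),
        }

    def test_matrix_cells_are_neg_log10_q(self, sim_bundle):
        pheno = self.phenotypes(sim_bundle)
        matrix, tables = se.run_batch(sim_bundle["db"], sim_bundle["universe"],
                                      pheno, None, se.AnalysisConfig(seed=71))
        assert matrix.values.shape == (2, sim_bundle["db"].n_samples)
        for label in pheno:
            per = tables[label].set_index("sample_id")
            for sid in matrix.values.columns:
                q = per.loc[sid, "q"]
                expected = 0.0 if q >= 1 else -np.log10(q)
                assert matrix.values.loc[label, sid] == pytest.approx(expected)

    def test_failed_phenotype_skipped_not_fatal(self, sim_bundle):
        pheno = self.phenotypes(sim_bundle)
        pheno["ghost"] = ["rsA", "rsB", "rsC", "rsD", "rsE"]
        matrix, tables = se.run_batch(sim_bundle["db"], sim_bundle["universe"],
                                      pheno, None, se.AnalysisConfig(seed=71))
        assert "ghost" not in matrix.values.index
        assert len(matrix.values) == 2

    def test_master_seed_determinism_and_order_independence(self, sim_bundle):
        pheno = self.phenotypes(sim_bundle)
        m1, _ = se.run_batch(sim_bundle["db"], sim_bundle["universe"],
                             pheno, None, se.AnalysisConfig(seed=71))
        reordered = dict(reversed(list(pheno.items())))
        m2, _ = se.run_batch(sim_bundle["db"], sim_bundle["universe"],
                             reordered, None, se.AnalysisConfig(seed=71))
        assert m1.values.sort_index().equals(m2.values.sort_index())

    def test_phenotype_seed_is_stable_and_below_2_31(self):
        s = phenotype_seed(20240101, "height")
        assert s == phenotype_seed(20240101, "height")
        assert 0 <= s < 2 ** 31
        assert s != phenotype_seed(20240101, "weight")

    def test_no_signal_phenotypes_flagged(self, sim_bundle):
        pheno = self.phenotypes(sim_bundle)
        matrix, _ = se.run_batch(sim_bundle["db"], sim_bundle["universe"],
                                 pheno, None, se.AnalysisConfig(seed=71))
        assert "trait two" in matrix.no_signal_phenotypes


class TestRowNormalise:
    def test_divide_by_row_max(self):
        m = PhenotypeMatrix(values=pd.DataFrame([[1.0, 2.0, 4.0]], index=["a"],
                                                columns=["x", "y", "z"]))
        out = se.row_normalise(m)
        assert list(out.values.loc["a"]) == [0.25, 0.5, 1.0]
        assert out.row_max.loc["a"] == 4.0
        assert out.row_normalised

    def test_zero_row_left_as_zeros(self):
        m = PhenotypeMatrix(values=pd.DataFrame([[0.0, 0.0]], index=["a"]))
        out = se.row_normalise(m)
        assert list(out.values.loc["a"]) == [0.0, 0.0]
        assert out.row_max.loc["a"] == 0.0

    def test_constant_row_becomes_ones(self):
        m = PhenotypeMatrix(values=pd.DataFrame([[3.0, 3.0]], index=["a"]))
        assert list(se.row_normalise(m).values.loc["a"]) == [1.0, 1.0]


def matrix_of(rows, labels):
    return PhenotypeMatrix(values=pd.DataFrame(
        np.asarray(rows, dtype=float), index=labels))


class TestClusterRows:
    def test_identical_pair_merges_first_at_height_zero(self):
        m = matrix_of([[1, 2], [5, 9], [1, 2]], ["a", "b", "c"])
        _, Z, _ = se.cluster_rows(m)
        assert Z[0, 2] == 0.0

    def test_hand_computed_merge_heights(self):
        # pairwise distances 3, 4, 5; first merge at 3, final at complete
        # linkage height 5
        m = matrix_of([[0, 0], [0, 3], [4, 0]], ["a", "b", "c"])
        _, Z, newick = se.cluster_rows(m)
        assert Z[0, 2] == pytest.approx(3.0)
        assert Z[1, 2] == pytest.approx(5.0)
        assert newick.endswith(";")

    def test_permutation_of_rows_gives_same_tree(self):
        rng = np.random.default_rng(8)
        data = rng.random((6, 4))
        labels = [f"p{i}" for i in range(6)]
        m1 = matrix_of(data, labels)
        perm = rng.permutation(6)
        m2 = matrix_of(data[perm], [labels[i] for i in perm])
        assert se.cluster_rows(m1)[2] == se.cluster_rows(m2)[2]

    def test_agrees_with_naive_complete_linkage(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            data = rng.random((n, int(rng.integers(2, 6))))
            m = matrix_of(data, [f"r{i:02d}" for i in range(n)])
            _, Z, _ = se.cluster_rows(m)
            coph = cophenet(Z)
            expected = naive_complete_linkage_cophenetic(data)
            iu = np.triu_indices(n, k=1)
            # labels sort to data order, so condensed entries align pairwise
            assert np.allclose(coph, expected[iu], atol=1e-9)

    def test_single_row_identity(self):
        labels, Z, newick = se.cluster_rows(matrix_of([[1, 2]], ["only"]))
        assert labels == ["only"] and Z.shape == (0, 4)


class TestIntersectionSummary:
    def test_two_set_worked_example(self):
        out = se.intersection_summary({"A": {"x", "y"}, "B": {"y", "z"}})
        counts = dict(zip(out["members"], out["count"]))
        assert counts == {"A": 1, "B": 1, "A&B": 1}

    def test_disjoint_sets(self):
        out = se.intersection_summary({"A": {"x"}, "B": {"y"}})
        counts = dict(zip(out["members"], out["count"]))
        assert counts == {"A": 1, "B": 1, "A&B": 0}

    def test_identical_sets_only_full_intersection(self):
        out = se.intersection_summary({"A": {"x", "y"}, "B": {"x", "y"},
                                       "C": {"x", "y"}})
        counts = dict(zip(out["members"], out["count"]))
        assert counts["A&B&C"] == 2
        assert sum(v for k, v in counts.items() if k != "A&B&C") == 0

    def test_fewer_than_two_sets_is_error(self):
        with pytest.raises(SnpEnrichError):
            se.intersection_summary({"A": {"x"}})
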