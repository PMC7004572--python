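import numpy as np
import pandas as pd
import pytest
import scipy.io
import scipy.sparse

from scgrn import (
    CellMetadata,
    CountMatrix,
    ExpressionMatrix,
    filter_zero_variance,
    log_transform,
    pseudobulk_aggregate,
    read_count_matrix,
    split_tasks,
)
from scgrn.matrices import MatrixParseError, MatrixValidationError


class TestCountMatrixIO:
    def test_dense_tsv_round_trip(self, tiny_counts, tmp_path):
        m = CountMatrix(tiny_counts)
        path = tmp_path / "counts.tsv"
        m.write_tsv(path)
        back, meta = read_count_matrix(path)
        pd.testing.assert_frame_equal(back.data, m.data)
        assert meta is None

    def test_metadata_columns_split_off(self, tiny_counts, tmp_path):
        df = tiny_counts.copy()
        df["condition"] = ["YPD", "YPD", "RAPA"]
        df["genotype"] = ["WT", "WT", "gat1"]
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t", index_label="cell_id")
        counts, meta = read_count_matrix(path)
        assert counts.gene_ids == ["g1", "g2", "g3"]
        assert list(meta.data["condition"]) == ["YPD", "YPD", "RAPA"]

    def test_triplet_densification(self, tmp_path):
        coo = scipy.sparse.coo_matrix(([4, 1], ([0, 1], [0, 1])), shape=(2, 2))
        scipy.io.mmwrite(tmp_path / "m.mtx", coo)
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        (tmp_path / "features.tsv").write_text("g1\ng2\n")
        m, _ = read_count_matrix(tmp_path / "m.mtx", fmt="triplet")
        np.testing.assert_array_equal(m.values, [[4, 0], [0, 1]])

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("cell_id\tg1\nc1\t-1\n")
        with pytest.raises(MatrixValidationError):
            read_count_matrix(path)

    def test_non_integer_count_rejected(self):
        with pytest.raises(MatrixValidationError):
            CountMatrix(pd.DataFrame([[1.5]], index=["c1"], columns=["g1"]))

    def test_duplicate_cell_ids_rejected(self):
        with pytest.raises(MatrixValidationError, match="duplicate cell"):
            CountMatrix(pd.DataFrame([[1], [2]], index=["c1", "c1"], columns=["g1"]))

    def test_non_numeric_column_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("cell_id\tg1\tweird\nc1\t1\tfoo\n")
        with pytest.raises(MatrixParseError):
            read_count_matrix(path)


class TestPreprocessing:
    def test_constant_columns_removed(self):
        df = pd.DataFrame(
            {"g1": [5, 5, 5], "g2": [0, 0, 0], "g3": [1, 2, 3]},
            index=["c1", "c2", "c3"],
        )
        out = filter_zero_variance(CountMatrix(df))
        assert out.gene_ids == ["g3"]
        assert out.cell_ids == ["c1", "c2", "c3"]

    def test_all_varying_is_identity(self, tiny_counts):
        m = CountMatrix(tiny_counts[["g1", "g2"]])
        out = filter_zero_variance(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_all_constant_errors(self):
        df = pd.DataFrame({"g1": [2, 2]}, index=["c1", "c2"])
        with pytest.raises(MatrixValidationError, match="no variable genes"):
            filter_zero_variance(CountMatrix(df))

    @pytest.mark.parametrize("count,expected", [(0, 0.0), (1, 1.0), (7, 3.0)])
    def test_log_transform_values(self, count, expected):
        m = CountMatrix(pd.DataFrame([[count]], index=["c1"], columns=["g1"]))
        assert log_transform(m).values[0, 0] == pytest.approx(expected)


class TestPseudobulk:
    def _meta(self, index, **cols):
        return CellMetadata(pd.DataFrame(cols, index=index))

    def test_counts_are_summed(self):
        m = CountMatrix(pd.DataFrame({"g1": [2, 3]}, index=["c1", "c2"]))
        meta = self._meta(["c1", "c2"], genotype=["wt", "wt"], replicate_barcode=["r1", "r1"])
        out = pseudobulk_aggregate(m, meta, ["genotype", "replicate_barcode"])
        assert out.values.tolist() == [[5]]

    def test_12_genotypes_by_6_replicates_gives_72_samples(self, rng):
        # one cell per (genotype, replicate) pair, mirroring a pooled library
        genotypes = [f"geno{g}" for g in range(12) for _ in range(6) for _ in range(2)]
        replicates = [f"rep{r}" for _ in range(12) for r in range(6) for _ in range(2)]
        cells = [f"c{i}" for i in range(len(genotypes))]
        counts = CountMatrix(
            pd.DataFrame({"g1": rng.integers(0, 9, len(cells))}, index=cells)
        )
        meta = self._meta(cells, genotype=genotypes, replicate_barcode=replicates)
        out = pseudobulk_aggregate(counts, meta, ["genotype", "replicate_barcode"])
        assert out.shape[0] == 72

    def test_total_counts_conserved(self, rng):
        cells = [f"c{i}" for i in range(30)]
        counts = CountMatrix(
            pd.DataFrame(rng.integers(0, 20, (30, 4)), index=cells,
                         columns=[f"g{j}" for j in range(4)])
        )
        meta = self._meta(cells, genotype=list(rng.choice(["a", "b", "c"], 30)))
        out = pseudobulk_aggregate(counts, meta, ["genotype"])
        assert out.values.sum() == counts.values.sum()

    def test_transformed_input_rejected(self, tiny_counts):
        x = log_transform(CountMatrix(tiny_counts))
        meta = self._meta(["c1", "c2", "c3"], genotype=["a", "a", "b"])
        with pytest.raises(TypeError):
            pseudobulk_aggregate(x, meta, ["genotype"])

    def test_empty_group_absent(self):
        m = CountMatrix(pd.DataFrame({"g1": [1, 2]}, index=["c1", "c2"]))
        meta = self._meta(["c1", "c2"], genotype=["a", "a"])
        out = pseudobulk_aggregate(m, meta, ["genotype"])
        assert out.shape[0] == 1


class TestSplitTasks:
    def _expr(self, conditions):
        cells = [f"c{i}" for i in range(len(conditions))]
        x = ExpressionMatrix(
            pd.DataFrame({"g1": np.arange(len(cells), dtype=float)}, index=cells)
        )
        meta = CellMetadata(pd.DataFrame({"condition": conditions}, index=cells))
        return x, meta

    def test_eleven_conditions_give_eleven_tasks(self):
        conditions = [f"cond{i % 11}" for i in range(44)]
        x, meta = self._expr(conditions)
        tasks = split_tasks(x, meta)
        assert len(tasks) == 11

    def test_single_condition_is_identity(self):
        x, meta = self._expr(["YPD"] * 5)
        tasks = split_tasks(x, meta)
        assert len(tasks) == 1
        pd.testing.assert_frame_equal(tasks.tasks[0].expression.data, x.data)

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        conditions = list(rng.choice(["a", "b", "c"], 40))
        x, meta = self._expr(conditions)
        tasks = split_tasks(x, meta)
        all_cells = [c for t in tasks for c in t.expression.cell_ids]
        assert sorted(all_cells) == sorted(x.cell_ids)
        assert len(set(all_cells)) == len(all_cells)

    def test_missing_label_errors(self):
        x, meta = self._expr(["a", None, "b"])
        with pytest.raises(MatrixValidationError, match="without condition"):
            split_tasks(x, meta)
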