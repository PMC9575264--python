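import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from negsel import (
    AssociationTable,
    SimilarityMatrix,
    build_feature_matrix,
    build_feature_vector,
    load_similarity_matrix,
    partition_samples,
)


def _write_tsv(path, labels_row, rows):
    lines = ["\t".join([""] + labels_row)]
    for name, vals in rows:
        lines.append("\t".join([name] + [str(v) for v in vals]))
    path.write_text("\n".join(lines) + "\n")


class TestSimilarityMatrixIO:
    def test_identity_matrix_loads(self, tmp_path):
        p = tmp_path / "sim.tsv"
        _write_tsv(p, ["a", "b", "c"], [("a", [1, 0, 0]), ("b", [0, 1, 0]), ("c", [0, 0, 1])])
        sm = load_similarity_matrix(p, kind="mirna")
        assert sm.labels == ["a", "b", "c"]
        assert np.array_equal(np.diag(sm.values), np.ones(3))

    def test_out_of_range_value_rejected(self, tmp_path):
        p = tmp_path / "sim.tsv"
        _write_tsv(p, ["a", "b"], [("a", [1, 1.2]), ("b", [1.2, 1])])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            load_similarity_matrix(p)

    def test_non_square_rejected(self, tmp_path):
        p = tmp_path / "sim.tsv"
        _write_tsv(p, ["a", "b", "c"], [("a", [1, 0, 0]), ("b", [0, 1, 0])])
        with pytest.raises(ValueError, match="square"):
            load_similarity_matrix(p)

    def test_nan_rejected(self, tmp_path):
        p = tmp_path / "sim.tsv"
        _write_tsv(p, ["a", "b"], [("a", [1, "nan"]), ("b", [0.5, 1])])
        with pytest.raises(ValueError, match="finite"):
            load_similarity_matrix(p)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SimilarityMatrix(labels=["a", "a"], values=np.eye(2))

    def test_off_diagonal_warns_only(self):
        with pytest.warns(UserWarning, match="diagonal"):
            SimilarityMatrix(labels=["a", "b"], values=np.array([[0.9, 0.1], [0.1, 1.0]]))

    @given(st.integers(0, 2**31 - 1))
    def test_tsv_round_trip_bit_exact(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        sm = SimilarityMatrix(labels=[f"e{i}" for i in range(n)], values=vals)
        p = tmp_path_factory.mktemp("rt") / "m.tsv"
        sm.to_tsv(p)
        back = SimilarityMatrix.from_tsv(p)
        assert back.labels == sm.labels
        assert np.array_equal(back.values, sm.values)


class TestFeatureVectors:
    def test_benchmark_scale_dimension(self):
        simM = SimilarityMatrix([f"m{i}" for i in range(495)], np.eye(495))
        simD = SimilarityMatrix([f"d{i}" for i in range(383)], np.eye(383))
        ps = build_feature_vector(0, 0, simM, simD)
        assert ps.feature.shape == (878,)

    def test_identity_rows_concatenate(self):
        simM = SimilarityMatrix(["m0", "m1"], np.eye(2))
        simD = SimilarityMatrix(["d0", "d1"], np.eye(2))
        ps = build_feature_vector(0, 1, simM, simD)
        assert ps.feature.tolist() == [1, 0, 0, 1]

    def test_rows_in_mirna_then_disease_order(self):
        simM = SimilarityMatrix(["m0", "m1"], np.array([[1, 0.5], [0.5, 1]]))
        simD = SimilarityMatrix(["d0", "d1"], np.array([[1, 0.2], [0.2, 1]]))
        ps = build_feature_vector(1, 0, simM, simD)
        assert ps.feature.tolist() == [0.5, 1, 1, 0.2]

    @pytest.mark.parametrize("mi,di", [(-1, 0), (2, 0), (0, -1), (0, 2)])
    def test_out_of_range_index(self, mi, di):
        simM = SimilarityMatrix(["m0", "m1"], np.eye(2))
        simD = SimilarityMatrix(["d0", "d1"], np.eye(2))
        with pytest.raises(IndexError):
            build_feature_vector(mi, di, simM, simD)

    @given(st.integers(0, 2**31 - 1))
    def test_feature_length_and_values(self, seed):
        rng = np.random.default_rng(seed)
        m, d = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        A = rng.random((m, m)); A = (A + A.T) / 2; np.fill_diagonal(A, 1)
        B = rng.random((d, d)); B = (B + B.T) / 2; np.fill_diagonal(B, 1)
        simM = SimilarityMatrix([f"m{i}" for i in range(m)], A)
        simD = SimilarityMatrix([f"d{i}" for i in range(d)], B)
        i, j = int(rng.integers(m)), int(rng.integers(d))
        feat = build_feature_vector(i, j, simM, simD).feature
        assert feat.shape == (m + d,)
        allowed = set(A.reshape(-1)) | set(B.reshape(-1))
        assert set(feat) <= allowed

    def test_feature_matrix_rows_match_single_pairs(self):
        rng = np.random.default_rng(7)
        A = rng.random((3, 3)); A = (A + A.T) / 2; np.fill_diagonal(A, 1)
        B = rng.random((2, 2)); B = (B + B.T) / 2; np.fill_diagonal(B, 1)
        simM = SimilarityMatrix(["m0", "m1", "m2"], A)
        simD = SimilarityMatrix(["d0", "d1"], B)
        X = build_feature_matrix(simM, simD)
        assert X.shape == (6, 5)
        for i in range(3):
            for j in range(2):
                expected = build_feature_vector(i, j, simM, simD).feature
                assert np.array_equal(X[i * 2 + j], expected)


class TestPartition:
    @pytest.fixture
    def grid32(self):
        simM = SimilarityMatrix(["m0", "m1", "m2"], np.eye(3))
        simD = SimilarityMatrix(["d0", "d1"], np.eye(2))
        return simM, simD

    def test_no_positives(self, grid32):
        sets = partition_samples(AssociationTable([]), *grid32)
        assert sets.P.size == 0 and sets.U.size == 6

    def test_no_unlabelled(self, grid32):
        pairs = [(f"m{i}", f"d{j}") for i in range(3) for j in range(2)]
        sets = partition_samples(AssociationTable(pairs), *grid32)
        assert sets.P.size == 6 and sets.U.size == 0

    def test_two_positives_on_six_pairs(self, grid32):
        sets = partition_samples(AssociationTable([("m0", "d0"), ("m2", "d1")]), *grid32)
        assert sets.P.size == 2 and sets.U.size == 4
        assert set(sets.P.tolist()) == {0, 5}  # row-major i*d + j

    def test_unknown_label_rejected(self, grid32):
        with pytest.raises(KeyError, match="m9"):
            partition_samples(AssociationTable([("m9", "d0")]), *grid32)

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            AssociationTable([("a", "b"), ("a", "b")])

    @given(st.integers(0, 2**31 - 1))
    def test_sizes_always_sum_to_grid(self, seed):
        rng = np.random.default_rng(seed)
        m, d = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        simM = SimilarityMatrix([f"m{i}" for i in range(m)], np.eye(m))
        simD = SimilarityMatrix([f"d{j}" for j in range(d)], np.eye(d))
        all_pairs = [(f"m{i}", f"d{j}") for i in range(m) for j in range(d)]
        k = int(rng.integers(0, m * d + 1))
        chosen = [all_pairs[t] for t in rng.choice(m * d, size=k, replace=False)]
        sets = partition_samples(AssociationTable(chosen), simM, simD)
        assert sets.P.size + sets.U.size == m * d
        assert not (set(sets.P.tolist()) & set(sets.U.tolist()))
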