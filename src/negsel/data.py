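"""Input containers and similarity-profile feature construction.

A dataset is two labelled square similarity matrices (miRNA functional
similarity, disease semantic similarity; values in [0, 1]) and an edge
list of known associations. Every (miRNA, disease) pair gets a feature
vector of length m + d: the miRNA's similarity-matrix row followed by the
disease's row. Known pairs form the positive set P; all remaining pairs
form the unlabelled set U.

Pair indices are canonical and row-major: pair (i, j) has index
``i * d + j`` with i, j following the label order of the two matrices.
Every staged sample set downstream stores indices under this order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "AssociationTable",
    "PairSample",
    "SampleSets",
    "load_similarity_matrix",
    "load_association_table",
    "build_feature_vector",
    "build_feature_matrix",
    "partition_samples",
]

STAGE_NAMES = ("P", "LP1", "LN1", "LN2", "RN", "RP")


@dataclass
class SimilarityMatrix:
    """A labelled square similarity matrix with values in [0, 1].

    Parameters
    ----------
    labels : list of str
        Entity names, one per row/column.
    values : ndarray of shape (n, n)
        Pairwise similarity scores.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(
                f"similarity matrix must be square, got shape {self.values.shape}"
            )
        if self.values.shape[0] != n:
            raise ValueError(
                f"{n} labels but matrix of shape {self.values.shape}"
            )
        if len(set(self.labels)) != n:
            dupes = {x for x in self.labels if self.labels.count(x) > 1}
            raise ValueError(f"duplicate labels: {sorted(dupes)}")
        bad = ~np.isfinite(self.values) | (self.values < 0.0) | (self.values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "similarity values must be finite and in [0, 1]; "
                f"offending entry at row {self.labels[i]!r}, column {self.labels[j]!r}: "
                f"{self.values[i, j]}"
            )
        # Diagonal != 1 indicates an unusual but not invalid input: the
        # matrices are used as given, never rescaled.
        if not np.allclose(np.diag(self.values), 1.0):
            warnings.warn(
                "similarity matrix diagonal is not all 1; using values as given",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not found in similarity matrix") from None

    def to_tsv(self, path: str | Path) -> None:
        """Write as labelled TSV; round-trips bit-exactly via repr floats."""
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", float_format=None)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        if df.shape[0] != df.shape[1]:
            raise ValueError(
                f"similarity TSV {path} is not square: shape {df.shape}"
            )
        row_labels = [str(x) for x in df.index]
        col_labels = [str(x) for x in df.columns]
        if row_labels != col_labels:
            raise ValueError(
                f"row and column labels of {path} differ; first mismatch at "
                f"position {next(i for i, (a, b) in enumerate(zip(row_labels, col_labels)) if a != b)}"
            )
        return cls(labels=row_labels, values=df.to_numpy(dtype=float))


@dataclass
class AssociationTable:
    """Known (miRNA, disease) associations — the positive set P."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        dupes = []
        for p in self.pairs:
            if p in seen:
                dupes.append(p)
            seen.add(p)
        if dupes:
            raise ValueError(f"duplicate association pairs: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.pairs)

    def resolve(self, simM: SimilarityMatrix, simD: SimilarityMatrix) -> np.ndarray:
        """Map label pairs to canonical pair indices (row-major i*d + j)."""
        d = simD.n
        idx = np.empty(len(self.pairs), dtype=np.int64)
        for k, (mir, dis) in enumerate(self.pairs):
            idx[k] = simM.index_of(mir) * d + simD.index_of(dis)
        return idx

    def to_csv(self, path: str | Path, header: bool = True) -> None:
        pd.DataFrame(self.pairs, columns=["mirna", "disease"]).to_csv(
            path, index=False, header=header
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, sep: str = ",", header: bool = True
    ) -> "AssociationTable":
        df = pd.read_csv(path, sep=sep, header=0 if header else None)
        if df.shape[1] != 2:
            raise ValueError(
                f"association table {path} must have 2 columns, got {df.shape[1]}"
            )
        return cls(pairs=[(str(a), str(b)) for a, b in df.itertuples(index=False)])


@dataclass
class PairSample:
    """One (miRNA, disease) pair with its concatenated similarity profile."""

    mirna_index: int
    disease_index: int
    feature: np.ndarray


@dataclass
class SampleSets:
    """The evolving P / U partition with the screening stages.

    All sets hold canonical pair indices. ``P`` and ``U`` partition the
    full m*d grid; LP1/LN1 partition U after the k-means screen; LN2 and
    RN are the successive Rocchio refinements of LN1; RP are the reliable
    positives.
    """

    n_mirna: int
    n_disease: int
    P: np.ndarray
    U: np.ndarray
    LP1: np.ndarray | None = None
    LN1: np.ndarray | None = None
    LN2: np.ndarray | None = None
    RN: np.ndarray | None = None
    RP: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def check_invariants(self) -> None:
        total = self.n_mirna * self.n_disease
        P, U = set(self.P.tolist()), set(self.U.tolist())
        assert not (P & U), "P and U overlap"
        assert len(P) + len(U) == total, "P and U do not cover the pair grid"
        if self.LP1 is not None and self.LN1 is not None:
            LP1, LN1 = set(self.LP1.tolist()), set(self.LN1.tolist())
            assert not (LP1 & LN1), "LP1 and LN1 overlap"
            assert LP1 | LN1 == U, "LP1 and LN1 do not partition U"
        if self.LN2 is not None and self.LN1 is not None:
            assert set(self.LN2.tolist()) <= set(self.LN1.tolist()), "LN2 not within LN1"
        if self.RN is not None and self.LN2 is not None:
            assert set(self.RN.tolist()) <= set(self.LN2.tolist()), "RN not within LN2"
        if self.RP is not None and self.RN is not None:
            assert not (set(self.RP.tolist()) & set(self.RN.tolist())), "RP and RN overlap"

    def stage_frame(self, simM: SimilarityMatrix, simD: SimilarityMatrix) -> pd.DataFrame:
        """Long-format export: one row per (pair, stage) membership."""
        rows = []
        d = self.n_disease
        for stage in STAGE_NAMES:
            idx = getattr(self, stage, None)
            if idx is None:
                continue
            for k in np.sort(np.asarray(idx)):
                rows.append((simM.labels[k // d], simD.labels[k % d], stage))
        return pd.DataFrame(rows, columns=["mirna", "disease", "stage"])


def load_similarity_matrix(path: str | Path, kind: str = "mirna") -> SimilarityMatrix:
    """Load and validate a labelled TSV similarity matrix.

    ``kind`` ({'mirna', 'disease'}) only annotates error messages; both
    kinds share the same format and invariants.
    """
    if kind not in ("mirna", "disease"):
        raise ValueError(f"kind must be 'mirna' or 'disease', got {kind!r}")
    try:
        return SimilarityMatrix.from_tsv(path)
    except ValueError as e:
        raise ValueError(f"invalid {kind} similarity matrix: {e}") from e


def load_association_table(
    path: str | Path, sep: str = ",", header: bool = True
) -> AssociationTable:
    return AssociationTable.from_csv(path, sep=sep, header=header)


def build_feature_vector(
    mirna_index: int,
    disease_index: int,
    simM: SimilarityMatrix,
    simD: SimilarityMatrix,
) -> PairSample:
    """Concatenate the pair's two similarity rows into one feature vector.

    The first m entries are row ``mirna_index`` of the miRNA matrix, the
    last d entries are row ``disease_index`` of the disease matrix —
    miRNA scores always first.
    """
    if not (0 <= mirna_index < simM.n):
        raise IndexError(f"mirna_index {mirna_index} out of range [0, {simM.n})")
    if not (0 <= disease_index < simD.n):
        raise IndexError(f"disease_index {disease_index} out of range [0, {simD.n})")
    feature = np.concatenate([simM.values[mirna_index], simD.values[disease_index]])
    return PairSample(mirna_index=mirna_index, disease_index=disease_index, feature=feature)


def build_feature_matrix(
    simM: SimilarityMatrix, simD: SimilarityMatrix
) -> np.ndarray:
    """Feature vectors for all m*d pairs, row k = canonical pair index k.

    Row ``i*d + j`` is the concatenation of miRNA row i and disease row j.
    """
    m, d = simM.n, simD.n
    mir_part = np.repeat(simM.values, d, axis=0)
    dis_part = np.tile(simD.values, (m, 1))
    return np.hstack([mir_part, dis_part])


def partition_samples(
    assoc: AssociationTable, simM: SimilarityMatrix, simD: SimilarityMatrix
) -> SampleSets:
    """Split the full pair grid into positives P and unlabelled U."""
    total = simM.n * simD.n
    P = np.sort(assoc.resolve(simM, simD))
    mask = np.ones(total, dtype=bool)
    mask[P] = False
    U = np.flatnonzero(mask)
    sets = SampleSets(n_mirna=simM.n, n_disease=simD.n, P=P, U=U)
    sets.check_invariants()
    return sets


def features_for(indices: Iterable[int], X: np.ndarray) -> np.ndarray:
    """Rows of the full feature matrix for the given pair indices."""
    return X[np.asarray(list(indices) if not isinstance(indices, np.ndarray) else indices)]
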