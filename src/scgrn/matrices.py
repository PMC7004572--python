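"""Count/expression containers, readers, and preprocessing.

Single-cell UMI data is held as a cells x genes integer matrix; the only
transforms applied before network inference are removal of zero-variance
genes and ``log2(x + 1)`` scaling.  Library-size normalization and batch
depth equalization are deliberately *not* part of this pipeline: the
latent-activity model downstream absorbs scale through per-task scaling.
All matrices align by identifier, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

METADATA_COLUMNS = ("condition", "genotype", "replicate_barcode")


class MatrixParseError(ValueError):
    """A file could not be parsed into a matrix."""


class MatrixValidationError(ValueError):
    """Parsed values violate a container invariant."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate {what} identifiers: {dups[:5]}")


@dataclass
class CountMatrix:
    """Cells x genes matrix of non-negative integer UMI counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "cell")
        _check_unique(self.data.columns, "gene")
        values = self.data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                    raise MatrixValidationError("counts must be integers")
                self.data = self.data.astype(np.int64)
                values = self.data.to_numpy()
            if np.any(values < 0):
                raise MatrixValidationError("counts must be non-negative")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="cell_id")


@dataclass
class ExpressionMatrix:
    """Cells x genes real-valued expression (log2 units)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "cell")
        _check_unique(self.data.columns, "gene")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise MatrixValidationError("expression values must be finite")
        self.data = self.data.astype(float)

    cell_ids = CountMatrix.cell_ids
    gene_ids = CountMatrix.gene_ids
    values = CountMatrix.values
    shape = CountMatrix.shape

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="cell_id")


@dataclass
class CellMetadata:
    """Per-cell annotation: condition, genotype, replicate barcode.

    Indexed by cell id; any subset of the three columns may be present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "cell")
        unknown = [c for c in self.data.columns if c not in METADATA_COLUMNS]
        if unknown:
            raise MatrixValidationError(f"unknown metadata columns: {unknown}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.index)

    def check_paired(self, counts: CountMatrix | ExpressionMatrix) -> None:
        missing = [c for c in counts.cell_ids if c not in self.data.index]
        if missing:
            raise MatrixValidationError(
                f"{len(missing)} cells lack metadata (first: {missing[:5]})"
            )

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="cell_id")


@dataclass
class Task:
    """One condition's expression slice for multitask inference."""

    name: str
    expression: ExpressionMatrix

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]


@dataclass
class TaskSet:
    tasks: list[Task]

    def __iter__(self):
        return iter(self.tasks)

    def __len__(self) -> int:
        return len(self.tasks)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tasks]


def read_count_matrix(
    path: str | Path,
    fmt: str = "dense-tsv",
    barcodes_path: str | Path | None = None,
    features_path: str | Path | None = None,
) -> tuple[CountMatrix, CellMetadata | None]:
    """Read a cells x genes count matrix.

    ``dense-tsv``: tab-separated, first column cell id, header row gene ids.
    Metadata columns (condition/genotype/replicate_barcode), if present, are
    split off into a :class:`CellMetadata`.

    ``triplet``: MatrixMarket coordinate file with sidecar ``barcodes.tsv``
    (cell ids, rows) and ``features.tsv`` (gene ids, columns) in the same
    directory unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "dense-tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise MatrixParseError(f"cannot parse {path}: {exc}") from exc
        if df.columns.has_duplicates or df.columns.isnull().any():
            raise MatrixParseError(f"malformed header line in {path}: {list(df.columns)[:8]}")
        df.index.name = None
        meta_cols = [c for c in df.columns if c in METADATA_COLUMNS]
        meta = None
        if meta_cols:
            meta = CellMetadata(df[meta_cols].copy())
            df = df.drop(columns=meta_cols)
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if bad:
            raise MatrixParseError(f"non-numeric count column(s) {bad[:5]} in {path}")
        return CountMatrix(df), meta
    if fmt == "triplet":
        barcodes = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        features = Path(features_path) if features_path else path.parent / "features.tsv"
        for side in (barcodes, features):
            if not side.exists():
                raise FileNotFoundError(f"missing sidecar file {side}")
        cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
        gene_ids = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
        try:
            mat = mmread(str(path)).toarray()
        except Exception as exc:
            raise MatrixParseError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise MatrixParseError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(cell_ids)} cells, {len(gene_ids)} genes)"
            )
        df = pd.DataFrame(mat, index=cell_ids, columns=gene_ids)
        return CountMatrix(df), None
    raise ValueError(f"unknown format {fmt!r}; expected 'dense-tsv' or 'triplet'")


def read_metadata(path: str | Path) -> CellMetadata:
    df = pd.read_csv(path, sep="\t", index_col="cell_id", dtype=str)
    return CellMetadata(df)


def filter_zero_variance(m: CountMatrix | ExpressionMatrix):
    """Drop genes with zero variance across cells; gene order preserved."""
    values = m.data.to_numpy(dtype=float)
    if values.shape[0] < 1:
        raise MatrixValidationError("need at least one cell")
    keep = values.var(axis=0) > 0
    if not keep.any():
        raise MatrixValidationError("no variable genes")
    if keep.all():
        return type(m)(m.data.copy())
    return type(m)(m.data.loc[:, m.data.columns[keep]].copy())


def log_transform(m: CountMatrix) -> ExpressionMatrix:
    """log2(x + 1) scaling of UMI counts."""
    if not isinstance(m, CountMatrix):
        raise TypeError("log_transform operates on raw counts")
    return ExpressionMatrix(np.log2(m.data.astype(float) + 1.0))


def pseudobulk_aggregate(
    m: CountMatrix, meta: CellMetadata, keys: Sequence[str]
) -> CountMatrix:
    """Sum raw UMI counts over cells sharing a metadata key combination.

    One output row per observed combination (e.g. genotype x replicate within
    a condition yields 72 pseudobulk samples for 12 genotypes x 6 replicates);
    the grand total of counts is conserved exactly.
    """
    if not isinstance(m, CountMatrix):
        raise TypeError("pseudobulk summation is defined on raw counts only")
    missing = [k for k in keys if k not in meta.data.columns]
    if missing:
        raise KeyError(f"metadata keys not present: {missing}")
    meta.check_paired(m)
    labels = meta.data.loc[m.data.index, list(keys)].astype(str)
    group = labels.agg("|".join, axis=1)
    summed = m.data.groupby(group, sort=True).sum()
    summed.index.name = "sample_id"
    return CountMatrix(summed)


def split_tasks(x: ExpressionMatrix, meta: CellMetadata) -> TaskSet:
    """Partition cells into one task per growth condition."""
    meta.check_paired(x)
    if "condition" not in meta.data.columns:
        raise MatrixValidationError("metadata lacks a 'condition' column")
    cond = meta.data.loc[x.data.index, "condition"]
    unlabeled = cond.index[cond.isna()].tolist()
    if unlabeled:
        raise MatrixValidationError(f"cells without condition label: {unlabeled[:5]}")
    tasks = []
    for name in sorted(cond.unique()):
        cells = cond.index[cond == name]
        tasks.append(Task(str(name), ExpressionMatrix(x.data.loc[cells].copy())))
    return TaskSet(tasks)
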