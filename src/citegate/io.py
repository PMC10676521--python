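"""Readers and writers for count matrices and ADT vectors.

Supported count formats:

``mtx10x``
    A 10x-style directory triplet: ``matrix.mtx[.gz]`` plus
    ``features.tsv[.gz]`` or ``genes.tsv[.gz]`` plus ``barcodes.tsv[.gz]``.
    On disk the matrix is genes x cells; it is transposed on read.
``csv`` / ``tsv``
    Dense table with a header row and an index column. Orientation is taken
    from the index name: ``gene``-like names mean genes-on-rows,
    ``barcode``/``cell``-like names mean cells-on-rows. Without a recognised
    index name rows are assumed to be cells; pass ``orientation`` to override.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import AdtVector, CountMatrix, ValidationError

_GENE_ROW_NAMES = {"gene", "genes", "gene_id", "gene_ids", "symbol", "symbols", "feature", "features"}
_CELL_ROW_NAMES = {"cell", "cells", "barcode", "barcodes", "cell_id", "cell_ids"}


def _find_member(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {stems} (optionally .gz) found in {directory}"
    )


def _read_tsv_column(path: Path, column: int = 0) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if column >= df.shape[1]:
        column = df.shape[1] - 1
    return df.iloc[:, column].to_numpy(dtype=object)


def read_counts(path, format: str = "mtx10x", orientation: str = "auto") -> CountMatrix:
    """Read a raw count matrix, normalising orientation to cells x genes.

    Parameters
    ----------
    path
        Directory (``mtx10x``) or file (``csv``/``tsv``).
    format
        One of ``mtx10x``, ``csv``, ``tsv``.
    orientation
        For dense tables: ``auto`` (infer from the index name),
        ``cells_by_genes`` or ``genes_by_cells``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if format == "mtx10x":
        matrix_path = _find_member(path, ["matrix.mtx"])
        features_path = _find_member(path, ["features.tsv", "genes.tsv"])
        barcodes_path = _find_member(path, ["barcodes.tsv"])
        mat = scipy.io.mmread(str(matrix_path))  # genes x cells on disk
        features_df = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
        # v3 features.tsv: id / symbol / type; legacy genes.tsv: id / symbol
        gene_col = 1 if features_df.shape[1] > 1 else 0
        genes = features_df.iloc[:, gene_col].to_numpy(dtype=object)
        barcodes = _read_tsv_column(barcodes_path)
        counts = sp.csr_matrix(mat).T
        return CountMatrix(counts, genes, barcodes)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        index_name = (df.index.name or "").strip().lower()
        if orientation == "auto":
            if index_name in _GENE_ROW_NAMES:
                orientation = "genes_by_cells"
            elif index_name in _CELL_ROW_NAMES:
                orientation = "cells_by_genes"
            else:
                orientation = "cells_by_genes"
        if orientation == "genes_by_cells":
            df = df.T
        elif orientation != "cells_by_genes":
            raise ValueError(f"unknown orientation: {orientation!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError(f"non-numeric entries in {path}")
        return CountMatrix(
            sp.csr_matrix(values),
            df.columns.to_numpy(dtype=object),
            df.index.to_numpy(dtype=object),
        )
    raise ValueError(f"unknown format: {format!r}")


def write_counts(m: CountMatrix, path, format: str = "mtx10x") -> None:
    """Write a count matrix in a format :func:`read_counts` round-trips."""
    path = Path(path)
    if format == "mtx10x":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), m.counts.T.tocoo())
        genes = pd.DataFrame({0: m.gene_ids, 1: m.gene_ids})
        genes.to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
        return
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(m.dense(), index=m.cell_ids.astype(str), columns=m.gene_ids.astype(str))
        df.index.name = "barcode"
        df.to_csv(path, sep=sep)
        return
    raise ValueError(f"unknown format: {format!r}")


def read_adt(path, column: str | None = None) -> AdtVector:
    """Read a per-cell ADT level from a barcode-keyed CSV.

    The file must have a header; the first column is the barcode, the ADT
    level is taken from ``column`` or, when omitted, the first value column.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"no value column in {path}")
    series = df[column] if column is not None else df.iloc[:, 0]
    return AdtVector(series.to_numpy(dtype=float), df.index.to_numpy(dtype=object))


def write_adt(adt: AdtVector, path, column: str = "adt") -> None:
    df = pd.DataFrame({column: adt.values}, index=adt.cell_ids.astype(str))
    df.index.name = "barcode"
    df.to_csv(path)
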