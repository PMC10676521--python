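"""Core data containers for count matrices, ADT vectors and QC reporting.

Conventions used throughout the package:

* count matrices are oriented **cells x genes** in memory, whatever the
  on-disk orientation was;
* gene identifiers are HGNC-style symbols, cell identifiers are barcodes;
* raw counts are non-negative integers (UMI counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """Input data violates a container invariant."""


def _as_str_array(ids: Iterable[str], what: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{what} must be one-dimensional")
    return arr


def _check_unique(ids: np.ndarray, what: str) -> None:
    values, counts = np.unique(ids.astype(str), return_counts=True)
    dups = values[counts > 1]
    if dups.size:
        raise ValidationError(f"duplicate {what}: {dups[0]!r}")


@dataclass
class CountMatrix:
    """Sparse cells x genes matrix of raw UMI counts.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells on rows, genes on columns.
        Any scipy sparse matrix or dense array is accepted and stored as CSR.
    gene_ids, cell_ids
        Unique gene symbols / cell barcodes aligned with the matrix axes.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        n_cells, n_genes = self.counts.shape
        if n_genes != self.gene_ids.size:
            raise ValidationError(
                f"matrix has {n_genes} gene columns but {self.gene_ids.size} gene_ids"
            )
        if n_cells != self.cell_ids.size:
            raise ValidationError(
                f"matrix has {n_cells} cell rows but {self.cell_ids.size} cell_ids"
            )
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.cell_ids, "cell_ids")
        data = self.counts.data
        if data.size:
            bad = np.flatnonzero((data < 0) | (data != np.round(data)))
            if bad.size:
                coo = self.counts.tocoo()
                i, j, v = coo.row[bad[0]], coo.col[bad[0]], coo.data[bad[0]]
                raise ValidationError(
                    f"count entry must be a non-negative integer; first offender: "
                    f"cell {self.cell_ids[i]!r}, gene {self.gene_ids[j]!r}, value {v!r}"
                )
        self.counts.data = self.counts.data.astype(np.int64)

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=np.int64)

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.counts[mask], self.gene_ids, self.cell_ids[mask])

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.counts[:, mask], self.gene_ids[mask], self.cell_ids)

    def gene_index(self, symbols: Sequence[str]) -> dict[str, int]:
        """Map each requested symbol to its column, skipping absent ones."""
        lookup = {g: i for i, g in enumerate(self.gene_ids.astype(str))}
        return {s: lookup[s] for s in symbols if s in lookup}

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy().astype(np.float32),
            obs=pd.DataFrame(index=self.cell_ids.astype(str)),
            var=pd.DataFrame(index=self.gene_ids.astype(str)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.gene_ids.astype(str), other.gene_ids.astype(str))
            and np.array_equal(self.cell_ids.astype(str), other.cell_ids.astype(str))
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class AdtVector:
    """Per-cell normalized, log-transformed antibody-derived-tag level."""

    values: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        if self.values.size != self.cell_ids.size:
            raise ValidationError("ADT values and cell_ids differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ADT values must be finite")
        _check_unique(self.cell_ids, "cell_ids")

    def align_to(self, cell_ids: Sequence[str]) -> "AdtVector":
        """Reorder/subset to the given barcodes (all must be present)."""
        order = pd.Series(np.arange(self.cell_ids.size), index=self.cell_ids.astype(str))
        wanted = pd.Index(np.asarray(cell_ids, dtype=str))
        missing = wanted.difference(order.index)
        if len(missing):
            raise ValidationError(f"barcodes missing from ADT vector: {list(missing[:5])}")
        idx = order.loc[wanted].to_numpy()
        return AdtVector(self.values[idx], wanted.to_numpy())


@dataclass
class QcReport:
    """Record of which filter removed what, in the order applied."""

    stages: list = field(default_factory=list)

    def add(self, name: str, *, n_cells_in: int, n_cells_out: int,
            n_genes_in: int, n_genes_out: int, params: dict | None = None,
            detail: dict | None = None) -> None:
        self.stages.append(
            {
                "name": name,
                "n_cells_in": int(n_cells_in),
                "n_cells_out": int(n_cells_out),
                "n_cells_removed": int(n_cells_in - n_cells_out),
                "n_genes_in": int(n_genes_in),
                "n_genes_out": int(n_genes_out),
                "n_genes_removed": int(n_genes_in - n_genes_out),
                "params": params or {},
                "detail": detail or {},
            }
        )

    def merged(self, other: "QcReport") -> "QcReport":
        return QcReport(stages=self.stages + other.stages)

    @property
    def stage_names(self) -> list[str]:
        return [s["name"] for s in self.stages]

    def to_json(self, path=None) -> str:
        text = json.dumps({"stages": self.stages}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
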