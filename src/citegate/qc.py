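"""T-cell gating and cell/gene quality-control filters.

The gating rule keeps cells that express at least one CD3-complex gene
(CD3D/CD3E/CD3G/CD247) and do not express the B-cell marker CD19; "express"
means raw UMI count > 0. Cell filters then drop cells whose ribosomal-gene
fraction of total counts is below 5%, and finally genes detected in fewer
than two cells are removed. The order gate -> cell filters -> gene filter is
part of the contract and is recorded in the QcReport.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

from .containers import CountMatrix, QcReport

DEFAULT_CD3_GENES = ("CD3D", "CD3E", "CD3G", "CD247")
DEFAULT_EXCLUSION_GENE = "CD19"
#: accepted aliases resolved before lookup
GENE_ALIASES = {"CD3Z": "CD247"}
RIBO_REGEX = r"^RP[SL]"
MITO_REGEX = r"^MT-"


class QcError(ValueError):
    pass


def _resolve(symbols, gene_ids) -> tuple[list[int], list[str]]:
    lookup = {g.upper(): i for i, g in enumerate(np.asarray(gene_ids, dtype=str))}
    idx, missing = [], []
    for s in symbols:
        key = GENE_ALIASES.get(s.upper(), s.upper())
        if key in lookup:
            idx.append(lookup[key])
        else:
            missing.append(s)
    return idx, missing


def gate_t_cells(
    m: CountMatrix,
    cd3_genes=DEFAULT_CD3_GENES,
    exclusion_gene: str = DEFAULT_EXCLUSION_GENE,
) -> tuple[CountMatrix, QcReport]:
    """Keep cells with any CD3-complex expression and no CD19 expression."""
    cd3_idx, cd3_missing = _resolve(cd3_genes, m.gene_ids)
    excl_idx, excl_missing = _resolve([exclusion_gene], m.gene_ids)
    missing = cd3_missing + excl_missing
    if missing:
        warnings.warn(f"gating genes not found in matrix: {missing}", stacklevel=2)
    if cd3_idx:
        cd3_pos = np.asarray((m.counts[:, cd3_idx] > 0).sum(axis=1)).ravel() > 0
    else:
        cd3_pos = np.ones(m.n_cells, dtype=bool)
    if excl_idx:
        excl_neg = np.asarray(m.counts[:, excl_idx].todense()).ravel() == 0
    else:
        excl_neg = np.ones(m.n_cells, dtype=bool)
    keep = cd3_pos & excl_neg
    if not keep.any():
        raise QcError("T-cell gate removed every cell; review gating gene list")
    out = m.subset_cells(keep)
    report = QcReport()
    report.add(
        "gate_t_cells",
        n_cells_in=m.n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=m.n_genes,
        n_genes_out=out.n_genes,
        params={"cd3_genes": list(cd3_genes), "exclusion_gene": exclusion_gene},
        detail={
            "missing_genes": missing,
            "removed_no_cd3": int((~cd3_pos).sum()),
            "removed_exclusion_positive": int((cd3_pos & ~excl_neg).sum()),
        },
    )
    return out, report


def filter_cells_genes(
    m: CountMatrix,
    min_ribo_frac: float = 0.05,
    min_cells_per_gene: int = 2,
    ribo_regex: str = RIBO_REGEX,
    min_counts: int | None = None,
    max_mito_frac: float | None = None,
    mito_regex: str = MITO_REGEX,
) -> tuple[CountMatrix, QcReport]:
    """Drop low-ribosomal-fraction cells, then rarely detected genes.

    ``min_counts`` (library-size floor, e.g. 1000) and ``max_mito_frac``
    (mitochondrial fraction ceiling, e.g. 0.2) are optional, off by default:
    they mirror upstream-provider filters and are only needed for raw data.
    """
    report = QcReport()
    genes = np.asarray(m.gene_ids, dtype=str)
    ribo_mask = np.array([bool(re.match(ribo_regex, g, re.IGNORECASE)) for g in genes])
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    ribo_counts = (
        np.asarray(m.counts[:, ribo_mask].sum(axis=1)).ravel().astype(float)
        if ribo_mask.any()
        else np.zeros(m.n_cells)
    )
    nonzero = totals > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ribo_frac = np.where(nonzero, ribo_counts / np.where(nonzero, totals, 1.0), np.nan)
    keep = nonzero & (ribo_frac >= min_ribo_frac)
    detail = {
        "removed_zero_library_size": int((~nonzero).sum()),
        "removed_low_ribo_frac": int((nonzero & ~keep).sum()),
        "n_ribo_genes": int(ribo_mask.sum()),
    }
    if min_counts is not None:
        low = totals < min_counts
        detail["removed_low_counts"] = int((keep & low).sum())
        keep &= ~low
    if max_mito_frac is not None:
        mito_mask = np.array([bool(re.match(mito_regex, g, re.IGNORECASE)) for g in genes])
        mito = (
            np.asarray(m.counts[:, mito_mask].sum(axis=1)).ravel().astype(float)
            if mito_mask.any()
            else np.zeros(m.n_cells)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(nonzero, mito / np.where(nonzero, totals, 1.0), 1.0)
        high = mito_frac > max_mito_frac
        detail["removed_high_mito_frac"] = int((keep & high).sum())
        keep &= ~high
    if not keep.any():
        raise QcError("cell filters removed every cell; review thresholds")
    cells_kept = m.subset_cells(keep)
    report.add(
        "filter_cells",
        n_cells_in=m.n_cells,
        n_cells_out=cells_kept.n_cells,
        n_genes_in=m.n_genes,
        n_genes_out=cells_kept.n_genes,
        params={
            "min_ribo_frac": min_ribo_frac,
            "min_counts": min_counts,
            "max_mito_frac": max_mito_frac,
        },
        detail=detail,
    )
    # gene filter runs after the cell filter by contract
    detected_in = np.asarray((cells_kept.counts > 0).sum(axis=0)).ravel()
    gene_keep = detected_in >= min_cells_per_gene
    out = cells_kept.subset_genes(gene_keep)
    report.add(
        "filter_genes",
        n_cells_in=cells_kept.n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=cells_kept.n_genes,
        n_genes_out=out.n_genes,
        params={"min_cells_per_gene": min_cells_per_gene},
    )
    return out, report


def apply_qc(
    m: CountMatrix,
    cd3_genes=DEFAULT_CD3_GENES,
    exclusion_gene: str = DEFAULT_EXCLUSION_GENE,
    min_ribo_frac: float = 0.05,
    min_cells_per_gene: int = 2,
    **kwargs,
) -> tuple[CountMatrix, QcReport]:
    """Full QC chain: T-cell gate, then cell filters, then gene filter."""
    gated, r1 = gate_t_cells(m, cd3_genes=cd3_genes, exclusion_gene=exclusion_gene)
    out, r2 = filter_cells_genes(
        gated,
        min_ribo_frac=min_ribo_frac,
        min_cells_per_gene=min_cells_per_gene,
        **kwargs,
    )
    return out, r1.merged(r2)
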