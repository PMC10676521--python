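"""Classifier feature assembly: DE thresholds plus splicing-factor correlation.

Two feature sources are combined:

* differentially expressed genes whose BH q-value is below 0.05 and whose
  log2 fold change clears the tunable thresholds (``t_de_upper`` for genes
  up in marker-negative cells, ``t_de_lower`` for genes up in positives);
* genes whose normalized expression rank-correlates with an anchor gene —
  by default HNRNPLL, the splicing factor controlling CD45RA exon usage —
  with |rho| in the top ``p_hn`` fraction and a raw Spearman p < 0.05.

Both thresholds are hyperparameters tuned jointly with the classifier.
Feature selection must only ever see training cells; the orchestrator
enforces this.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DeResult
from .preprocess import NormMatrix

DEFAULT_ANCHOR = "HNRNPLL"
DE_Q_CUTOFF = 0.05
CORR_P_CUTOFF = 0.05


class FeatureSelectionError(ValueError):
    pass


@dataclass
class CorrResult:
    """Spearman correlation of every gene with the anchor gene."""

    table: pd.DataFrame  # gene, rho, p_value, abs_rank_quantile
    anchor: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def spearman_with_anchor(values: np.ndarray, anchor_col: np.ndarray):
    """Vectorised Spearman rho (average-rank ties) and two-sided t-approx p.

    ``values`` is cells x genes; returns (rho, p) arrays. Constant columns
    get rho = 0, p = 1.
    """
    n = values.shape[0]
    ranks = stats.rankdata(values, axis=0)
    anchor_ranks = stats.rankdata(anchor_col)
    rc = ranks - ranks.mean(axis=0, keepdims=True)
    ac = anchor_ranks - anchor_ranks.mean()
    denom = np.sqrt((rc**2).sum(axis=0) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rc.T @ ac / np.where(denom > 0, denom, 1.0), 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(denom > 0, p, 1.0)
    return rho, p


def spearman_screen(
    nm: NormMatrix,
    anchor: str = DEFAULT_ANCHOR,
    p_hn: float = 0.05,
) -> tuple[CorrResult, list[str]]:
    """Rank-correlation screen against the anchor gene.

    Selected genes (anchor excluded) have |rho| in the top ``p_hn`` fraction
    of tested genes — descending-rank quantile rank/n <= p_hn — and a raw
    two-sided p < 0.05.
    """
    if not (0 < p_hn < 1):
        raise ValueError("p_hn must be in (0, 1)")
    genes = np.asarray(nm.gene_ids, dtype=str)
    anchor_idx = np.flatnonzero(genes == anchor)
    if anchor_idx.size == 0:
        near = difflib.get_close_matches(anchor, list(genes), n=3)
        raise KeyError(f"anchor gene {anchor!r} not in matrix; close matches: {near}")
    anchor_col = nm.values[:, anchor_idx[0]]
    if np.ptp(anchor_col) == 0:
        raise FeatureSelectionError(f"anchor gene {anchor!r} has constant expression")
    rho, p = spearman_with_anchor(nm.values, anchor_col)

    is_anchor = genes == anchor
    tested = ~is_anchor
    n_tested = int(tested.sum())
    # descending rank of |rho| among tested genes: 1 = strongest
    order = np.argsort(-np.abs(rho[tested]), kind="stable")
    rank = np.empty(n_tested)
    rank[order] = np.arange(1, n_tested + 1)
    quantile = np.full(genes.size, np.nan)
    quantile[tested] = rank / n_tested

    table = pd.DataFrame(
        {"gene": genes, "rho": rho, "p_value": p, "abs_rank_quantile": quantile}
    )
    selected_mask = tested & (quantile <= p_hn) & (p < CORR_P_CUTOFF)
    sel = table[selected_mask].copy()
    sel = sel.iloc[np.lexsort((sel["gene"].to_numpy(), -np.abs(sel["rho"].to_numpy())))]
    return CorrResult(table=table, anchor=anchor), sel["gene"].tolist()


@dataclass
class FeatureSet:
    """Ordered classifier gene list with per-gene provenance."""

    genes: list
    provenance: dict = field(default_factory=dict)  # gene -> {"de","corr","both"}
    t_de_upper: float = np.nan
    t_de_lower: float = np.nan
    p_hn: float = np.nan

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("feature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def to_json(self, path=None) -> str:
        payload = {
            "genes": list(self.genes),
            "provenance": dict(self.provenance),
            "t_de_upper": float(self.t_de_upper),
            "t_de_lower": float(self.t_de_lower),
            "p_hn": float(self.p_hn),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FeatureSet":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            genes=payload["genes"],
            provenance=payload["provenance"],
            t_de_upper=payload["t_de_upper"],
            t_de_lower=payload["t_de_lower"],
            p_hn=payload["p_hn"],
        )


def select_de_genes(de: DeResult, t_de_upper: float, t_de_lower: float) -> list[str]:
    """DE genes with q < 0.05 whose log2FC clears either threshold, ordered by |log2FC| desc."""
    t = de.table
    lfc = t["log2fc"].to_numpy(dtype=float)
    q = t["q_value"].to_numpy(dtype=float)
    conv = t["converged"].to_numpy(dtype=bool)
    with np.errstate(invalid="ignore"):
        mask = conv & (q < DE_Q_CUTOFF) & (
            np.nan_to_num(lfc, nan=0.0, posinf=np.inf, neginf=-np.inf) >= t_de_upper
        ) | (
            conv & (q < DE_Q_CUTOFF)
            & (np.nan_to_num(lfc, nan=0.0, posinf=np.inf, neginf=-np.inf) <= t_de_lower)
        )
    sel = t[mask]
    genes = sel["gene"].to_numpy(dtype=str)
    abs_lfc = np.abs(sel["log2fc"].to_numpy(dtype=float))
    order = np.lexsort((genes, -abs_lfc))
    return [str(g) for g in genes[order]]


def select_features(
    de: DeResult,
    corr: CorrResult,
    t_de_upper: float,
    t_de_lower: float,
    p_hn: float,
) -> FeatureSet:
    """Union of DE-threshold genes and anchor-correlated genes.

    Ordering is deterministic: DE genes by |log2FC| descending, then
    correlation genes by |rho| descending, lexicographic ties.
    """
    if not (t_de_upper > 0 > t_de_lower):
        raise ValueError("need t_de_upper > 0 > t_de_lower")
    de_genes = select_de_genes(de, t_de_upper, t_de_lower)

    t = corr.table
    tested = t["gene"].to_numpy(dtype=str) != corr.anchor
    quant = t["abs_rank_quantile"].to_numpy(dtype=float)
    p = t["p_value"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        cmask = tested & (quant <= p_hn) & (p < CORR_P_CUTOFF)
    csel = t[cmask]
    cg = csel["gene"].to_numpy(dtype=str)
    corder = np.lexsort((cg, -np.abs(csel["rho"].to_numpy(dtype=float))))
    corr_genes = [str(g) for g in cg[corder]]

    de_set, corr_set = set(de_genes), set(corr_genes)
    genes = de_genes + [g for g in corr_genes if g not in de_set]
    if not genes:
        raise FeatureSelectionError("no features at these thresholds")
    provenance = {
        g: ("both" if (g in de_set and g in corr_set) else ("de" if g in de_set else "corr"))
        for g in genes
    }
    return FeatureSet(
        genes=genes,
        provenance=provenance,
        t_de_upper=float(t_de_upper),
        t_de_lower=float(t_de_lower),
        p_hn=float(p_hn),
    )
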