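"""Variance-stabilising normalization, covariate regression and HVG selection.

The normalization contract is a negative-binomial Pearson-residual transform
with a log-library-size offset:

* per-gene rate ``p_g`` = mean over cells of ``y_cg / L_c`` (library-size
  L_c; scale-equivariant in any one cell's library);
* expected counts ``mu_cg = L_c * p_g``;
* per-gene dispersion ``phi_g`` by method of moments on the full residuals,
  ``phi = max(0, sum((y-mu)^2 - mu) / sum(mu^2))``;
* residual ``r = (y - mu) / sqrt(mu + phi*mu^2)``, clipped at ±sqrt(n_cells);
* nuisance covariates (mitochondrial fraction, S-minus-G2M cell-cycle score)
  regressed out of each gene's residual vector by ordinary least squares.

``corrected_counts`` invert the (regressed) residual at the median library
size, floored at zero and rounded half-to-even, giving a count-scale matrix
for the GLM stage. Full parity with any particular reference normalization
implementation is a non-goal; the analytic transform above is what the rest
of the pipeline is defined against.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .containers import CountMatrix
from .qc import MITO_REGEX


def _load_gene_list(name: str) -> list[str]:
    text = resources.files("citegate.data").joinpath(name).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def default_s_genes() -> list[str]:
    """The standard 43 S-phase human gene symbols."""
    return _load_gene_list("s_genes.txt")


def default_g2m_genes() -> list[str]:
    """The standard 54 G2M-phase human gene symbols."""
    return _load_gene_list("g2m_genes.txt")


@dataclass
class CellCovariates:
    """Per-cell nuisance covariates regressed out during normalization."""

    mito_frac: np.ndarray
    s_score: np.ndarray
    g2m_score: np.ndarray

    @property
    def cc_diff(self) -> np.ndarray:
        return self.s_score - self.g2m_score

    def get(self, name: str) -> np.ndarray:
        if name == "mito_frac":
            return self.mito_frac
        if name == "cc_diff":
            return self.cc_diff
        raise KeyError(f"unknown covariate {name!r}; expected 'mito_frac' or 'cc_diff'")


def cell_cycle_score(
    m: CountMatrix,
    s_genes: list[str] | None = None,
    g2m_genes: list[str] | None = None,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    mito_regex: str = MITO_REGEX,
) -> CellCovariates:
    """Cell-cycle scores via expression-bin-matched control gene sets.

    Each score is the mean log-normalized expression of the phase gene set
    minus the mean of ``n_ctrl`` control genes drawn per set gene from the
    same average-expression bin (of ``n_bins`` bins). Scoring is delegated to
    :func:`scanpy.tl.score_genes`. Sets with fewer than 5 genes present in
    the matrix get a zero score with a warning.
    """
    import scanpy as sc

    s_genes = default_s_genes() if s_genes is None else list(s_genes)
    g2m_genes = default_g2m_genes() if g2m_genes is None else list(g2m_genes)

    adata = m.to_anndata()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)

    n = m.n_cells
    scores = {}
    for score_name, gene_list in (("s_score", s_genes), ("g2m_score", g2m_genes)):
        present = [g for g in gene_list if g in adata.var_names]
        if len(present) < 5:
            warnings.warn(
                f"only {len(present)} of {len(gene_list)} {score_name} genes found; "
                "score set to 0",
                stacklevel=2,
            )
            scores[score_name] = np.zeros(n)
            continue
        sc.tl.score_genes(
            adata,
            gene_list=present,
            ctrl_size=n_ctrl,
            n_bins=n_bins,
            score_name=score_name,
            random_state=seed,
        )
        scores[score_name] = adata.obs[score_name].to_numpy(dtype=float)

    genes = np.asarray(m.gene_ids, dtype=str)
    mito_mask = np.array([bool(re.match(mito_regex, g, re.IGNORECASE)) for g in genes])
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    mito = (
        np.asarray(m.counts[:, mito_mask].sum(axis=1)).ravel().astype(float)
        if mito_mask.any()
        else np.zeros(n)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.where(totals > 0, totals, 1.0), 0.0)
    return CellCovariates(mito_frac=mito_frac, s_score=scores["s_score"],
                          g2m_score=scores["g2m_score"])


@dataclass
class NormParams:
    """Per-gene normalization parameters, reusable on query data at inference."""

    gene_ids: np.ndarray
    rate: np.ndarray        # expected counts per unit library size
    phi: np.ndarray         # NB dispersion, Var = mu + phi*mu^2
    median_library: float
    clip: float

    def to_dict(self) -> dict:
        return {
            "gene_ids": [str(g) for g in self.gene_ids],
            "rate": self.rate.tolist(),
            "phi": self.phi.tolist(),
            "median_library": float(self.median_library),
            "clip": float(self.clip),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormParams":
        return cls(
            gene_ids=np.asarray(d["gene_ids"], dtype=object),
            rate=np.asarray(d["rate"], dtype=float),
            phi=np.asarray(d["phi"], dtype=float),
            median_library=float(d["median_library"]),
            clip=float(d["clip"]),
        )


@dataclass
class NormMatrix:
    """Variance-stabilized, covariate-regressed expression (cells x genes).

    ``hvg_variance`` holds each gene's residual variance computed under a
    *common* (median) dispersion: per-gene dispersion standardises every
    gene's residual variance towards 1, which is what the downstream
    classifier wants but would erase the excess variability that
    highly-variable-gene ranking looks for.
    """

    values: np.ndarray
    corrected_counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    params: NormParams
    regressed: list = field(default_factory=list)
    hvg_variance: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_column(self, symbol: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.gene_ids, dtype=str) == symbol)
        if idx.size == 0:
            raise KeyError(symbol)
        return self.values[:, idx[0]]


def fit_norm_params(m: CountMatrix, clip: float | None = None) -> NormParams:
    """Estimate per-gene rate and dispersion for the residual transform."""
    y = m.dense().astype(float)
    lib = y.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("cells with zero library size must be filtered before normalization")
    rate = (y / lib[:, None]).mean(axis=0)
    mu = lib[:, None] * rate[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((y - mu) ** 2 - mu).sum(axis=0)
        den = (mu**2).sum(axis=0)
        phi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    phi = np.clip(phi, 0.0, 1e6)
    if clip is None:
        clip = float(np.sqrt(m.n_cells))
    return NormParams(
        gene_ids=np.asarray(m.gene_ids, dtype=object),
        rate=rate,
        phi=phi,
        median_library=float(np.median(lib)),
        clip=clip,
    )


def residual_transform(counts: np.ndarray, library: np.ndarray, params: NormParams) -> np.ndarray:
    """Clipped NB Pearson residuals under stored parameters.

    With stored parameters, each cell's residuals depend only on its own
    counts and library size, so rescaling one cell never moves another.
    """
    mu = library[:, None] * params.rate[None, :]
    sd = np.sqrt(mu + params.phi[None, :] * mu**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sd > 0, (counts - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return np.clip(r, -params.clip, params.clip)


def _regress_out(values: np.ndarray, covariates: list[tuple[str, np.ndarray]]) -> np.ndarray:
    kept = []
    for name, c in covariates:
        if np.ptp(c) == 0:
            warnings.warn(f"covariate {name!r} is constant; regression skipped", stacklevel=3)
            continue
        kept.append(c)
    if not kept:
        return values
    design = np.column_stack([np.ones(values.shape[0])] + kept)
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def normalize_regress(
    m: CountMatrix,
    cov: CellCovariates | None = None,
    regress: tuple[str, ...] = ("mito_frac", "cc_diff"),
    params: NormParams | None = None,
) -> NormMatrix:
    """Residual transform plus OLS removal of nuisance covariates.

    When ``params`` is given (inference on query data) the stored per-gene
    rate/dispersion are reused; covariates are only regressed when supplied.
    """
    if params is None:
        params = fit_norm_params(m)
    y = m.dense().astype(float)
    lib = y.sum(axis=1)
    r = residual_transform(y, lib, params)
    if cov is not None and regress:
        r = _regress_out(r, [(name, cov.get(name)) for name in regress])
        regressed = [name for name in regress if np.ptp(cov.get(name)) != 0]
    else:
        regressed = []
    mu_med = params.median_library * params.rate
    sd_med = np.sqrt(mu_med + params.phi * mu_med**2)
    corrected = np.maximum(mu_med[None, :] + r * sd_med[None, :], 0.0)
    corrected = np.round(corrected)  # numpy rounds half to even

    # residual variance under a shared dispersion, for HVG ranking
    phi_common = float(np.median(params.phi))
    common = NormParams(
        gene_ids=params.gene_ids,
        rate=params.rate,
        phi=np.full_like(params.phi, phi_common),
        median_library=params.median_library,
        clip=params.clip,
    )
    hvg_variance = residual_transform(y, lib, common).var(axis=0)
    return NormMatrix(
        values=r,
        corrected_counts=corrected,
        gene_ids=np.asarray(m.gene_ids, dtype=object),
        cell_ids=np.asarray(m.cell_ids, dtype=object),
        params=params,
        regressed=regressed,
        hvg_variance=hvg_variance,
    )


def highly_variable_genes(nm: NormMatrix, n_top: int = 3000) -> list[str]:
    """Top-``n_top`` genes by residual variance, ties broken lexicographically.

    The variance is taken under a common dispersion (see
    :class:`NormMatrix`), so genes that are genuinely more variable than the
    shared noise model stand out.
    """
    if n_top > nm.values.shape[1]:
        raise ValueError(f"n_top={n_top} exceeds the {nm.values.shape[1]} genes available")
    var = nm.hvg_variance if nm.hvg_variance is not None else nm.values.var(axis=0)
    genes = np.asarray(nm.gene_ids, dtype=str)
    # sort by (-variance, symbol): descending variance, lexicographic ties
    order = np.lexsort((genes, -var))
    return [str(g) for g in genes[order[:n_top]]]
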