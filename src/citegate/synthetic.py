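"""Synthetic CITE-seq data with known ground truth.

The generator emulates the structure of a gated T-cell CITE-seq experiment:

* a two-component Gaussian mixture for the normalized-log ADT level, with
  component membership defining the true marker status;
* negative-binomial gene counts with a log-normal library-size offset and
  per-gene dispersion (``Var = mu + phi*mu^2``);
* a planted set of DE genes whose mean differs between the true classes by
  a factor of ``2**de_log2fc`` (half up in the marker-negative class, half
  up in the positive class — matching the pipeline's sign convention where
  positive log2FC means up in negatives);
* a block of genes rank-correlated with the anchor ("splicing factor")
  gene via a Gaussian copula, so Spearman targets are scale-free;
* housekeeping structure so QC is exercised: CD3-complex genes expressed in
  (almost) every cell, CD19 silent, a ribosomal block carrying a realistic
  share of the library, and a planted block of high-dispersion genes for
  HVG recovery.

Defaults mirror the training-data conditions the pipeline is designed for:
a few thousand T cells, clearly bimodal ADT, a modest planted DE signal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .containers import AdtVector, CountMatrix

ANCHOR_GENE = "HNRNPLL"


@dataclass
class SimConfig:
    """Knobs of the synthetic CITE-seq experiment."""

    n_cells: int = 3000
    n_genes: int = 2000
    # ADT mixture: normalized-log scale
    adt_mean_neg: float = 1.5
    adt_mean_pos: float = 3.5
    adt_sd: float = 0.4
    frac_positive: float = 0.4
    # planted signal
    n_de_genes: int = 30
    de_log2fc: float = 2.0
    n_corr_genes: int = 50
    corr_strength: float = 0.6
    n_hvg_planted: int = 50
    hvg_dispersion_factor: float = 10.0
    # noise model
    nb_dispersion: float = 0.5
    library_log_mean: float = np.log(6000.0)
    library_log_sd: float = 0.3
    seed: int = 0
    #: seed of the gene-level structure (base rates, planted gene identities,
    #: dispersions). Kept separate from ``seed`` so datasets simulated with
    #: different seeds share the same "biology" — the situation a classifier
    #: trained on one experiment and applied to another assumes.
    panel_seed: int = 20451

    def __post_init__(self) -> None:
        if not (0 < self.frac_positive < 1):
            raise ValueError("frac_positive must be in (0, 1)")
        if self.de_log2fc == 0 and self.n_de_genes > 0:
            # a zero effect size is allowed only as an explicit null run
            pass
        if abs(self.corr_strength) > 0.98:
            raise ValueError("infeasible corr_strength: |rho| must be <= 0.98")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    is_positive: np.ndarray
    de_genes_up_in_negative: list
    de_genes_up_in_positive: list
    corr_genes: list
    corr_target_rho: float
    hvg_genes: list
    anchor: str = ANCHOR_GENE
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "is_positive": [int(v) for v in self.is_positive],
            "de_genes_up_in_negative": self.de_genes_up_in_negative,
            "de_genes_up_in_positive": self.de_genes_up_in_positive,
            "corr_genes": self.corr_genes,
            "corr_target_rho": self.corr_target_rho,
            "hvg_genes": self.hvg_genes,
            "anchor": self.anchor,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


_FIXED_GENES = ["CD3D", "CD3E", "CD3G", "CD247", "CD19", ANCHOR_GENE]
_N_RIBO = 20


def _gene_panel(n_genes: int) -> list[str]:
    ribo = [f"RPS{i}" for i in range(1, 11)] + [f"RPL{i}" for i in range(1, 11)]
    named = _FIXED_GENES + ribo
    n_rest = n_genes - len(named)
    if n_rest < 0:
        raise ValueError(f"n_genes must be at least {len(named)}")
    rest = [f"G{i:05d}" for i in range(1, n_rest + 1)]
    return named + rest


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB draws with Var = mu + phi*mu^2 (Poisson when phi ~ 0)."""
    if phi < 1e-8:
        return rng.poisson(mu)
    shape = 1.0 / phi
    lam = rng.gamma(shape, phi * mu)
    return rng.poisson(lam)


def _nb_ppf(u: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Quantile transform for NB(mean=mu, Var=mu+phi*mu^2)."""
    n = 1.0 / phi
    p = n / (n + mu)
    return stats.nbinom.ppf(u, n, p)


def simulate(cfg: SimConfig | None = None, **overrides):
    """Generate (CountMatrix, AdtVector, SimTruth) under ``cfg``.

    Keyword overrides are applied on top of ``cfg`` (or the defaults).
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = SimConfig(**{**cfg.to_dict(), **overrides})
    rng = np.random.default_rng(cfg.seed)
    panel_rng = np.random.default_rng(cfg.panel_seed)
    genes = _gene_panel(cfg.n_genes)
    n, g = cfg.n_cells, len(genes)
    gene_arr = np.asarray(genes, dtype=object)

    # --- true classes and ADT -----------------------------------------
    is_positive = rng.random(n) < cfg.frac_positive
    adt = np.where(
        is_positive,
        rng.normal(cfg.adt_mean_pos, cfg.adt_sd, n),
        rng.normal(cfg.adt_mean_neg, cfg.adt_sd, n),
    )

    # --- base expression rates (panel-seeded: shared across datasets) --
    rate = np.exp(panel_rng.normal(-1.0, 1.0, g))  # relative abundance
    name_to_idx = {gname: i for i, gname in enumerate(genes)}
    ribo_idx = np.array([i for i, gname in enumerate(genes)
                         if gname.startswith(("RPS", "RPL"))])
    rate[ribo_idx] = np.exp(panel_rng.normal(2.8, 0.3, ribo_idx.size))  # ribo share ~20%
    for cd3 in ("CD3D", "CD3E", "CD3G", "CD247"):
        rate[name_to_idx[cd3]] = np.exp(1.0)  # robustly detected in T cells
    rate[name_to_idx["CD19"]] = 0.0  # B-cell marker: silent in gated T cells
    rate[name_to_idx[ANCHOR_GENE]] = np.exp(1.5)  # anchor well expressed

    # --- planted gene blocks (disjoint, generic genes only) ------------
    generic = np.array([i for i, gname in enumerate(genes) if gname.startswith("G")])
    need = cfg.n_de_genes + cfg.n_corr_genes + cfg.n_hvg_planted
    if need > generic.size:
        raise ValueError("not enough generic genes for the requested planted blocks")
    chosen = panel_rng.choice(generic, size=need, replace=False)
    de_idx = chosen[: cfg.n_de_genes]
    corr_idx = chosen[cfg.n_de_genes: cfg.n_de_genes + cfg.n_corr_genes]
    hvg_idx = chosen[cfg.n_de_genes + cfg.n_corr_genes:]
    # planted DE/corr genes get solid expression so the signal is detectable
    rate[de_idx] = np.exp(panel_rng.normal(0.5, 0.3, de_idx.size))
    rate[corr_idx] = np.exp(panel_rng.normal(0.8, 0.3, corr_idx.size))
    rate = rate / rate.sum()

    # --- per-cell expected counts -------------------------------------
    library = np.exp(rng.normal(cfg.library_log_mean, cfg.library_log_sd, n))
    mu = library[:, None] * rate[None, :]

    # DE effect: half the genes up in negatives (positive log2FC by the
    # pipeline convention), half up in positives, total ratio 2**de_log2fc
    n_up_neg = cfg.n_de_genes // 2
    up_neg_idx = de_idx[:n_up_neg]
    up_pos_idx = de_idx[n_up_neg:]
    half = 2.0 ** (cfg.de_log2fc / 2.0)
    neg_mask = ~is_positive
    mu[np.ix_(neg_mask, up_neg_idx)] *= half
    mu[np.ix_(is_positive, up_neg_idx)] /= half
    mu[np.ix_(is_positive, up_pos_idx)] *= half
    mu[np.ix_(neg_mask, up_pos_idx)] /= half

    # --- dispersions ---------------------------------------------------
    phi = np.full(g, cfg.nb_dispersion)
    phi[hvg_idx] = cfg.nb_dispersion * cfg.hvg_dispersion_factor

    # --- counts: copula block for corr genes, independent NB elsewhere -
    counts = np.empty((n, g), dtype=np.int64)
    indep = np.ones(g, dtype=bool)
    indep[corr_idx] = False
    anchor_i = name_to_idx[ANCHOR_GENE]
    indep[anchor_i] = False
    for j in np.flatnonzero(indep):
        counts[:, j] = _nb_sample(rng, mu[:, j], phi[j])

    # Gaussian copula: latent anchor z0, corr-gene latents with latent
    # correlation chosen so the *rank* correlation hits corr_strength
    # (bivariate-normal identity rho_s = (6/pi)*asin(rho_l/2)). Copula-block
    # marginals use the median library so shared library size does not add
    # rank dependence on top of the target.
    rho_latent = 2.0 * np.sin(np.pi * cfg.corr_strength / 6.0)
    med_lib = float(np.median(library))
    z0 = rng.standard_normal(n)
    u0 = stats.norm.cdf(z0)
    mu_anchor = med_lib * mu[:, anchor_i] / library
    counts[:, anchor_i] = _nb_ppf(u0, mu_anchor, phi[anchor_i]).astype(np.int64)
    for j in corr_idx:
        zj = rho_latent * z0 + np.sqrt(1.0 - rho_latent**2) * rng.standard_normal(n)
        counts[:, j] = _nb_ppf(stats.norm.cdf(zj), med_lib * mu[:, j] / library,
                               phi[j]).astype(np.int64)

    cell_ids = np.array([f"CELL{i:06d}" for i in range(1, n + 1)], dtype=object)
    cm = CountMatrix(sp.csr_matrix(counts), gene_arr, cell_ids)
    adt_vec = AdtVector(adt, cell_ids)
    truth = SimTruth(
        is_positive=is_positive.astype(int),
        de_genes_up_in_negative=[genes[i] for i in up_neg_idx],
        de_genes_up_in_positive=[genes[i] for i in up_pos_idx],
        corr_genes=[genes[i] for i in corr_idx],
        corr_target_rho=float(cfg.corr_strength),
        hvg_genes=[genes[i] for i in hvg_idx],
        config=cfg.to_dict(),
    )
    return cm, adt_vec, truth


def simulate_to_dir(cfg: SimConfig, out_dir) -> None:
    """Write a simulated dataset in the formats the readers accept."""
    from .io import write_adt, write_counts

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm, adt, truth = simulate(cfg)
    write_counts(cm, out_dir / "counts", format="mtx10x")
    write_adt(adt, out_dir / "adt.csv")
    truth.to_json(out_dir / "truth.json")


def worked_toy():
    """Tiny hand-checkable fixture shipped with the package.

    40 cells x 18 genes with a clearly bimodal ADT; small enough that the
    brute-force Otsu, GLM grid and BH step-up oracles run in milliseconds.
    """
    from .io import read_adt, read_counts

    data_dir = resources.files("citegate.data")
    with resources.as_file(data_dir.joinpath("toy_counts.csv")) as p:
        cm = read_counts(p, format="csv")
    with resources.as_file(data_dir.joinpath("toy_adt.csv")) as p:
        adt = read_adt(p)
    return cm, adt
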