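"""Cell-cycle scoring, NB Pearson-residual normalization, HVG selection."""

import numpy as np
import pytest

from citegate.containers import CountMatrix
from citegate.preprocess import (
    CellCovariates,
    cell_cycle_score,
    default_g2m_genes,
    default_s_genes,
    fit_norm_params,
    highly_variable_genes,
    normalize_regress,
    residual_transform,
)
from citegate.synthetic import SimConfig, simulate


def _matrix_with_phase_genes(perturb_s=False, seed=0):
    rng = np.random.default_rng(seed)
    s_genes, g2m_genes = default_s_genes()[:10], default_g2m_genes()[:10]
    other = [f"G{i}" for i in range(180)]
    genes = s_genes + g2m_genes + other
    counts = rng.poisson(3.0, size=(300, len(genes)))
    if perturb_s:
        counts[:150, :10] *= 2  # double S-gene counts in half the cells
    return CountMatrix(counts, genes, [f"c{i}" for i in range(300)]), s_genes


class TestCellCycleScore:
    def test_uniform_expression_scores_zero(self):
        genes = default_s_genes()[:10] + [f"G{i}" for i in range(90)]
        counts = np.full((50, 100), 4)
        m = CountMatrix(counts, genes, [f"c{i}" for i in range(50)])
        cov = cell_cycle_score(m, seed=0)
        # float32 arithmetic inside the scorer leaves ~1e-7 noise
        assert np.allclose(cov.s_score, 0.0, atol=1e-5)
        assert np.allclose(cov.g2m_score, 0.0, atol=1e-5)

    def test_s_gene_amplification_raises_s_score(self):
        base, _ = _matrix_with_phase_genes(perturb_s=False)
        perturbed, _ = _matrix_with_phase_genes(perturb_s=True)
        cov0 = cell_cycle_score(base, seed=1)
        cov1 = cell_cycle_score(perturbed, seed=1)
        assert cov1.s_score[:150].mean() > cov0.s_score[:150].mean() + 0.05

    def test_deterministic_under_seed(self):
        m, _ = _matrix_with_phase_genes(perturb_s=True)
        a = cell_cycle_score(m, seed=7)
        b = cell_cycle_score(m, seed=7)
        assert np.array_equal(a.s_score, b.s_score)
        assert np.array_equal(a.g2m_score, b.g2m_score)

    def test_too_few_set_genes_warns_and_zeroes(self):
        m = CountMatrix(np.ones((10, 3), dtype=int), ["GA", "GB", "GC"],
                        [f"c{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="score set to 0"):
            cov = cell_cycle_score(m, seed=0)
        assert np.all(cov.s_score == 0) and np.all(cov.g2m_score == 0)


class TestNormalizeRegress:
    def test_constant_gene_zero_residuals(self):
        counts = np.column_stack([np.full(20, 5), np.full(20, 3)])
        m = CountMatrix(counts, ["GA", "GB"], [f"c{i}" for i in range(20)])
        nm = normalize_regress(m, cov=None)
        assert np.allclose(nm.values, 0.0, atol=1e-10)

    def test_ols_orthogonality(self, sim_small):
        m, _, _ = sim_small
        rng = np.random.default_rng(0)
        cov = CellCovariates(
            mito_frac=rng.uniform(0, 0.2, m.n_cells),
            s_score=rng.normal(0, 1, m.n_cells),
            g2m_score=rng.normal(0, 1, m.n_cells),
        )
        nm = normalize_regress(m, cov)
        for name in ("mito_frac", "cc_diff"):
            c = cov.get(name) - cov.get(name).mean()
            corr = (nm.values - nm.values.mean(axis=0)).T @ c
            assert np.max(np.abs(corr)) < 1e-6 * m.n_cells

    def test_poisson_residual_variance_near_unity(self):
        # Poisson counts, equal library sizes: Pearson residual variance ~ 1
        rng = np.random.default_rng(42)
        means = rng.uniform(1, 20, 100)
        counts = rng.poisson(means, size=(2000, 100))
        m = CountMatrix(counts, [f"G{i}" for i in range(100)],
                        [f"c{i}" for i in range(2000)])
        nm = normalize_regress(m, cov=None)
        variances = nm.values.var(axis=0)
        assert np.all(variances > 0.8) and np.all(variances < 1.2)

    def test_shape_and_alignment_preserved(self, sim_small):
        m, _, _ = sim_small
        nm = normalize_regress(m, cov=None)
        assert nm.values.shape == m.shape
        assert nm.corrected_counts.shape == m.shape
        assert np.array_equal(nm.gene_ids, m.gene_ids)
        assert np.array_equal(nm.cell_ids, m.cell_ids)
        assert np.all(np.isfinite(nm.values))
        assert np.all(nm.corrected_counts >= 0)

    def test_empty_regress_is_identity_on_residuals(self, sim_small):
        m, _, _ = sim_small
        rng = np.random.default_rng(1)
        cov = CellCovariates(
            mito_frac=rng.uniform(0, 0.2, m.n_cells),
            s_score=np.zeros(m.n_cells),
            g2m_score=np.zeros(m.n_cells),
        )
        plain = normalize_regress(m, cov=None)
        empty = normalize_regress(m, cov, regress=())
        assert np.array_equal(plain.values, empty.values)

    def test_constant_covariate_skipped_with_warning(self, sim_small):
        m, _, _ = sim_small
        cov = CellCovariates(
            mito_frac=np.full(m.n_cells, 0.1),
            s_score=np.zeros(m.n_cells),
            g2m_score=np.zeros(m.n_cells),
        )
        with pytest.warns(UserWarning, match="constant"):
            nm = normalize_regress(m, cov)
        assert np.all(np.isfinite(nm.values))

    def test_library_scaling_touches_only_that_cell(self, sim_small):
        """Under stored parameters, rescaling one cell leaves other cells alone."""
        m, _, _ = sim_small
        params = fit_norm_params(m)
        y = m.dense().astype(float)
        lib = y.sum(axis=1)
        base = residual_transform(y, lib, params)
        y2 = y.copy()
        y2[0] *= 3
        scaled = residual_transform(y2, y2.sum(axis=1), params)
        assert np.array_equal(base[1:], scaled[1:])
        assert not np.array_equal(base[0], scaled[0])


class TestHighlyVariableGenes:
    def test_degenerate_top_k_returns_all(self, sim_small):
        m, _, _ = sim_small
        nm = normalize_regress(m, cov=None)
        hvg = highly_variable_genes(nm, n_top=m.n_genes)
        assert sorted(hvg) == sorted(m.gene_ids.astype(str))

    def test_planted_high_dispersion_genes_recovered(self):
        cm, _, truth = simulate(SimConfig(n_cells=2000, n_genes=500, seed=3))
        nm = normalize_regress(cm, cov=None)
        hvg = set(highly_variable_genes(nm, n_top=len(truth.hvg_genes) + 30))
        recovered = sum(g in hvg for g in truth.hvg_genes)
        assert recovered >= 45  # 50 planted at 10x dispersion

    def test_tie_break_lexicographic(self):
        counts = np.array([[4, 4, 1], [1, 1, 1], [4, 4, 1], [1, 1, 1]])
        m = CountMatrix(counts, ["GB", "GA", "GC"], [f"c{i}" for i in range(4)])
        nm = normalize_regress(m, cov=None)
        hvg = highly_variable_genes(nm, n_top=3)
        # GA and GB have identical counts hence identical variance ->
        # the tie resolves lexicographically
        assert hvg.index("GA") < hvg.index("GB")

    def test_n_top_exceeding_gene_count_errors(self, sim_small):
        m, _, _ = sim_small
        nm = normalize_regress(m, cov=None)
        with pytest.raises(ValueError):
            highly_variable_genes(nm, n_top=m.n_genes + 1)
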