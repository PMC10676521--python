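# Methods

This note documents the statistical machinery inside `citegate`: the models,
their assumptions, the defaults and why, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## ADT labeling

The ADT channel is assumed already normalized and log-transformed by the
data provider (the usual CITE-seq deliverable); all thresholds live on that
scale. Otsu's method builds a 256-bin equal-width histogram over the
observed range and returns the bin center maximising the between-class
variance ω₀ω₁(μ₀−μ₁)². Ties resolve to the lowest qualifying bin; note that
when the histogram has an empty stretch between modes every split inside it
is an exact tie, so the returned threshold can sit at the low edge of the
gap — any such split separates the classes identically.

Cells with ADT in the open interval (t\*−margin, t\*+margin) are labeled
`excluded` and never reach training; the boundaries are inclusive
(≥ t\*+margin ⇒ positive, ≤ t\*−margin ⇒ negative). The default margin 0.5
is calibrated to the provider-normalized CD45RA scale and is a free
parameter for other markers. margin = 0 partitions all cells.

## Normalization

The variance-stabilising transform is an analytic negative-binomial
Pearson residual with a library-size offset:

* per-gene rate `p_g = mean_c(y_cg / L_c)` (the mean of per-cell rates is
  equivariant under rescaling any single cell's library, unlike the
  ratio-of-totals estimator);
* `mu_cg = L_c p_g`; per-gene dispersion by method of moments,
  `phi_g = max(0, Σ((y−μ)²−μ) / Σμ²)`, under `Var = μ + φμ²`;
* residual `(y−μ)/√(μ+φμ²)`, clipped at ±√n_cells (prevents rare extreme
  cells from dominating rank-based statistics downstream);
* requested covariates (mitochondrial fraction; S-score minus G2M-score,
  computed by expression-bin-matched control sets, 25 bins, 50 controls
  per gene, seeded) are removed from each gene's residual vector by OLS.

Full numerical parity with any particular reference normalization tool is
explicitly out of scope; the transform above is the contract the rest of
the pipeline is defined against.

Two derived matrices come out of it:

* **corrected counts** — the covariate-regressed residual inverted at the
  median library size, `max(0, μ_med + r·sd_med)`, rounded half-to-even.
  This is the count-scale input of the GLM stage, so the regressed
  covariates are also absent from DE testing.
* **HVG variance** — residual variance recomputed under a *common*
  (median) dispersion. Per-gene dispersion standardises every gene's
  residual variance towards 1 by construction, which is desirable for the
  classifier but would erase exactly the excess variability that
  highly-variable-gene ranking looks for; a shared dispersion (the
  convention of analytic Pearson-residual HVG selection) restores it.
  Ties in the ranking resolve lexicographically.

At inference time the stored per-gene rate and dispersion are reused;
library offsets are recomputed on the query and covariate regression is
skipped unless covariates are supplied (conventional scRNA-seq queries
rarely ship them). With stored parameters each cell's residuals depend only
on its own counts, so predictions are per-cell independent.

## Differential expression

Per gene, a two-condition GLM with natural-log link and quasi-Poisson
noise, `Var(y) = μ + φμ²`. The quasi-likelihood integrating the quasi-score
`(y−μ)/(μ+φμ²)` is

    Q(y; μ, φ) = y·log μ − (y + 1/φ)·log(1 + φμ)   (+ terms in y only),

and the test statistic is `D = 2(Q_full − Q_null)` with the full model's
moment-estimated φ used in both likelihoods (the standard quasi-LRT
convention), referred to χ²₁. With a condition-only design the IRLS fixed
point is the per-condition mean, so the table routine fits every gene in
closed form; the single-gene entry point runs IRLS and agrees to machine
precision. `D ≥ 0` holds by construction (the pooled mean lies inside the
full model's parameter space). All-zero genes report D = 0, p = 1.
Dispersion is clamped to [1e-8, 1e6].

The log₂ fold change is `(β_neg − β_pos)/ln 2`: the GLM coefficients are
natural-log means, and dividing by ln 2 makes the quantity equal
log₂(mean_neg/mean_pos). **Positive log₂FC = higher in marker-negative
cells** — this sign convention is used everywhere. Genes expressed in only
one condition get ±∞, which any finite threshold accepts; genes expressed
in neither are excluded via q = 1. BH q-values come from the standard
step-up procedure; DE eligibility is fixed at q < 0.05, the tunable
thresholds act on the fold change only.

Null calibration: on negative-binomial null data (φ = 0.5, mean 2, 200
cells per group) the LRT's empirical type-I error at α = 0.05 falls inside
[0.03, 0.07] (checked at 2000 genes in the test suite).

## Correlation features

Spearman correlation of every gene's residual expression with the anchor
gene (default HNRNPLL, the splicing factor that drives CD45RA exon
exclusion), average ranks for ties, two-sided p by the t approximation.
"Top P_hn" is a descending-rank quantile: a gene is selected when
`rank(|ρ|)/n_tested ≤ P_hn` and p < 0.05 (raw, not multiplicity-adjusted —
the screen is a feature heuristic, not an inference). The anchor itself is
never selected. Smaller P_hn is stricter; P_hn → 1e-6 selects nothing.

Feature sets order DE genes by |log₂FC| descending, then correlation genes
by |ρ| descending, ties lexicographic, de-duplicated with provenance
(`de` / `corr` / `both`). Tightening any threshold can only shrink the set.

## Classifiers and tuning

Five model kinds share a fit/predict surface; features are standardised
inside the classifier. Logistic regression (L2, cost C_LR, probability cut
0.5); linear and RBF SVMs (cost C_SVM, kernel width γ, hard decision at
0); a stack whose meta logistic regression consumes the two base models'
hard 0/1 predictions (its own regularisation stays at the default — it
only sees two binary features); and an MLP of 1–3 dense ReLU layers with
inverted dropout ρ, sigmoid output, binary cross-entropy, Adam with
learning rate η, He-uniform init, 15 epochs, batch 32, all seeded.

Search boxes: t_DE-upper ∈ (1, 4), t_DE-lower ∈ (−4, −1),
P_hn ∈ (1e-6, 0.1), C_SVM ∈ (1e-6, 100), γ ∈ (1e-6, 2), C_LR ∈ (1e-6, 2),
N_layers ∈ {1, 2, 3}, N_nodes ∈ [16, 128], η ∈ (1e-4, 0.01), ρ ∈ (0.1, 0.5).
The two fold-change bounds are searched independently because optimal
upper and lower cutoffs generally differ.

The tuner is a Gaussian-process Bayesian optimizer: Matérn ν = 2.5 kernel
with per-dimension length scales by marginal likelihood, inputs mapped to
the unit box, no priors on the values, 5 Latin-hypercube initial points,
expected-improvement acquisition over 2048 uniform candidates, a budget of
30 evaluations, early stop when max EI < 1e-6. Two optimizer design
choices matter in practice:

* **log-space traversal** of the positive scale parameters (C_SVM, γ,
  C_LR, η, P_hn). On ~100 standardized features an RBF kernel is
  informative only for γ ≲ 1/d; uniform traversal of (1e-6, 2) visits that
  region with probability ~0.5%, and every evaluation then ties at the
  majority-class rate. Log-space traversal makes each decade equally
  likely while leaving the box endpoints untouched.
* **plateau exploration**: when every observed score is identical the GP
  posterior is constant and EI is identically zero, so the early-stop rule
  would fire on a false plateau; the acquisition instead evaluates the
  candidate farthest from everything observed until the response varies.

The objective is the 5-fold stratified CV mean accuracy (mean binary
cross-entropy, minimised, for the MLP). Inside every fold the DE table and
the correlation screen are recomputed from that fold's training portion
only; because those tables do not depend on the thresholds, they are cached
per fold and reused across optimizer iterations. An empty feature set
scores worst so the optimizer steers away. The returned optimum is the
arg-best observed point; the final model re-derives features from, and is
refit on, the entire training split.

The train/test split is a plain shuffled 80/20 split with seed 42 (not
stratified). Feature selection and model fitting see training barcodes
only; `fit(audit=True)` records the barcodes reaching each stage so the
guarantee is checkable, and the test suite asserts the intersection with
the test split is empty.

## Synthetic data

The generator emulates a gated T-cell CITE-seq experiment: a two-component
Gaussian ADT mixture (means 1.5/3.5, sd 0.4, 40% positive) whose component
defines true marker status; log-normal library sizes (median ≈ 6000, sd
0.3 in log); NB counts with φ = 0.5; CD3-complex genes expressed, CD19
silent, a 20-gene ribosomal block carrying ≈ 19% of the library; 30 DE
genes planted at |log₂FC| = 2 (half up in each class); 50 genes
rank-correlated with HNRNPLL at ρ = 0.6 through a Gaussian copula
(`ρ_latent = 2 sin(πρ_s/6)`, marginals at the median library so shared
library size does not inflate the rank target); 50 genes at 10× dispersion
for HVG recovery. Gene-level structure (rates, planted identities,
dispersions) is drawn from a separate `panel_seed` held fixed by default,
so datasets simulated under different seeds share the same "biology" — the
premise of training on one experiment and predicting on another.

The defaults are the study conditions of the whole test battery; the
acceptance script runs them unchanged (3000 cells x 2000 genes), and the
CLI smoke test uses a smaller instance (1000 x 400) of the same process.

What passing on this generator shows: the pipeline recovers planted means,
correlations, and class structure through all of its stages, with no
leakage and full determinism. What it does not show: robustness to batch
effects, doublets, ambient RNA, or cross-platform shifts — none of which
are simulated — nor performance on real CD45RA data, which depends on how
strongly transcription tracks the protein in the tissue at hand.

A 40-cell x 18-gene toy (bimodal ADT, two planted DE genes) ships as CSV
for hand-checkable verification of the Otsu, GLM and BH computations
against brute-force oracles.

## Degenerate inputs and edge rules

Constant ADT vectors are an error ("degenerate ADT distribution"); an
all-excluding margin is an error advising a smaller margin. Zero-library
cells are removed with the reason recorded (the ribosomal fraction is
undefined). Constant covariates are skipped with a warning. Single-class
training labels are an error. Query matrices missing > 50% of the model's
features are an error, > 20% a warning. Model archives carry a SHA-256
manifest; any mismatch or truncation is rejected.

## Known limitations

* The quasi-LRT's χ²₁ reference is asymptotic; at very small group sizes
  the moment dispersion is noisy and the test can be mildly conservative.
* The Otsu threshold assumes a roughly bimodal ADT; unimodal channels
  will produce an arbitrary split (gate upstream, or widen the margin).
* Corrected counts are a residual inversion, not a generative model fit;
  they are a pragmatic count-scale carrier for the GLM.
* The stack consumes hard base predictions, so its scores are coarse
  (meta-probabilities over four input patterns).
* Cross-validated accuracy on the synthetic defaults saturates near 1.0,
  so differences between the five model kinds are not resolvable there;
  they matter on real, noisier data.
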