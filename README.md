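# citegate

**Surface-marker classifiers learned from CITE-seq ADT gating, applied to
plain scRNA-seq.**

Some T-cell surface markers — CD45RA, the alternatively spliced CD45
isoform that separates naive from central-memory and TEMRA from
effector-memory T cells, being the canonical case — are poorly captured by
short-read scRNA-seq, because isoform-discriminating reads are rare. CITE-seq
measures the protein directly through DNA-barcoded antibodies (ADTs), but
most datasets, past and future, are mRNA-only. `citegate` closes that gap:
it learns a marker-positive/negative classifier from a CITE-seq experiment
(mRNA counts + one ADT channel) and then infers marker status on any
conventional count matrix.

## Method

1. **QC / gating** — keep T cells (any of CD3D/CD3E/CD3G/CD247 expressed,
   CD19 silent), drop cells with < 5% ribosomal counts, drop genes detected
   in < 2 cells.
2. **Labeling** — Otsu's method on the normalized-log ADT histogram finds
   the threshold *t\** maximising the between-class variance
   ω₀ω₁(μ₀−μ₁)²; cells with ADT ≥ *t\**+0.5 are positive, ≤ *t\**−0.5
   negative, and the ambiguous band in between is excluded from training.
3. **Normalization** — negative-binomial Pearson residuals with a
   log-library-size offset and per-gene moment dispersion
   (Var = μ + φμ²), clipped at ±√n; mitochondrial fraction and the
   S-minus-G2M cell-cycle score are regressed out.
4. **Features** — two sources, both tunable:
   differentially expressed genes from a per-gene quasi-Poisson GLM
   likelihood-ratio test, D = 2(ℓ_full − ℓ_null) ~ χ²₁, kept when the BH
   q-value < 0.05 and the log₂ fold change clears (t_DE-upper, t_DE-lower);
   plus genes whose expression rank-correlates with the CD45 splicing
   factor **HNRNPLL** (|ρ| in the top P_hn fraction, p < 0.05).
5. **Models** — logistic regression, linear- and RBF-kernel SVMs, an
   LR+SVM stack, and a small dropout MLP. Feature thresholds and model
   hyperparameters are tuned **jointly** by Gaussian-process Bayesian
   optimization (Matérn ν = 2.5, expected improvement, ≤ 30 evaluations)
   against 5-fold stratified cross-validation, with features re-derived
   inside every fold so the held-out fold never leaks into selection.
6. **Inference** — the stored per-gene rate/dispersion reproduce the
   residual transform on query data; absent genes are zero-filled (with a
   warning above 20% missing, an error above 50%).

Everything is testable offline: the `citegate.synthetic` module simulates a
CITE-seq experiment with known ground truth (bimodal ADT, NB counts,
planted DE genes, a copula-correlated splicing-factor block).

## Worked example

```python
from citegate import MarkerModel, SimConfig, simulate

counts, adt, truth = simulate(SimConfig(seed=1))   # 3000 cells x 2000 genes
model = MarkerModel(counts, adt)
results = model.fit("svm_rbf", optimize=True, max_iter=30, seed=42)
print(results.summary())
```

```
Marker classifier results
============================================================
model kind:          svm_rbf
anchor gene:         HNRNPLL
Otsu threshold t*:   2.4815 (margin ±0.5)
labeled cells:       1102 positive, 1587 negative, 311 excluded
train/test cells:    2151/538
------------------------------------------------------------
hyperparameters:
  t_de_upper   = 1.93271
  t_de_lower   = -1.67606
  p_hn         = 0.000112082
  c_svm        = 43.0257
  gamma        = 0.000199598
------------------------------------------------------------
features:            24 (de: 24)
CV (accuracy): mean 1.0000 over 5 folds
training accuracy:   100.00%
test accuracy:       100.00%
test precision:      100.00%
test recall:         100.00%
test ROC AUC:        1.0000
```

The Otsu threshold 2.48 sits in the gap between the two simulated ADT
modes (1.5 and 3.5); 311 cells inside the ±0.5 margin are excluded from
training. The optimizer settled on 24 differential-expression features and
a small RBF width, and the planted signal is recovered perfectly on the
held-out 538 cells. Applying the model to a second, all-marker-negative
simulated experiment:

```python
query, _, _ = simulate(SimConfig(seed=2, frac_positive=0.001))
pred = results.predict(query)      # DataFrame: barcode, label, score
print((pred["label"] == "negative").mean())   # 0.9997
```

## Command line

```bash
citegate simulate --out sim/ --seed 3 --n-cells 1000 --n-genes 400
citegate train    --counts sim/counts --adt sim/adt.csv --model-out model.zip
citegate predict  --counts sim/counts --model model.zip --out pred.csv
citegate evaluate --predictions pred.csv --truth sim/truth.json --out metrics.json
```

Models travel as zip archives with a SHA-256 manifest that is verified on
load. Exit codes: 0 success, 2 validation/input error, 1 internal error.

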