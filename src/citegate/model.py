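"""Marker-classifier model: training orchestration, CV and evaluation.

The entry point is :class:`MarkerModel`, built from a raw count matrix plus
the matching per-cell ADT vector. ``fit()`` runs the whole training
protocol — QC, Otsu labeling with margin exclusion, normalization, the
train/test split (test size 0.2, seed 42), Gaussian-process Bayesian
optimization of the feature-selection thresholds jointly with the model
hyperparameters under 5-fold stratified CV, and a final refit on the entire
training split — and returns a :class:`MarkerResults` carrying the
estimates, diagnostics, trace and a ``summary()`` table.

Feature selection (DE testing and the anchor-gene correlation screen) and
classifier fitting are *re-derived inside every CV fold from that fold's
training portion*, and never see the held-out test split: an audit log of
the barcodes reaching each stage backs this up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classifiers import (
    FEATURE_HP_NAMES,
    INTEGER_HPS,
    MODEL_HP_NAMES,
    SEARCH_BOUNDS,
    HyperParams,
    MarkerClassifier,
)
from .containers import AdtVector, CountMatrix, QcReport
from .diffexp import DeResult, qp_glm_table
from .features import (
    DEFAULT_ANCHOR,
    CorrResult,
    FeatureSelectionError,
    FeatureSet,
    select_features,
    spearman_with_anchor,
)
from .gating import AdtLabels, label_adt
from .optimize import Dimension, OptimizeResult, bayes_optimize
from .preprocess import CellCovariates, NormMatrix, cell_cycle_score, normalize_regress
from .qc import apply_qc as _apply_qc


def split_train_test(n_cells: int, test_size: float = 0.2, seed: int = 42):
    """Plain shuffled train/test index split (not stratified)."""
    idx = np.arange(n_cells)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, random_state=seed, shuffle=True
    )
    return np.sort(train_idx), np.sort(test_idx)


def anchor_corr_table(values: np.ndarray, gene_ids, anchor: str) -> CorrResult:
    """Spearman-vs-anchor table over all genes (no selection applied)."""
    genes = np.asarray(gene_ids, dtype=str)
    anchor_idx = np.flatnonzero(genes == anchor)
    if anchor_idx.size == 0:
        raise KeyError(f"anchor gene {anchor!r} not in matrix")
    rho, p = spearman_with_anchor(values, values[:, anchor_idx[0]])
    tested = genes != anchor
    n_tested = int(tested.sum())
    order = np.argsort(-np.abs(rho[tested]), kind="stable")
    rank = np.empty(n_tested)
    rank[order] = np.arange(1, n_tested + 1)
    quant = np.full(genes.size, np.nan)
    quant[tested] = rank / n_tested
    table = pd.DataFrame(
        {"gene": genes, "rho": rho, "p_value": p, "abs_rank_quantile": quant}
    )
    return CorrResult(table=table, anchor=anchor)


@dataclass
class CvScore:
    """Per-fold cross-validation metric and its mean."""

    fold_values: list
    metric: str  # "accuracy" or "binary_cross_entropy"

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_values))


def _binary_cross_entropy(y_true: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    y = np.asarray(y_true, dtype=float)
    return float(-np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


class CvEvaluator:
    """5-fold stratified CV with per-fold feature re-derivation.

    The fold-level DE and correlation tables depend only on the fold split,
    not on the thresholds, so they are computed once and cached; each
    hyperparameter evaluation then only re-selects features and refits the
    classifier.
    """

    def __init__(self, X_input: np.ndarray, corrected: np.ndarray, y: np.ndarray,
                 gene_ids, cell_ids, anchor: str = DEFAULT_ANCHOR, k: int = 5,
                 seed: int = 0, audit: dict | None = None):
        self.X_input = X_input
        self.corrected = corrected
        self.y = np.asarray(y, dtype=int)
        self.gene_ids = np.asarray(gene_ids, dtype=str)
        self.cell_ids = np.asarray(cell_ids, dtype=str)
        self.anchor = anchor
        self.k = k
        self.seed = seed
        self.audit = audit
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        self.folds = list(skf.split(np.zeros(len(self.y)), self.y))
        self._cache: dict[int, tuple[DeResult, CorrResult]] = {}
        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}

    def _audit_add(self, stage: str, cell_ids: np.ndarray) -> None:
        if self.audit is not None:
            self.audit.setdefault(stage, set()).update(map(str, cell_ids))

    def fold_tables(self, fold: int) -> tuple[DeResult, CorrResult]:
        if fold not in self._cache:
            tr, _ = self.folds[fold]
            self._audit_add("de", self.cell_ids[tr])
            self._audit_add("corr", self.cell_ids[tr])
            de = qp_glm_table(self.corrected[tr], self.y[tr] == 1, self.gene_ids)
            corr = anchor_corr_table(self.X_input[tr], self.gene_ids, self.anchor)
            self._cache[fold] = (de, corr)
        return self._cache[fold]

    def score(self, hp: HyperParams) -> CvScore:
        metric = "binary_cross_entropy" if hp.model_kind == "mlp" else "accuracy"
        values = []
        for fold, (tr, te) in enumerate(self.folds):
            de, corr = self.fold_tables(fold)
            try:
                fs = select_features(de, corr, hp.t_de_upper, hp.t_de_lower, hp.p_hn)
            except FeatureSelectionError:
                # empty feature set: worst possible score so the optimizer steers away
                values.append(0.0 if metric == "accuracy" else np.inf)
                continue
            cols = [self._gene_pos[g] for g in fs.genes]
            self._audit_add("fit", self.cell_ids[tr])
            clf = MarkerClassifier(hp.model_kind, hp, seed=self.seed).fit(
                self.X_input[np.ix_(tr, cols)], self.y[tr]
            )
            Xte = self.X_input[np.ix_(te, cols)]
            if metric == "accuracy":
                values.append(float(skm.accuracy_score(self.y[te], clf.predict(Xte))))
            else:
                values.append(_binary_cross_entropy(self.y[te], clf.predict_score(Xte)))
        return CvScore(fold_values=values, metric=metric)


def stratified_kfold_score(
    hp: HyperParams,
    X_input: np.ndarray,
    corrected: np.ndarray,
    y: np.ndarray,
    gene_ids,
    cell_ids=None,
    k: int = 5,
    seed: int = 0,
    anchor: str = DEFAULT_ANCHOR,
) -> CvScore:
    """Score one hyperparameter point by leakage-safe stratified k-fold CV."""
    if cell_ids is None:
        cell_ids = np.array([f"cell{i}" for i in range(len(y))])
    ev = CvEvaluator(X_input, corrected, y, gene_ids, cell_ids, anchor=anchor, k=k, seed=seed)
    return ev.score(hp)


#: positive scale parameters are searched in log space (see Dimension.log)
LOG_SCALE_HPS = {"p_hn", "c_svm", "gamma", "c_lr", "eta"}


def search_dimensions(model_kind: str) -> list[Dimension]:
    names = FEATURE_HP_NAMES + MODEL_HP_NAMES[model_kind]
    return [
        Dimension(name=n, low=SEARCH_BOUNDS[n][0], high=SEARCH_BOUNDS[n][1],
                  integer=n in INTEGER_HPS, log=n in LOG_SCALE_HPS)
        for n in names
    ]


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
    clusters: np.ndarray | None = None,
) -> dict:
    """Accuracy/precision/recall plus ROC and precision-recall summaries.

    Positive class is the marker-positive label (1). When the data contain
    no positive instances, precision and recall are reported as ``None``
    (undefined), never 0. With ``clusters`` given, a per-cluster
    misclassification table is included.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    out: dict = {"n": int(y_true.size)}
    out["accuracy"] = float(skm.accuracy_score(y_true, y_pred))
    has_pos = bool((y_true == 1).any())
    has_pred_pos = bool((y_pred == 1).any())
    out["precision"] = (
        float(skm.precision_score(y_true, y_pred, zero_division=np.nan))
        if has_pos and has_pred_pos
        else None
    )
    out["recall"] = float(skm.recall_score(y_true, y_pred)) if has_pos else None
    if scores is not None and has_pos and bool((y_true == 0).any()):
        fpr, tpr, _ = skm.roc_curve(y_true, scores)
        prec, rec, _ = skm.precision_recall_curve(y_true, scores)
        out["roc_auc"] = float(skm.roc_auc_score(y_true, scores))
        out["average_precision"] = float(skm.average_precision_score(y_true, scores))
        out["roc_curve"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
        out["pr_curve"] = {"precision": prec.tolist(), "recall": rec.tolist()}
    if clusters is not None:
        clusters = np.asarray(clusters)
        rows = []
        for c in pd.unique(clusters):
            mask = clusters == c
            rows.append(
                {
                    "cluster": c,
                    "n": int(mask.sum()),
                    "misclassified_pct": float(100.0 * (y_true[mask] != y_pred[mask]).mean()),
                }
            )
        out["per_cluster"] = rows
    return out


class MarkerModel:
    """Surface-marker classifier model built from CITE-seq training data.

    Parameters
    ----------
    counts
        Raw cells x genes UMI counts.
    adt
        Normalized, log-transformed ADT level for the marker, keyed by
        barcode (superset of the count matrix barcodes is fine).
    margin
        Exclusion half-width around the Otsu threshold (ADT units).
    n_bins
        Histogram bins for Otsu thresholding.
    anchor
        Anchor gene for the correlation feature source.
    apply_qc
        Run the T-cell gate and cell/gene filters first.
    classifier_input
        ``"residuals"`` (default) feeds the variance-stabilized residuals
        to the classifier; ``"corrected"`` feeds count-scale corrected
        counts.
    """

    def __init__(
        self,
        counts: CountMatrix,
        adt: AdtVector,
        *,
        margin: float = 0.5,
        n_bins: int = 256,
        anchor: str = DEFAULT_ANCHOR,
        apply_qc: bool = True,
        regress: tuple[str, ...] = ("mito_frac", "cc_diff"),
        classifier_input: str = "residuals",
        qc_kwargs: dict | None = None,
    ):
        self.counts = counts
        self.adt = adt
        self.margin = margin
        self.n_bins = n_bins
        self.anchor = anchor
        self.apply_qc = apply_qc
        self.regress = tuple(regress)
        if classifier_input not in ("residuals", "corrected"):
            raise ValueError("classifier_input must be 'residuals' or 'corrected'")
        self.classifier_input = classifier_input
        self.qc_kwargs = qc_kwargs or {}
        # populated by prepare()
        self.qc_report: QcReport | None = None
        self.labels: AdtLabels | None = None
        self.norm: NormMatrix | None = None
        self.covariates: CellCovariates | None = None
        self._prepared = False

    @classmethod
    def from_files(cls, counts_path, adt_path, format: str = "mtx10x", **kwargs):
        from .io import read_adt, read_counts

        return cls(read_counts(counts_path, format=format), read_adt(adt_path), **kwargs)

    # ------------------------------------------------------------------
    def prepare(self, seed: int = 0) -> None:
        """QC, Otsu labeling, covariates and normalization (idempotent)."""
        if self._prepared:
            return
        m = self.counts
        if self.apply_qc:
            m, self.qc_report = _apply_qc(m, **self.qc_kwargs)
        else:
            self.qc_report = QcReport()
        adt = self.adt.align_to(m.cell_ids.astype(str))
        self.labels = label_adt(adt, margin=self.margin, n_bins=self.n_bins)
        keep = self.labels.training_mask()
        self._m_labeled = m.subset_cells(keep)
        self._y = self.labels.binary()
        self.covariates = cell_cycle_score(self._m_labeled, seed=seed)
        self.norm = normalize_regress(self._m_labeled, self.covariates, regress=self.regress)
        self._prepared = True

    def _input_matrix(self) -> np.ndarray:
        return (
            self.norm.values
            if self.classifier_input == "residuals"
            else self.norm.corrected_counts
        )

    # ------------------------------------------------------------------
    def fit(
        self,
        model_kind: str = "svm_rbf",
        *,
        optimize: bool = True,
        hp: HyperParams | None = None,
        max_iter: int = 30,
        ei_tol: float = 1e-6,
        k: int = 5,
        test_size: float = 0.2,
        seed: int = 42,
        audit: bool = False,
    ) -> "MarkerResults":
        """Train (and optionally hyperparameter-optimize) one classifier kind."""
        self.prepare(seed=seed)
        X = self._input_matrix()
        y = self._y
        cell_ids = self._m_labeled.cell_ids.astype(str)
        train_idx, test_idx = split_train_test(len(y), test_size=test_size, seed=seed)
        for cls_label, name in ((1, "positive"), (0, "negative")):
            if (y[train_idx] == cls_label).sum() == 0 or (y[test_idx] == cls_label).sum() == 0:
                import warnings

                warnings.warn(f"class {name!r} missing from one side of the split", stacklevel=2)

        audit_log: dict | None = {} if audit else None
        evaluator = CvEvaluator(
            X[train_idx], self.norm.corrected_counts[train_idx], y[train_idx],
            self.norm.gene_ids, cell_ids[train_idx], anchor=self.anchor, k=k,
            seed=seed, audit=audit_log,
        )

        opt_result: OptimizeResult | None = None
        if optimize:
            dims = search_dimensions(model_kind)

            def objective(params: dict) -> float:
                cand = HyperParams(model_kind=model_kind, **params)
                cv = evaluator.score(cand)
                # the optimizer maximizes; BCE is minimized via its negative
                return cv.mean if cv.metric == "accuracy" else -cv.mean

            opt_result = bayes_optimize(
                objective, dims, max_iter=max_iter, ei_tol=ei_tol, seed=seed
            )
            hp = HyperParams(model_kind=model_kind, **opt_result.best_params)
        elif hp is None:
            hp = HyperParams(model_kind=model_kind)

        cv_score = evaluator.score(hp)

        # final feature set + classifier from the entire training split
        if audit_log is not None:
            for stage in ("de", "corr", "fit"):
                audit_log.setdefault(stage, set()).update(cell_ids[train_idx])
        de = qp_glm_table(
            self.norm.corrected_counts[train_idx], y[train_idx] == 1, self.norm.gene_ids
        )
        corr = anchor_corr_table(X[train_idx], self.norm.gene_ids, self.anchor)
        feature_set = select_features(de, corr, hp.t_de_upper, hp.t_de_lower, hp.p_hn)
        gene_pos = {g: i for i, g in enumerate(np.asarray(self.norm.gene_ids, dtype=str))}
        cols = [gene_pos[g] for g in feature_set.genes]
        classifier = MarkerClassifier(model_kind, hp, seed=seed).fit(
            X[np.ix_(train_idx, cols)], y[train_idx]
        )

        metrics_train = evaluate_predictions(
            y[train_idx],
            classifier.predict(X[np.ix_(train_idx, cols)]),
            classifier.predict_score(X[np.ix_(train_idx, cols)]),
        )
        metrics_test = evaluate_predictions(
            y[test_idx],
            classifier.predict(X[np.ix_(test_idx, cols)]),
            classifier.predict_score(X[np.ix_(test_idx, cols)]),
        )

        return MarkerResults(
            model=self,
            model_kind=model_kind,
            hp=hp,
            feature_set=feature_set,
            classifier=classifier,
            de_result=de,
            corr_result=corr,
            cv_score=cv_score,
            optimizer=opt_result,
            metrics_train=metrics_train,
            metrics_test=metrics_test,
            train_barcodes=cell_ids[train_idx],
            test_barcodes=cell_ids[test_idx],
            seed=seed,
            audit_log=audit_log,
        )


@dataclass
class MarkerResults:
    """Fitted marker classifier with its estimates and diagnostics."""

    model: MarkerModel
    model_kind: str
    hp: HyperParams
    feature_set: FeatureSet
    classifier: MarkerClassifier
    de_result: DeResult
    corr_result: CorrResult
    cv_score: CvScore
    optimizer: OptimizeResult | None
    metrics_train: dict
    metrics_test: dict
    train_barcodes: np.ndarray
    test_barcodes: np.ndarray
    seed: int
    audit_log: dict | None = None

    @property
    def params(self) -> dict:
        return self.hp.to_dict()

    def summary(self) -> str:
        def pct(x):
            return "undefined" if x is None else f"{100 * x:.2f}%"

        lines = [
            "Marker classifier results",
            "=" * 60,
            f"model kind:          {self.model_kind}",
            f"anchor gene:         {self.model.anchor}",
            f"Otsu threshold t*:   {self.model.labels.t_star:.4f} "
            f"(margin ±{self.model.labels.margin})",
            f"labeled cells:       {self.model.labels.n_positive} positive, "
            f"{self.model.labels.n_negative} negative, "
            f"{self.model.labels.n_excluded} excluded",
            f"train/test cells:    {len(self.train_barcodes)}/{len(self.test_barcodes)}",
            "-" * 60,
            "hyperparameters:",
        ]
        for name, value in self.params.items():
            if name == "model_kind":
                continue
            lines.append(f"  {name:12s} = {value:g}" if isinstance(value, (int, float))
                         else f"  {name:12s} = {value}")
        prov = pd.Series(list(self.feature_set.provenance.values())).value_counts()
        lines += [
            "-" * 60,
            f"features:            {len(self.feature_set)} "
            f"({', '.join(f'{k}: {v}' for k, v in prov.items())})",
            f"CV ({self.cv_score.metric}): mean {self.cv_score.mean:.4f} over "
            f"{len(self.cv_score.fold_values)} folds",
            f"training accuracy:   {pct(self.metrics_train['accuracy'])}",
            f"test accuracy:       {pct(self.metrics_test['accuracy'])}",
            f"test precision:      {pct(self.metrics_test['precision'])}",
            f"test recall:         {pct(self.metrics_test['recall'])}",
        ]
        if "roc_auc" in self.metrics_test:
            lines.append(f"test ROC AUC:        {self.metrics_test['roc_auc']:.4f}")
        return "\n".join(lines)

    # -- inference ------------------------------------------------------
    def to_trained_model(self):
        from .inference import TrainedModel

        return TrainedModel(
            model_kind=self.model_kind,
            classifier=self.classifier,
            feature_set=self.feature_set,
            norm_params=self.model.norm.params,
            classifier_input=self.model.classifier_input,
            decision_threshold=self.classifier.decision_threshold,
            metadata={
                "seed": int(self.seed),
                "hyperparams": _jsonable(self.params),
                "cv_metric": self.cv_score.metric,
                "cv_mean": self.cv_score.mean,
                "cv_folds": [float(v) for v in self.cv_score.fold_values],
                "training_accuracy": self.metrics_train["accuracy"],
                "optimizer_trace": (
                    [
                        {"iteration": r["iteration"], "score": r["score"],
                         "params": _jsonable(r["params"])}
                        for r in self.optimizer.trace
                    ]
                    if self.optimizer is not None
                    else []
                ),
            },
        )

    def predict(self, counts: CountMatrix, normalize: bool = True) -> pd.DataFrame:
        from .inference import infer

        return infer(self.to_trained_model(), counts, normalize=normalize)

    def save(self, path) -> None:
        self.to_trained_model().save(path)

    # -- plotting -------------------------------------------------------
    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if "roc_curve" not in self.metrics_test:
            raise ValueError("test split has a single class; no ROC curve")
        if ax is None:
            _, ax = plt.subplots()
        rc = self.metrics_test["roc_curve"]
        ax.plot(rc["fpr"], rc["tpr"],
                label=f"{self.model_kind} (AUC={self.metrics_test['roc_auc']:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            out[k] = int(v)
        elif isinstance(v, (np.floating,)):
            out[k] = float(v)
        else:
            out[k] = v
    return out
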