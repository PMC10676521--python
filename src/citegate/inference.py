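"""Apply a trained marker classifier to new scRNA-seq count matrices.

Query preprocessing reuses the training-time per-gene rate and dispersion
(library-size offsets are recomputed on the query, covariate regression is
skipped unless covariates are supplied); query genes are aligned to the
stored feature list, with absent genes zero-filled. Models travel as a zip
archive with a manifest of member SHA-256 hashes that is verified on load.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings
import zipfile
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd

from .classifiers import MarkerClassifier
from .containers import CountMatrix
from .features import FeatureSet
from .gating import LABEL_NEGATIVE, LABEL_POSITIVE
from .preprocess import CellCovariates, NormParams, _regress_out, residual_transform

ARCHIVE_FORMAT_VERSION = 1


class ArchiveError(ValueError):
    """Model archive is corrupt, truncated or tampered with."""


def align_features(values: np.ndarray, gene_ids, fs: FeatureSet,
                   warn_frac: float = 0.2, error_frac: float = 0.5) -> np.ndarray:
    """Restrict/reorder columns to ``fs.genes``, zero-filling absent genes.

    Warns above ``warn_frac`` missing, errors above ``error_frac``.
    """
    genes = np.asarray(gene_ids, dtype=str)
    pos = {g: i for i, g in enumerate(genes)}
    missing = [g for g in fs.genes if g not in pos]
    frac = len(missing) / len(fs.genes)
    if frac > error_frac:
        raise ValueError(
            f"feature space mismatch: {len(missing)}/{len(fs.genes)} "
            f"({100 * frac:.0f}%) features absent from the query matrix"
        )
    if frac > warn_frac:
        warnings.warn(
            f"{len(missing)}/{len(fs.genes)} features absent from the query; zero-filled",
            stacklevel=2,
        )
    elif missing:
        warnings.warn(f"features absent from the query (zero-filled): {missing[:10]}",
                      stacklevel=2)
    out = np.zeros((values.shape[0], len(fs.genes)), dtype=float)
    for j, g in enumerate(fs.genes):
        if g in pos:
            out[:, j] = values[:, pos[g]]
    return out


@dataclass
class TrainedModel:
    """Serializable bundle: classifier + feature set + preprocessing contract."""

    model_kind: str
    classifier: MarkerClassifier
    feature_set: FeatureSet
    norm_params: NormParams
    classifier_input: str = "residuals"
    decision_threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        members: dict[str, bytes] = {}
        buf = _io.BytesIO()
        joblib.dump({"classifier": self.classifier}, buf)
        members["model.joblib"] = buf.getvalue()
        members["featureset.json"] = self.feature_set.to_json().encode()
        members["preprocessing.json"] = json.dumps(
            {
                "norm_params": self.norm_params.to_dict(),
                "classifier_input": self.classifier_input,
                "decision_threshold": self.decision_threshold,
            },
            indent=2,
        ).encode()
        members["metadata.json"] = json.dumps(
            {"model_kind": self.model_kind, **self.metadata}, indent=2
        ).encode()
        manifest = {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "tool": "citegate",
            "members": {name: hashlib.sha256(data).hexdigest() for name, data in members.items()},
        }
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("manifest.json", json.dumps(manifest, indent=2))
            for name, data in members.items():
                zf.writestr(name, data)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        try:
            with zipfile.ZipFile(path) as zf:
                manifest = json.loads(zf.read("manifest.json"))
                if manifest.get("format_version") != ARCHIVE_FORMAT_VERSION:
                    raise ArchiveError(
                        f"unsupported archive format version: {manifest.get('format_version')}"
                    )
                members = {}
                for name, digest in manifest["members"].items():
                    data = zf.read(name)
                    if hashlib.sha256(data).hexdigest() != digest:
                        raise ArchiveError(f"manifest hash mismatch for member {name!r}")
                    members[name] = data
        except (zipfile.BadZipFile, KeyError, EOFError) as exc:
            raise ArchiveError(f"manifest hash mismatch or truncated archive: {exc}") from exc
        payload = joblib.load(_io.BytesIO(members["model.joblib"]))
        pre = json.loads(members["preprocessing.json"])
        meta = json.loads(members["metadata.json"])
        model_kind = meta.pop("model_kind")
        return cls(
            model_kind=model_kind,
            classifier=payload["classifier"],
            feature_set=FeatureSet.from_json(members["featureset.json"].decode()),
            norm_params=NormParams.from_dict(pre["norm_params"]),
            classifier_input=pre["classifier_input"],
            decision_threshold=pre["decision_threshold"],
            metadata=meta,
        )


def _query_matrix(model: TrainedModel, m: CountMatrix, normalize: bool,
                  covariates: CellCovariates | None,
                  regress: tuple[str, ...] = ()) -> np.ndarray:
    if not normalize:
        return align_features(m.dense().astype(float), m.gene_ids, model.feature_set)
    params = model.norm_params
    # align query counts to the training gene axis before the residual transform
    train_fs = FeatureSet(genes=[str(g) for g in params.gene_ids])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # coverage is checked on the feature list below
        counts = align_features(m.dense().astype(float), m.gene_ids,
                                train_fs, warn_frac=1.1, error_frac=1.1)
    # report coverage in terms of the classifier's feature list
    genes = set(np.asarray(m.gene_ids, dtype=str))
    missing = [g for g in model.feature_set.genes if g not in genes]
    frac = len(missing) / len(model.feature_set.genes)
    if frac > 0.5:
        raise ValueError(
            f"feature space mismatch: {len(missing)}/{len(model.feature_set.genes)} "
            "features absent from the query matrix"
        )
    if frac > 0.2:
        warnings.warn(
            f"{len(missing)}/{len(model.feature_set.genes)} features absent from the query",
            stacklevel=3,
        )
    library = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    r = residual_transform(counts, library, params)
    if covariates is not None and regress:
        r = _regress_out(r, [(name, covariates.get(name)) for name in regress])
    if model.classifier_input == "corrected":
        mu_med = params.median_library * params.rate
        sd_med = np.sqrt(mu_med + params.phi * mu_med**2)
        r = np.round(np.maximum(mu_med[None, :] + r * sd_med[None, :], 0.0))
    pos = {str(g): i for i, g in enumerate(params.gene_ids)}
    cols = [pos[g] for g in model.feature_set.genes if g in pos]
    out = np.zeros((r.shape[0], len(model.feature_set.genes)))
    j_out = [j for j, g in enumerate(model.feature_set.genes) if g in pos]
    out[:, j_out] = r[:, cols]
    return out


def infer(
    model: TrainedModel,
    m: CountMatrix,
    normalize: bool = True,
    covariates: CellCovariates | None = None,
    regress: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Score every cell of a query count matrix.

    Returns a DataFrame with columns ``barcode``, ``label`` and ``score``
    (probability for probabilistic models, decision value for SVMs); the
    label is positive iff score >= the stored decision threshold.
    """
    X = _query_matrix(model, m, normalize, covariates, regress)
    scores = model.classifier.predict_score(X)
    threshold = model.classifier.decision_threshold
    labels = np.where(scores >= threshold, LABEL_POSITIVE, LABEL_NEGATIVE)
    return pd.DataFrame(
        {"barcode": m.cell_ids.astype(str), "label": labels, "score": scores}
    )


def write_predictions(pred: pd.DataFrame, path) -> None:
    """Deterministic prediction CSV (full float precision)."""
    pred.to_csv(path, index=False, float_format="%.17g")
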