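"""ADT gating: Otsu thresholding and ternary positive/negative/excluded labels.

The marker-positive/negative split is learned from the ADT histogram by
Otsu's method — the threshold t* maximising the between-class variance
w0*w1*(mu0-mu1)^2 over candidate bin positions. Cells within ``margin`` of
t* (default 0.5 on the normalized-log ADT scale) are labelled ``excluded``
and never reach model training; boundaries are inclusive: positive iff
adt >= t* + margin, negative iff adt <= t* - margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AdtVector

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_EXCLUDED = "excluded"


class DegenerateAdtError(ValueError):
    pass


def adt_histogram(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram over [min, max] with its bin centers."""
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(float), centers


def otsu_threshold(adt: AdtVector | np.ndarray, n_bins: int = 256) -> float:
    """Histogram-based Otsu threshold of the ADT distribution.

    Returns the bin center maximising the between-class variance; the low
    class is every bin at or below the returned center. Deterministic: ties
    resolve to the lowest qualifying bin.
    """
    values = adt.values if isinstance(adt, AdtVector) else np.asarray(adt, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateAdtError("degenerate ADT distribution: need >= 2 distinct values")
    counts, centers = adt_histogram(values, n_bins)
    w0 = np.cumsum(counts)
    w1 = np.cumsum(counts[::-1])[::-1]
    mu0 = np.cumsum(counts * centers) / np.where(w0 > 0, w0, 1.0)
    rev_w1 = np.cumsum(counts[::-1])
    mu1 = (np.cumsum((counts * centers)[::-1]) / np.where(rev_w1 > 0, rev_w1, 1.0))[::-1]
    # candidate split after bin i: classes {<=i}, {>i}
    between = w0[:-1] * w1[1:] * (mu0[:-1] - mu1[1:]) ** 2
    return float(centers[int(np.argmax(between))])


@dataclass
class AdtLabels:
    """Ternary marker call per cell plus the threshold that produced it."""

    labels: np.ndarray  # values in {positive, negative, excluded}
    cell_ids: np.ndarray
    t_star: float
    margin: float
    n_bins: int

    @property
    def n_positive(self) -> int:
        return int((self.labels == LABEL_POSITIVE).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == LABEL_NEGATIVE).sum())

    @property
    def n_excluded(self) -> int:
        return int((self.labels == LABEL_EXCLUDED).sum())

    def training_mask(self) -> np.ndarray:
        return self.labels != LABEL_EXCLUDED

    def binary(self) -> np.ndarray:
        """1 = positive, 0 = negative, over non-excluded cells only."""
        mask = self.training_mask()
        return (self.labels[mask] == LABEL_POSITIVE).astype(int)


def assign_labels(
    adt: AdtVector,
    t_star: float,
    margin: float = 0.5,
) -> AdtLabels:
    """Ternary labels around t*: the open interval (t*-margin, t*+margin) is excluded."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    v = adt.values
    labels = np.full(v.size, LABEL_EXCLUDED, dtype=object)
    labels[v >= t_star + margin] = LABEL_POSITIVE
    labels[v <= t_star - margin] = LABEL_NEGATIVE
    if not (labels != LABEL_EXCLUDED).any():
        raise ValueError("all cells fall inside the exclusion margin; use a smaller margin")
    return AdtLabels(labels=labels, cell_ids=adt.cell_ids, t_star=float(t_star),
                     margin=float(margin), n_bins=0)


def label_adt(adt: AdtVector, margin: float = 0.5, n_bins: int = 256) -> AdtLabels:
    """Otsu-threshold the ADT vector and assign ternary labels."""
    t_star = otsu_threshold(adt, n_bins=n_bins)
    out = assign_labels(adt, t_star, margin)
    out.n_bins = n_bins
    return out
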