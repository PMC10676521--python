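"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: explicit
loops, naive formulas, grid searches. They are slow and only run on tiny
inputs.
"""

from __future__ import annotations

import numpy as np


def otsu_between_variances(values: np.ndarray, n_bins: int):
    """Between-class variance of every candidate split, by explicit loops.

    Returns (variances, centers) where variances[i] is w0*w1*(mu0-mu1)^2 for
    the split {bins <= i} vs {bins > i} (-inf where a class is empty).
    """
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    out = np.full(n_bins - 1, -np.inf)
    for i in range(n_bins - 1):
        w0 = counts[: i + 1].sum()
        w1 = counts[i + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float((counts[: i + 1] * centers[: i + 1]).sum()) / w0
        mu1 = float((counts[i + 1:] * centers[i + 1:]).sum()) / w1
        out[i] = w0 * w1 * (mu0 - mu1) ** 2
    return out, centers


def assert_otsu_attains_maximum(threshold: float, values: np.ndarray, n_bins: int,
                                rtol: float = 1e-9) -> None:
    """Check a threshold is an argmax of the exhaustive between-class search.

    When the data leave an empty stretch between modes, every split inside
    it is an exact mathematical tie, so the contract is membership in the
    argmax set (to float tolerance), not index identity.
    """
    variances, centers = otsu_between_variances(values, n_bins)
    idx = int(np.argmin(np.abs(centers[:-1] - threshold)))
    best = variances.max()
    assert variances[idx] >= best * (1.0 - rtol) - 1e-300, (
        f"threshold {threshold} attains {variances[idx]}, oracle max {best}"
    )


def otsu_brute_force(values: np.ndarray, n_bins: int) -> float:
    """Exhaustive search over every candidate bin threshold.

    For each split point, the between-class variance w0*w1*(mu0-mu1)^2 is
    computed with explicit loops over the histogram; the returned threshold
    is the bin center of the best split (first maximum wins).
    """
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best, best_t = -np.inf, None
    for i in range(n_bins - 1):
        w0 = counts[: i + 1].sum()
        w1 = counts[i + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float((counts[: i + 1] * centers[: i + 1]).sum()) / w0
        mu1 = float((counts[i + 1:] * centers[i + 1:]).sum()) / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best:
            best, best_t = v, centers[i]
    assert best_t is not None
    return float(best_t)


def quasi_loglik_naive(y: np.ndarray, mu: float, phi: float) -> float:
    """Per-observation quasi-likelihood sum, scalar mean, explicit loop."""
    total = 0.0
    for yi in y:
        if yi > 0:
            total += yi * np.log(mu)
        total -= (yi + 1.0 / phi) * np.log1p(phi * mu)
    return total


def glm_grid_oracle(y: np.ndarray, cond: np.ndarray) -> float:
    """LRT statistic D by grid maximisation of the quasi-likelihood.

    The dispersion is moment-estimated at the group means (independent
    arithmetic), then the full-model group means and the null pooled mean
    are each found by a refining 1-D grid search (the quasi-likelihood is
    separable across conditions), and D = 2*(Q_full - Q_null).
    """
    y = np.asarray(y, dtype=float)
    cond = np.asarray(cond, dtype=bool)
    y1, y2 = y[cond], y[~cond]
    m1, m2 = y1.mean(), y2.mean()
    mu_hat = np.where(cond, m1, m2)
    phi = max(
        float(np.sum((y - mu_hat) ** 2 - mu_hat)) / float(np.sum(mu_hat**2)), 1e-8
    )

    def grid_max(yg: np.ndarray) -> float:
        lo, hi = max(yg.mean() * 0.2, 1e-6), yg.mean() * 5.0 + 1e-6
        best_mu = yg.mean()
        for _ in range(4):  # refine the grid around the current best
            grid = np.linspace(lo, hi, 2001)
            vals = [quasi_loglik_naive(yg, m, phi) for m in grid]
            best_mu = grid[int(np.argmax(vals))]
            width = (hi - lo) / 2000 * 4
            lo, hi = max(best_mu - width, 1e-9), best_mu + width
        return quasi_loglik_naive(yg, best_mu, phi)

    q_full = grid_max(y1) + grid_max(y2)
    q_null = grid_max(y)
    return 2.0 * (q_full - q_null)


def bh_stepup_naive(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recipe."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        q = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, q)
        q_sorted[rank_from_top] = min(running_min, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def spearman_naive(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho via explicit average ranks and the Pearson formula."""

    def ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0  # average of 1-based positions i..j
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    return float((rxc * ryc).sum() / denom)
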