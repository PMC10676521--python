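"""Gaussian-process Bayesian optimization with expected improvement.

A GP surrogate with a Matérn (nu = 2.5) kernel is fit to the observed
objective values; candidate points are scored by expected improvement (EI)
and the best candidate is evaluated next. No priors are placed on the
hyperparameters: the search box is sampled uniformly (5 space-filling
Latin-hypercube points to start), inputs are min-max scaled to the unit box
and GP length scales are set by marginal likelihood. Optimization stops at
``max_iter`` total evaluations or as soon as the maximal EI over candidates
drops below ``ei_tol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


class OptimizationError(RuntimeError):
    pass


@dataclass
class Dimension:
    """One search-box axis.

    ``log=True`` traverses the box in log space — the right parameterisation
    for positive scale parameters whose plausible values span orders of
    magnitude (SVM cost, kernel width, learning rate, selection fractions).
    The box endpoints are unchanged and no prior is placed on the value.
    """

    name: str
    low: float
    high: float
    integer: bool = False
    log: bool = False

    def from_unit(self, u: float) -> float:
        if self.log:
            v = float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        else:
            v = self.low + u * (self.high - self.low)
        return int(round(v)) if self.integer else float(v)


@dataclass
class OptimizeResult:
    best_params: dict
    best_score: float
    trace: list = field(default_factory=list)  # dicts: iteration, params, score
    stopped_early: bool = False

    def trace_frame(self):
        import pandas as pd

        rows = []
        for rec in self.trace:
            row = {"iteration": rec["iteration"], "score": rec["score"]}
            row.update(rec["params"])
            rows.append(row)
        return pd.DataFrame(rows)


def expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    """EI for maximization: E[max(f - best, 0)] under N(mu, sigma^2)."""
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def bayes_optimize(
    objective: Callable[[dict], float],
    dimensions: Sequence[Dimension],
    max_iter: int = 30,
    ei_tol: float = 1e-6,
    seed: int = 0,
    n_init: int = 5,
    n_candidates: int = 2048,
) -> OptimizeResult:
    """Maximise ``objective`` over the box with a GP-EI loop.

    ``objective`` receives a dict of parameter values and returns a scalar
    score (larger is better). The full evaluation trace is recorded; the
    returned optimum is the arg-best *observed* point.
    """
    dims = list(dimensions)
    d = len(dims)
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=d, seed=rng)
    n_init = min(n_init, max_iter)
    X_unit = [sampler.random(1)[0] for _ in range(n_init)]

    def to_params(u: np.ndarray) -> dict:
        return {dim.name: dim.from_unit(float(ui)) for dim, ui in zip(dims, u)}

    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []
    trace: list[dict] = []

    def evaluate(u: np.ndarray) -> float:
        params = to_params(u)
        score = float(objective(params))
        X_obs.append(np.asarray(u, dtype=float))
        y_obs.append(score)
        trace.append({"iteration": len(y_obs), "params": params, "score": score})
        return score

    for u in X_unit:
        evaluate(u)

    stopped_early = False
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.5), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    while len(y_obs) < max_iter:
        X = np.vstack(X_obs)
        y = np.asarray(y_obs, dtype=float)
        if np.ptp(y) == 0:
            # a constant response gives the surrogate nothing to model and
            # makes EI identically zero; explore the point farthest from
            # everything observed instead of stopping on a false plateau
            candidates = rng.random((n_candidates, d))
            dists = np.min(
                ((candidates[:, None, :] - X[None, :, :]) ** 2).sum(axis=2), axis=1
            )
            evaluate(candidates[int(np.argmax(dists))])
            continue
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, alpha=1e-8, n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(X, y)
        candidates = rng.random((n_candidates, d))
        mu, sigma = gp.predict(candidates, return_std=True)
        ei = expected_improvement(mu, sigma, float(y.max()))
        best_idx = int(np.argmax(ei))
        if ei[best_idx] < ei_tol:
            stopped_early = True
            break
        evaluate(candidates[best_idx])

    y = np.asarray(y_obs, dtype=float)
    if np.all(y == 0):
        raise OptimizationError("optimization degenerate: every evaluation scored 0")
    best = int(np.argmax(y))
    return OptimizeResult(
        best_params=trace[best]["params"],
        best_score=float(y[best]),
        trace=trace,
        stopped_early=stopped_early,
    )
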