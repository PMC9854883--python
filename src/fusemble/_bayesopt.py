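"""Seeded sequential model-based (Bayesian) maximization over the unit box.

A Gaussian-process surrogate (Matérn 5/2) with expected-improvement
acquisition over a random candidate pool.  Deterministic under a fixed seed.
Used for voting-weight optimization; deliberately small and dependency-free
beyond scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

import warnings

__all__ = ["maximize_on_unit_box", "OptResult"]


@dataclass
class OptResult:
    x: np.ndarray
    value: float
    n_evals: int
    history: np.ndarray  # best-so-far trace


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def maximize_on_unit_box(
    f,
    dim: int,
    budget: int,
    seed: int,
    first_point: np.ndarray = None,
    n_candidates: int = 256,
) -> OptResult:
    """Maximize ``f`` over [0, 1]^dim with at most ``budget`` evaluations.

    ``first_point`` (if given) is always evaluated first, so the returned
    optimum never scores below it on ``f``.  Roughly the first quarter of the
    budget (at least 2·dim points, at most budget) is random exploration; the
    remainder is GP/EI guided.  All-zero proposals are re-sampled because a
    zero weight vector is degenerate for voting.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)

    def draw(n):
        x = rng.random((n, dim))
        # re-sample rows that are numerically all-zero
        for i in range(n):
            while np.max(x[i]) < 1e-9:
                x[i] = rng.random(dim)
        return x

    X, y = [], []

    def evaluate(x):
        X.append(np.asarray(x, dtype=float))
        y.append(float(f(X[-1])))

    if first_point is not None:
        evaluate(np.asarray(first_point, dtype=float))
    n_init = min(budget - len(X), max(2 * dim, max(1, budget // 4)))
    for x in draw(n_init):
        evaluate(x)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(dim, 0.5), length_scale_bounds=(1e-2, 1e2), nu=2.5
    )
    while len(X) < budget:
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-6,
            normalize_y=True,
            n_restarts_optimizer=0,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.asarray(X), np.asarray(y))
        cand = draw(n_candidates)
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, max(y))
        evaluate(cand[int(np.argmax(ei))])

    y_arr = np.asarray(y)
    best = int(np.argmax(y_arr))
    return OptResult(
        x=np.asarray(X)[best],
        value=float(y_arr[best]),
        n_evals=len(y),
        history=np.maximum.accumulate(y_arr),
    )
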