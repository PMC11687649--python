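"""Seeded sequential model-based hyperparameter optimization.

A compact Bayesian-optimization loop: random exploration followed by a
Gaussian-process surrogate (Matern 5/2) with expected-improvement
acquisition over the unit hypercube.  Parameters are encoded to [0, 1]
(log-scaled where requested) and decoded back on evaluation.  The whole
loop is deterministic given the seed, which is what the repeated-
experiment harness needs for exact reruns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .datamodel import ConfigurationError


@dataclass(frozen=True)
class Dimension:
    """One search dimension: linear or log scale, float or integer."""

    name: str
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def decode(self, u: float) -> float | int:
        if self.log:
            value = np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low)))
        else:
            value = self.low + u * (self.high - self.low)
        return int(round(value)) if self.integer else float(value)


@dataclass
class OptimizationResult:
    best_params: dict
    best_score: float
    history: list[tuple[dict, float]]


def maximize(
    objective: Callable[[Mapping[str, float | int]], float],
    space: Sequence[Dimension],
    budget: int = 30,
    seed: int = 0,
    n_candidates: int = 256,
) -> OptimizationResult:
    """Maximize ``objective`` over ``space`` with ``budget`` evaluations."""
    if budget < 5:
        raise ConfigurationError("tuning budget must be >= 5")
    rng = np.random.default_rng(seed)
    dim = len(space)
    n_init = max(min(budget // 3, 10), 3)

    U: list[np.ndarray] = []
    scores: list[float] = []
    history: list[tuple[dict, float]] = []

    def run(u: np.ndarray) -> None:
        params = {d.name: d.decode(float(u[k])) for k, d in enumerate(space)}
        s = float(objective(params))
        U.append(u)
        scores.append(s)
        history.append((params, s))

    for _ in range(min(n_init, budget)):
        run(rng.random(dim))

    while len(scores) < budget:
        X = np.vstack(U)
        y = np.asarray(scores)
        # fixed length-scale surrogate: cheap, deterministic, and adequate
        # over the unit hypercube at these budgets
        gp = GaussianProcessRegressor(
            kernel=Matern(length_scale=np.full(dim, 0.3), nu=2.5,
                          length_scale_bounds="fixed"),
            alpha=1e-6,
            normalize_y=True,
            optimizer=None,
            random_state=int(rng.integers(2**31)),
        )
        # duplicate points can make the GP fit ill-conditioned; jitter alpha up
        try:
            gp.fit(X, y)
        except np.linalg.LinAlgError:  # pragma: no cover - rare
            gp.alpha = 1e-3
            gp.fit(X, y)
        cand = rng.random((n_candidates, dim))
        mu, sd = gp.predict(cand, return_std=True)
        best = y.max()
        sd = np.maximum(sd, 1e-12)
        z = (mu - best) / sd
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        run(cand[int(np.argmax(ei))])

    k = int(np.argmax(scores))
    return OptimizationResult(
        best_params=history[k][0], best_score=scores[k], history=history
    )
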