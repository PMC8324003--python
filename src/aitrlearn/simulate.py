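"""Synthetic randomized-trial generators for the three benchmark designs.

All designs draw covariates uniformly on [-1, 1]^p, assign the treatment
uniformly at random (propensity 1/k), and set ``Y = mu_A(X) + eps`` with
``eps ~ N(0, noise_variance)``.  The conditional mean functions:

* Example 1 (k=3): ``mu_1 = 1 + 3 X1^2 + 3 X2^2``,
  ``mu_2 = 3 - 0.5 X1^2 - 0.5 X2^2``, ``mu_3 = 3 + X1 + X2`` — one
  quadratic bowl against two nearly flat arms, giving about 70/25/5
  percent of the space to one-, two- and three-treatment oracle sets at
  c = 1.2.
* Example 2 (k=4): ``mu_A = 2 + sign(A - 2.5) cos(pi (X1 + (-1)^A X2)/2)``
  — arms 2 and 4 are everywhere dominated, but come within the
  near-optimality band on part of the space.
* Example 3 (k=3): ``mu_1 = max(2.5, 2.3 + X1^2 + X2^2)``,
  ``mu_2 = 2.7 - 2 X1 + exp(X3^2) - X4^3``,
  ``mu_3 = min(3, 3.2 - X1^2 - X2^2)`` — the clipping creates regions of
  exactly proportional means, violating the no-ties margin condition the
  one-step theory assumes.

Every generator is fully reproducible from an integer seed and also
returns the per-arm potential outcomes needed for performance intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import Dataset

logger = logging.getLogger(__name__)

__all__ = ["DGPSpec", "PotentialOutcomeTable", "true_mu", "draw_dataset", "toy_2d"]

_K_BY_EXAMPLE = {1: 3, 2: 4, 3: 3, "toy": 3}
_MIN_P = {1: 2, 2: 2, 3: 4, "toy": 2}


@dataclass(frozen=True)
class DGPSpec:
    """One simulation design.

    ``noise_variance`` is the variance of the Gaussian outcome noise
    (default 1/2, i.e. sd ~ 0.707).  ``shared_noise`` draws one noise
    variable per subject shared across arms instead of independent
    per-arm draws; the default is independent, which is what the
    potential-outcome performance intervals use.
    """

    example_id: int | str = 1
    p: int = 5
    noise_variance: float = 0.5
    c: float = 1.2
    shared_noise: bool = False

    def __post_init__(self):
        if self.example_id not in _K_BY_EXAMPLE:
            raise ValueError(f"unknown example {self.example_id!r}")
        if self.p < _MIN_P[self.example_id]:
            raise ValueError(
                f"example {self.example_id} needs p >= {_MIN_P[self.example_id]}"
            )
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be nonnegative")

    @property
    def k(self) -> int:
        return _K_BY_EXAMPLE[self.example_id]

    @property
    def propensity(self) -> float:
        return 1.0 / self.k


@dataclass
class PotentialOutcomeTable:
    """True means and realized potential outcomes, one column per arm."""

    mu: np.ndarray     # (n, k)
    ystar: np.ndarray  # (n, k)


def true_mu(spec: DGPSpec, X: np.ndarray) -> np.ndarray:
    """Evaluate the design's conditional mean functions at X (n, p)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size and (X.min() < -1 or X.max() > 1):
        logger.warning("covariates outside [-1, 1]; formulas applied anyway")
    x1 = X[:, 0]
    x2 = X[:, 1]
    ex = spec.example_id
    if ex in (1, "toy"):
        return np.stack(
            [
                1.0 + 3.0 * x1 ** 2 + 3.0 * x2 ** 2,
                3.0 - 0.5 * x1 ** 2 - 0.5 * x2 ** 2,
                3.0 + x1 + x2,
            ],
            axis=1,
        )
    if ex == 2:
        arms = np.arange(1, 5)
        return 2.0 + np.sign(arms - 2.5) * np.cos(
            0.5 * np.pi * (x1[:, None] + (-1.0) ** arms * x2[:, None])
        )
    x3 = X[:, 2]
    x4 = X[:, 3]
    return np.stack(
        [
            np.maximum(2.5, 2.3 + x1 ** 2 + x2 ** 2),
            2.7 - 2.0 * x1 + np.exp(x3 ** 2) - x4 ** 3,
            np.minimum(3.0, 3.2 - x1 ** 2 - x2 ** 2),
        ],
        axis=1,
    )


def draw_dataset(
    spec: DGPSpec, n: int, seed: int
) -> tuple[Dataset, PotentialOutcomeTable]:
    """Draw a randomized-trial sample of size n.

    The observed outcome is the assigned arm's entry of the potential
    outcome table, so the consistency identity
    ``Y = sum_j Y*(j) 1[A = j]`` holds exactly.
    """
    rng = np.random.default_rng(seed)
    k = spec.k
    X = rng.uniform(-1.0, 1.0, size=(n, spec.p))
    A = rng.integers(1, k + 1, size=n)
    mu = true_mu(spec, X) if n else np.empty((0, k))
    sd = np.sqrt(spec.noise_variance)
    if spec.shared_noise:
        eps = rng.normal(0.0, sd, size=(n, 1)) * np.ones((1, k))
    else:
        eps = rng.normal(0.0, sd, size=(n, k))
    ystar = mu + eps
    y = ystar[np.arange(n), A - 1] if n else np.empty(0)
    data = Dataset(
        X=X.reshape(n, spec.p), A=A, y=y,
        propensity=np.full(n, spec.propensity), k=k,
    )
    return data, PotentialOutcomeTable(mu=mu, ystar=ystar)


def toy_2d(n: int, seed: int) -> tuple[Dataset, PotentialOutcomeTable]:
    """Example 1 restricted to p = 2, for boundary plots and smoke tests."""
    return draw_dataset(DGPSpec(example_id="toy", p=2), n, seed)
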