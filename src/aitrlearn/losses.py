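"""Increasing convex surrogate losses for outcome-weighted learning.

Because a *smaller* outcome is preferred here, all surrogates are increasing
in the margin (the mirror image of the usual classification losses).  Two
families matter:

* differentiable losses (``squared``, ``exponential``) drive the two-step
  rule, which recovers conditional-mean *ratios* from derivative ratios of
  the population minimizer;
* bent losses (``bent_hinge``, and bent variants of the smooth losses) add
  an extra slope ``c - 1`` on the positive half-line.  The kink at zero
  shrinks the margins of near-optimal treatments to exactly zero at the
  population optimum, which is what makes the one-step set rule work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["LossSpec", "loss_value", "loss_derivative", "ratio_estimate"]

_FAMILIES = (
    "hinge",
    "bent_hinge",
    "squared",
    "exponential",
    "bent_squared",
    "bent_exponential",
)
_DIFFERENTIABLE = ("squared", "exponential")
_BENT = ("bent_hinge", "bent_squared", "bent_exponential")


@dataclass(frozen=True)
class LossSpec:
    """A surrogate loss: a family name plus the near-optimality slope ``c``.

    ``c`` (>= 1) is only active for the bent families, where the loss is
    ``l1(u) + (c - 1) u_+``.  ``derivative_floor`` guards the squared-loss
    derivative (which vanishes at u = -1) inside :func:`ratio_estimate`.
    """

    family: str
    c: float = 1.0
    derivative_floor: float = 1e-6

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown loss family {self.family!r}")
        if self.c < 1.0:
            raise ValueError(f"near-optimality constant c must be >= 1, got {self.c}")
        if self.derivative_floor <= 0:
            raise ValueError("derivative_floor must be positive")

    @property
    def is_differentiable(self) -> bool:
        return self.family in _DIFFERENTIABLE

    @property
    def bent_slope(self) -> float:
        """Extra slope on u > 0 (zero for the plain families)."""
        return self.c - 1.0 if self.family in _BENT else 0.0


def _l1_value(family: str, u: np.ndarray) -> np.ndarray:
    if family in ("hinge", "bent_hinge"):
        return np.maximum(1.0 + u, 0.0)
    if family in ("squared", "bent_squared"):
        return (1.0 + u) ** 2
    # exponential / bent_exponential
    return np.exp(u)


def _l1_derivative(family: str, u: np.ndarray) -> np.ndarray:
    if family in ("hinge", "bent_hinge"):
        # left-continuous subgradient: 0 at the kink u = -1
        return (u > -1.0).astype(float)
    if family in ("squared", "bent_squared"):
        return 2.0 * (1.0 + u)
    return np.exp(u)


def loss_value(spec: LossSpec, u) -> np.ndarray:
    """Evaluate the loss at margin ``u`` (scalar or array)."""
    u = np.asarray(u, dtype=float)
    out = _l1_value(spec.family, u)
    slope = spec.bent_slope
    if slope:
        out = out + slope * np.maximum(u, 0.0)
    return out


def loss_derivative(spec: LossSpec, u) -> np.ndarray:
    """Derivative of the loss at ``u``.

    At kinks the left-continuous convention applies: the bent-hinge
    derivative is 0 at u = -1 and 1 at u = 0 (its one-sided limits there are
    ``l'(0-) = 1`` and ``l'(0+) = c``).
    """
    u = np.asarray(u, dtype=float)
    out = _l1_derivative(spec.family, u)
    slope = spec.bent_slope
    if slope:
        out = out + slope * (u > 0.0)
    return out


def ratio_estimate(spec: LossSpec, margins: np.ndarray) -> np.ndarray:
    """Estimated mean-outcome ratios ``mu_j / mu_(1)`` from angle margins.

    At the population minimizer of the differentiable-loss problem, the
    derivative ratio ``l'(<W_(1), f>) / l'(<W_j, f>)`` equals the
    conditional-mean ratio ``mu_j / mu_(1)``, where ``(1)`` indexes the
    largest margin (the best treatment).  Applied verbatim to an estimated
    decision function, this is the two-step method's ratio estimator.

    Parameters
    ----------
    spec : LossSpec
        Must be a differentiable family (``squared`` or ``exponential``).
    margins : ndarray of shape (k,)

    Returns
    -------
    ndarray of shape (k,)
        Nonnegative ratios; the entry at the argmax margin is exactly 1.
    """
    if not spec.is_differentiable:
        raise ValueError(
            "ratio estimation requires a differentiable loss family, "
            f"got {spec.family!r}"
        )
    margins = np.asarray(margins, dtype=float)
    deriv = loss_derivative(spec, margins)
    best = int(np.argmax(margins))  # lowest index wins ties
    num = deriv[best]
    floor = spec.derivative_floor
    if num <= floor:
        logger.warning(
            "all loss derivatives at or below the floor %.2g; "
            "ratio estimates are unidentified (+inf)",
            floor,
        )
        out = np.full(margins.shape, np.inf)
        out[best] = 1.0
        return out
    out = num / np.maximum(deriv, floor)
    out[best] = 1.0
    return out
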