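"""Single- and set-valued treatment rules.

A set-valued recommendation ("A-ITR") maps covariates to the nonempty set
of treatments whose conditional mean outcome is within a multiplicative
factor ``c`` (the near-optimality constant, chosen by the clinician) of the
best one.  The oracle rule is ``phi*(x) = {j : mu_j(x)/mu_(1)(x) <= c}``.
A second oracle, ``phi+``, minimizes the cardinality-penalized weighted
outcome ``mu^phi = sum_{j in phi} mu_j / (1 + (|phi|-1) c)`` over all
nonempty subsets; the two coincide for k = 2 and are nested in general
(phi+ never recommends more treatments than phi*, and they agree on where
a single treatment suffices).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .losses import LossSpec, ratio_estimate

logger = logging.getLogger(__name__)

__all__ = [
    "RecommendationSet",
    "itr_rule",
    "two_step_rule",
    "one_step_rule",
    "plugin_rule",
    "mu_phi",
    "bayes_phi_star",
    "bayes_phi_plus",
]


@dataclass
class RecommendationSet:
    """Per-subject treatment subsets as a boolean membership matrix.

    ``membership[i, j]`` is True when treatment ``j+1`` is recommended to
    subject ``i``.  Every row is nonempty; ``itr``-tagged sets are
    singletons.
    """

    membership: np.ndarray  # (n, k) bool
    rule_tag: str

    def __post_init__(self):
        self.membership = np.atleast_2d(np.asarray(self.membership, dtype=bool))
        card = self.membership.sum(axis=1)
        if (card == 0).any():
            raise ValueError("empty recommendation set")
        if self.rule_tag == "itr" and (card != 1).any():
            raise ValueError("itr-tagged sets must be singletons")

    @property
    def n(self) -> int:
        return self.membership.shape[0]

    @property
    def k(self) -> int:
        return self.membership.shape[1]

    @property
    def cardinality(self) -> np.ndarray:
        return self.membership.sum(axis=1)

    def to_lists(self) -> list[list[int]]:
        """1-based treatment lists per subject."""
        return [[int(j) for j in np.flatnonzero(row) + 1]
                for row in self.membership]

    @classmethod
    def from_lists(cls, sets, k: int, rule_tag: str) -> "RecommendationSet":
        memb = np.zeros((len(sets), k), dtype=bool)
        for i, s in enumerate(sets):
            memb[i, np.asarray(list(s), dtype=int) - 1] = True
        return cls(memb, rule_tag)


def _rows(margins) -> np.ndarray:
    return np.atleast_2d(np.asarray(margins, dtype=float))


def itr_rule(margins) -> np.ndarray:
    """Single best treatment: argmax margin, lowest index on ties (1-based)."""
    m = _rows(margins)
    out = np.argmax(m, axis=1) + 1
    return out if np.ndim(margins) > 1 else int(out[0])


def two_step_rule(margins, loss: LossSpec, c: float) -> np.ndarray:
    """Membership of the two-step set ``{j : ratio_j <= c}``.

    Ratios come from :func:`aitrlearn.losses.ratio_estimate` on a
    differentiable loss; the argmax-margin treatment has ratio 1 and is
    always included.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    m = _rows(margins)
    memb = np.zeros(m.shape, dtype=bool)
    for i, row in enumerate(m):
        memb[i] = ratio_estimate(loss, row) <= c
    return memb if np.ndim(margins) > 1 else memb[0]


def one_step_rule(margins, delta: float = 0.0) -> np.ndarray:
    """Membership of the normalized one-step set.

    Recommends every treatment with margin at or above ``delta * M`` where
    ``M`` is the magnitude of the smallest (most negative) margin; at
    ``delta = 0`` this is the plain nonnegative-margin rule that the bent
    loss makes consistent.  ``delta`` is a small tuning constant around 0;
    values above 1 can empty the set, in which case the argmax singleton is
    substituted and a warning logged.
    """
    if delta > 1:
        logger.warning("delta=%.3g > 1 can produce empty sets", delta)
    m = _rows(margins)
    M = np.abs(m.min(axis=1))
    memb = m >= (delta * M)[:, None]
    empty = ~memb.any(axis=1)
    if empty.any():
        logger.warning("%d empty one-step sets replaced by the ITR singleton",
                       int(empty.sum()))
        best = np.argmax(m[empty], axis=1)
        memb[np.flatnonzero(empty), best] = True
    return memb if np.ndim(margins) > 1 else memb[0]


def plugin_rule(mu_hat, c: float) -> np.ndarray:
    """Regression plug-in set ``{j : mu_hat_j / min_i mu_hat_i <= c}``."""
    if c < 1:
        raise ValueError("c must be >= 1")
    mu = _rows(mu_hat)
    if (mu <= 0).any():
        raise ValueError("conditional mean estimates must be positive")
    memb = mu <= c * mu.min(axis=1, keepdims=True)
    return memb if np.ndim(mu_hat) > 1 else memb[0]


def mu_phi(mu, phi, c: float) -> float:
    """Cardinality-penalized weighted mean outcome of the set ``phi``.

    ``mu^phi = sum_{j in phi} mu_j / (1 + (|phi| - 1) c)``; for a singleton
    this is just that treatment's mean, and adding a treatment with
    ``mu_j < c * mu_(1)`` strictly decreases it.
    """
    mu = np.asarray(mu, dtype=float)
    phi = list(phi)
    if len(phi) == 0:
        raise ValueError("phi must be nonempty")
    idx = np.asarray(phi, dtype=int) - 1
    return float(mu[idx].sum() / (1.0 + (len(phi) - 1) * c))


def bayes_phi_star(mu, c: float) -> np.ndarray:
    """Oracle near-optimal set from true conditional means (= plugin rule)."""
    return plugin_rule(mu, c)


def _subsets_in_tiebreak_order(k: int) -> list[tuple[int, ...]]:
    subs = []
    for r in range(1, k + 1):
        subs.extend(itertools.combinations(range(1, k + 1), r))
    return subs  # sorted by cardinality, then lexicographic


def bayes_phi_plus(mu, c: float) -> np.ndarray:
    """Brute-force minimizer of ``mu^phi`` over all nonempty subsets.

    Ties broken by smaller cardinality, then lexicographic order, so the
    rule is deterministic even on crafted inputs where the generic
    no-ties condition fails.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    mu2 = _rows(mu)
    if (mu2 <= 0).any():
        raise ValueError("conditional means must be positive")
    n, k = mu2.shape
    subs = _subsets_in_tiebreak_order(k)
    vals = np.empty((n, len(subs)))
    for s_idx, sub in enumerate(subs):
        idx = np.asarray(sub, dtype=int) - 1
        vals[:, s_idx] = mu2[:, idx].sum(axis=1) / (1.0 + (len(sub) - 1) * c)
    best = np.argmin(vals, axis=1)  # first occurrence = tie-break order
    memb = np.zeros((n, k), dtype=bool)
    for i, s_idx in enumerate(best):
        memb[i, np.asarray(subs[s_idx], dtype=int) - 1] = True
    return memb if np.ndim(mu) > 1 else memb[0]
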