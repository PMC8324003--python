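"""Value estimation, region decomposition, and the two-stage tuning.

The value of a single-valued rule ``d`` is estimated by the
self-normalized IPW ratio

    sum_i 1[a_i = d_i] y_i / p_i  /  sum_i 1[a_i = d_i] / p_i ,

and the set-valued analogue penalizes cardinality with the near-optimality
constant ``c``:

    sum_i 1[a_i in phi_i] y_i / [p_i (1 + (|phi_i|-1) c)]
    ------------------------------------------------------ .
    sum_i 1[a_i in phi_i] / (p_i |phi_i|)

For singleton sets the two coincide exactly.  Tuning is two-stage: the
ridge penalty ``lambda`` is chosen by cross-validated value of the induced
single-valued rule, then (one-step method only) the margin threshold
``delta`` by the cross-validated weighted outcome of the induced sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .geometry import angle_margins, simplex_vertices
from .recommend import RecommendationSet, bayes_phi_star, one_step_rule
from .simulate import DGPSpec, true_mu

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedValueError",
    "EvalReport",
    "MCEstimate",
    "empirical_value",
    "empirical_weighted_outcome",
    "region_partition",
    "performance_interval",
    "tune_lambda",
    "tune_delta",
    "population_oracle",
    "LambdaTuning",
]


class UndefinedValueError(ValueError):
    """No subject matched the rule: the IPW denominator is empty."""


def empirical_value(data: Dataset, d) -> float:
    """Self-normalized IPW value of a single-valued rule.

    ``d`` is the per-subject recommended treatment (1-based array).
    Raises :class:`UndefinedValueError` when no subject took their
    recommended treatment.
    """
    d = np.asarray(d, dtype=int)
    match = data.A == d
    if not match.any():
        raise UndefinedValueError("rule never matches the observed treatment")
    inv_p = 1.0 / data.propensity[match]
    return float((data.y[match] * inv_p).sum() / inv_p.sum())


def empirical_weighted_outcome(data: Dataset, phi: RecommendationSet, c: float) -> float:
    """Self-normalized IPW weighted outcome of a set-valued rule."""
    memb = phi.membership
    card = phi.cardinality
    match = memb[np.arange(data.n), data.A - 1]
    if not match.any():
        raise UndefinedValueError("no observed treatment falls in its set")
    p = data.propensity[match]
    m = card[match].astype(float)
    num = (data.y[match] / (p * (1.0 + (m - 1.0) * c))).sum()
    den = (1.0 / (p * m)).sum()
    if den == 0:
        raise UndefinedValueError("zero IPW denominator")
    return float(num / den)


def region_partition(mu_true: np.ndarray, c: float) -> np.ndarray:
    """Label each subject R1/R2/R3 by the size of the oracle set phi*.

    R1: a single treatment; R2: several but not all; R3: all treatments.
    """
    mu_true = np.atleast_2d(np.asarray(mu_true, dtype=float))
    k = mu_true.shape[1]
    card = bayes_phi_star(mu_true, c).sum(axis=1)
    labels = np.where(card == 1, "R1", np.where(card == k, "R3", "R2"))
    return labels


def performance_interval(
    phi: RecommendationSet, potential_Y: np.ndarray, labels: np.ndarray
) -> tuple[dict[str, tuple[float, float]], list[str]]:
    """Per-region (best-case, worst-case) mean potential outcome.

    The lower limit assumes every subject picks the best treatment inside
    their recommended set, the upper the worst.  Returns the intervals and
    the list of regions with no subjects (omitted).
    """
    potential_Y = np.asarray(potential_Y, dtype=float)
    labels = np.asarray(labels)
    memb = phi.membership
    best = np.where(memb, potential_Y, np.inf).min(axis=1)
    worst = np.where(memb, potential_Y, -np.inf).max(axis=1)
    intervals: dict[str, tuple[float, float]] = {}
    missing: list[str] = []
    for region in ("R1", "R2", "R3"):
        mask = labels == region
        if not mask.any():
            missing.append(region)
            continue
        intervals[region] = (float(best[mask].mean()), float(worst[mask].mean()))
    return intervals, missing


@dataclass
class EvalReport:
    """Evaluation summary of one rule on one dataset."""

    value: float | None
    weighted_outcome: float | None
    region_labels: np.ndarray | None = None
    intervals: dict | None = None
    missing_regions: list = field(default_factory=list)
    cardinality_histogram: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "value": self.value,
            "weighted_outcome": self.weighted_outcome,
            "intervals": self.intervals,
            "missing_regions": self.missing_regions,
            "cardinality_histogram": self.cardinality_histogram,
        }
        if self.region_labels is not None:
            uniq, counts = np.unique(self.region_labels, return_counts=True)
            payload["region_counts"] = dict(zip(uniq.tolist(), counts.tolist()))
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _cv_folds(n: int, folds: int, seed: int):
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


@dataclass
class LambdaTuning:
    best_lambda: float
    cv_values: dict
    fold_fits: list  # [(FitResult, val_idx)] at the best lambda


def tune_lambda(
    data: Dataset,
    fit_fn,
    lambda_grid,
    folds: int = 5,
    seed: int = 0,
) -> LambdaTuning:
    """Pick ``lambda`` by cross-validated value of the induced ITR.

    ``fit_fn(train_data, lam) -> FitResult`` fits one candidate.  Grid
    points whose IPW denominator is empty in every fold are infeasible and
    skipped; ties go to the smaller lambda.
    """
    grid = sorted(set(float(l) for l in np.atleast_1d(lambda_grid)))
    if not grid:
        raise ValueError("empty lambda grid")
    geom = simplex_vertices(data.k)
    splits = _cv_folds(data.n, folds, seed)
    cv_values: dict[float, float] = {}
    fold_fits: dict[float, list] = {}
    for lam in grid:
        vals = []
        fits = []
        for tr_idx, va_idx in splits:
            fit = fit_fn(data.subset(tr_idx), lam)
            fits.append((fit, va_idx))
            val_data = data.subset(va_idx)
            margins = angle_margins(geom, fit.predict(val_data.X))
            d = np.argmax(margins, axis=1) + 1
            try:
                vals.append(empirical_value(val_data, d))
            except UndefinedValueError:
                vals.append(np.nan)
        vals = np.asarray(vals)
        if np.isnan(vals).all():
            logger.warning("lambda=%.4g infeasible in every fold; skipped", lam)
            continue
        cv_values[lam] = float(np.nanmean(vals))
        fold_fits[lam] = fits
    if not cv_values:
        raise UndefinedValueError("every lambda in the grid was infeasible")
    best = min(cv_values, key=lambda l: (cv_values[l], l))
    return LambdaTuning(best_lambda=best, cv_values=cv_values,
                        fold_fits=fold_fits[best])


def tune_delta(
    data: Dataset,
    fold_fits,
    delta_grid,
    c: float,
) -> tuple[float, dict]:
    """Pick the one-step threshold ``delta`` by cross-validated weighted outcome.

    ``fold_fits`` are the per-fold fits (at the tuned lambda) with their
    held-out indices.  Ties go to the delta closest to zero, then the
    smaller one.
    """
    grid = list(dict.fromkeys(float(d) for d in np.atleast_1d(delta_grid)))
    if not grid:
        raise ValueError("empty delta grid")
    geom = simplex_vertices(data.k)
    fold_margins = []
    for fit, va_idx in fold_fits:
        val_data = data.subset(va_idx)
        fold_margins.append((val_data, angle_margins(geom, fit.predict(val_data.X))))
    cv: dict[float, float] = {}
    for delta in grid:
        vals = []
        for val_data, margins in fold_margins:
            phi = RecommendationSet(one_step_rule(margins, delta), "one_step")
            try:
                vals.append(empirical_weighted_outcome(val_data, phi, c))
            except UndefinedValueError:
                vals.append(np.nan)
        vals = np.asarray(vals)
        if np.isnan(vals).all():
            continue
        cv[delta] = float(np.nanmean(vals))
    if not cv:
        raise UndefinedValueError("every delta in the grid was infeasible")
    best = min(cv, key=lambda d: (cv[d], abs(d), d))
    return best, cv


@dataclass(frozen=True)
class MCEstimate:
    value: float
    stderr: float
    n: int


def population_oracle(
    dgp: DGPSpec, rule, n_mc: int, seed: int = 0
) -> MCEstimate:
    """Monte-Carlo population value of an oracle rule.

    ``rule`` is ``"bayes_itr"`` (expected outcome of the best arm),
    ``"bayes_aitr"`` (expected ``mu^phi*`` with the design's ``c``), or a
    callable mapping the (n, k) true-mean matrix to a boolean membership
    matrix.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, size=(n_mc, dgp.p))
    mu = true_mu(dgp, X)
    if rule == "bayes_itr":
        vals = mu.min(axis=1)
    else:
        if rule == "bayes_aitr":
            memb = bayes_phi_star(mu, dgp.c)
        else:
            memb = np.atleast_2d(rule(mu))
        card = memb.sum(axis=1)
        vals = (mu * memb).sum(axis=1) / (1.0 + (card - 1) * dgp.c)
    return MCEstimate(
        value=float(vals.mean()),
        stderr=float(vals.std(ddof=1) / np.sqrt(n_mc)),
        n=n_mc,
    )
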