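"""Model/Results facade over the outcome-weighted learning machinery.

:class:`AITRModel` is built from data (arrays or a DataFrame) and a method
choice; ``fit`` returns an :class:`AITRResults` carrying the fitted
decision function, the tuned hyperparameters, diagnostics and a
``summary()`` table, in the style of statsmodels estimators.

Methods
-------
``one_step``
    Bent-hinge outcome-weighted classification solved in its dual; the
    recommendation set is the treatments with (normalized) nonnegative
    angle margins.
``two_step``
    Differentiable-loss (squared by default) outcome-weighted
    classification; the set collects treatments whose derivative-ratio
    estimate of ``mu_j / mu_(1)`` is at most ``c``.
``plugin``
    Per-arm kernel ridge regression of the outcome on the covariates; the
    set thresholds the estimated mean ratios directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .evaluate import (
    EvalReport,
    empirical_value,
    empirical_weighted_outcome,
    tune_delta,
    tune_lambda,
)
from .geometry import angle_margins, simplex_vertices
from .losses import LossSpec
from .recommend import (
    RecommendationSet,
    itr_rule,
    one_step_rule,
    plugin_rule,
    two_step_rule,
)
from .solvers import FitResult, KernelSpec, SolverConfig, fit_admm, fit_dual_cd

logger = logging.getLogger(__name__)

__all__ = ["AITRModel", "AITRResults"]

_DEFAULT_LAMBDA_GRID = 2.0 ** np.arange(-10, 5)
_DEFAULT_DELTA_GRID = np.linspace(-0.3, 0.3, 25)


class AITRModel:
    """Near-optimal treatment recommendation model.

    Parameters
    ----------
    data : Dataset
        Covariates, treatments (1..k), positive outcomes (smaller is
        better) and propensities.
    c : float
        Near-optimality constant (>= 1): treatments whose conditional mean
        is within a factor ``c`` of the best are considered alternatives.
        This is a clinical choice, not a tuning parameter.
    method : {"one_step", "two_step", "plugin"}
    loss : LossSpec, optional
        Defaults: bent hinge (one_step) with slope ``c``; squared
        (two_step).
    kernel : KernelSpec or None
        None for linear learning.
    """

    def __init__(
        self,
        data: Dataset,
        c: float = 1.2,
        method: str = "one_step",
        loss: LossSpec | None = None,
        kernel: KernelSpec | None = None,
        solver_config: SolverConfig | None = None,
    ):
        if method not in ("one_step", "two_step", "plugin"):
            raise ValueError(f"unknown method {method!r}")
        if c < 1:
            raise ValueError("c must be >= 1")
        self.data = data
        self.c = float(c)
        self.method = method
        if loss is None:
            loss = (
                LossSpec("bent_hinge", c=self.c)
                if method == "one_step"
                else LossSpec("squared")
            )
        self.loss = loss
        self.kernel = kernel
        self.config = solver_config or SolverConfig()
        self.geometry = simplex_vertices(data.k)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str = "outcome",
        treatment: str = "treatment",
        covariates: list[str] | None = None,
        propensity: str | None = "propensity",
        randomized: bool = False,
        **kwargs,
    ) -> "AITRModel":
        from .data import estimate_propensity

        if covariates is None:
            special = {outcome, treatment, propensity}
            covariates = [col for col in df.columns if col not in special]
        A = df[treatment].to_numpy(dtype=int)
        X = df[covariates].to_numpy(dtype=float)
        if propensity is not None and propensity in df.columns:
            prop = df[propensity].to_numpy(dtype=float)
        elif randomized:
            prop = np.full(len(df), 1.0 / int(A.max()))
        else:
            prop = estimate_propensity(X, A)
        data = Dataset(X=X, A=A, y=df[outcome].to_numpy(dtype=float),
                       propensity=prop)
        return cls(data, **kwargs)

    # -- fitting ---------------------------------------------------------

    def _fit_decision_function(self, data: Dataset, lam: float) -> FitResult:
        if self.loss.family in ("hinge", "bent_hinge"):
            return fit_dual_cd(data, self.geometry, self.loss, lam,
                               self.config, self.kernel)
        return fit_admm(data, self.geometry, self.loss, lam,
                        self.config, self.kernel)

    def _fit_plugin(self, data: Dataset, lam: float):
        from sklearn.kernel_ridge import KernelRidge

        models = []
        for arm in range(1, data.k + 1):
            mask = data.A == arm
            Xa, ya = data.X[mask], data.y[mask]
            if self.kernel is None:
                kr = KernelRidge(alpha=lam * max(mask.sum(), 1), kernel="linear")
            else:
                spec = self.kernel.resolve(data.X)
                if spec.kind == "gaussian":
                    kr = KernelRidge(alpha=lam * max(mask.sum(), 1),
                                     kernel="rbf", gamma=0.5 / spec.bandwidth ** 2)
                else:
                    kr = KernelRidge(alpha=lam * max(mask.sum(), 1),
                                     kernel="polynomial", degree=spec.degree,
                                     gamma=1.0 / data.p, coef0=spec.offset)
            kr.fit(Xa, ya)
            models.append(kr)
        return models

    def fit(self, lam: float = 1.0, delta: float = 0.0) -> "AITRResults":
        """Fit at fixed hyperparameters."""
        if self.method == "plugin":
            models = self._fit_plugin(self.data, lam)
            return AITRResults(self, None, lam=lam, delta=delta,
                               plugin_models=models)
        fit = self._fit_decision_function(self.data, lam)
        return AITRResults(self, fit, lam=lam, delta=delta)

    def fit_tuned(
        self,
        lambda_grid=None,
        delta_grid=None,
        folds: int = 5,
        seed: int = 0,
    ) -> "AITRResults":
        """Two-stage tuned fit: lambda by CV value, then delta (one-step).

        The plugin method tunes lambda the same way (through the ITR its
        mean estimates induce) and has no delta.
        """
        lambda_grid = (_DEFAULT_LAMBDA_GRID if lambda_grid is None
                       else np.atleast_1d(lambda_grid))
        if self.method == "plugin":
            fit_fn = self._fit_plugin

            def predictor(models, X):
                return np.column_stack([m.predict(X) for m in models])

            # reuse tune_lambda by wrapping the per-arm models
            class _PluginFit:
                def __init__(self, models):
                    self.models = models

                def predict(self, X):  # margins proxy: negated means
                    mu = predictor(self.models, X)
                    # map means to pseudo-margins so argmax picks argmin mu
                    geom = simplex_vertices(mu.shape[1])
                    return -mu @ np.linalg.pinv(geom.vertices).T

            tuning = tune_lambda(
                self.data, lambda a, l: _PluginFit(fit_fn(a, l)),
                lambda_grid, folds=folds, seed=seed,
            )
            models = self._fit_plugin(self.data, tuning.best_lambda)
            return AITRResults(self, None, lam=tuning.best_lambda, delta=0.0,
                               plugin_models=models, lambda_tuning=tuning)
        tuning = tune_lambda(self.data, self._fit_decision_function,
                             lambda_grid, folds=folds, seed=seed)
        delta = 0.0
        delta_cv = None
        if self.method == "one_step":
            delta_grid = (_DEFAULT_DELTA_GRID if delta_grid is None
                          else np.atleast_1d(delta_grid))
            delta, delta_cv = tune_delta(self.data, tuning.fold_fits,
                                         delta_grid, self.c)
        fit = self._fit_decision_function(self.data, tuning.best_lambda)
        return AITRResults(self, fit, lam=tuning.best_lambda, delta=delta,
                           lambda_tuning=tuning, delta_cv=delta_cv)


@dataclass
class AITRResults:
    """Fitted decision function with recommendation and evaluation methods."""

    model: AITRModel
    fit_result: FitResult | None
    lam: float
    delta: float = 0.0
    plugin_models: list | None = None
    lambda_tuning: object | None = None
    delta_cv: dict | None = None

    # -- prediction ------------------------------------------------------

    def decision_function(self, X=None) -> np.ndarray:
        X = self.model.data.X if X is None else np.atleast_2d(X)
        if self.model.method == "plugin":
            raise AttributeError("the plugin method has no decision function")
        return self.fit_result.predict(X)

    def margins(self, X=None) -> np.ndarray:
        return angle_margins(self.model.geometry, self.decision_function(X))

    def estimated_means(self, X=None) -> np.ndarray:
        if self.model.method != "plugin":
            raise AttributeError("only the plugin method estimates means")
        X = self.model.data.X if X is None else np.atleast_2d(X)
        mu = np.column_stack([m.predict(X) for m in self.plugin_models])
        floor = 1e-6
        if (mu <= 0).any():
            logger.warning("nonpositive mean estimates clipped to %.1g", floor)
            mu = np.maximum(mu, floor)
        return mu

    def itr(self, X=None) -> np.ndarray:
        """Single-valued recommendation (1-based treatment per subject)."""
        if self.model.method == "plugin":
            return np.argmin(self.estimated_means(X), axis=1) + 1
        return np.atleast_1d(itr_rule(self.margins(X)))

    def recommend(self, X=None, delta: float | None = None) -> RecommendationSet:
        """Set-valued recommendation under the model's method and ``c``."""
        c = self.model.c
        if self.model.method == "plugin":
            return RecommendationSet(plugin_rule(self.estimated_means(X), c),
                                     "plugin")
        m = self.margins(X)
        if self.model.method == "two_step":
            return RecommendationSet(two_step_rule(m, self.model.loss, c),
                                     "two_step")
        d = self.delta if delta is None else delta
        return RecommendationSet(one_step_rule(m, d), "one_step")

    # -- evaluation ------------------------------------------------------

    def evaluate(self, data: Dataset | None = None) -> EvalReport:
        """In- or out-of-sample IPW value and weighted outcome."""
        data = data or self.model.data
        X = data.X
        d = self.itr(X)
        phi = self.recommend(X)
        card, counts = np.unique(phi.cardinality, return_counts=True)
        return EvalReport(
            value=empirical_value(data, d),
            weighted_outcome=empirical_weighted_outcome(data, phi, self.model.c),
            cardinality_histogram=dict(zip(card.tolist(), counts.tolist())),
        )

    def summary(self) -> str:
        model = self.model
        data = model.data
        lines = [
            "Near-optimal treatment recommendation results",
            "=" * 45,
            f"method:            {model.method}",
            f"loss:              {model.loss.family}",
            f"kernel:            {model.kernel.kind if model.kernel else 'linear'}",
            f"n / p / k:         {data.n} / {data.p} / {data.k}",
            f"near-optimality c: {model.c:g}",
            f"lambda:            {self.lam:g}",
        ]
        if model.method == "one_step":
            lines.append(f"delta:             {self.delta:g}")
        if self.fit_result is not None:
            from .solvers import primal_objective

            obj = primal_objective(
                data, model.geometry, self.fit_result.predict(data.X),
                model.loss, self.lam, self.fit_result.penalty())
            lines.append(f"final objective:   {obj:.6g}")
            lines.append(f"solver iterations: {self.fit_result.n_iter}"
                         + ("" if self.fit_result.converged else " (cap reached)"))
        try:
            report = self.evaluate()
            lines.append(f"IPW value (ITR):   {report.value:.4f}")
            lines.append(f"weighted outcome:  {report.weighted_outcome:.4f}")
            hist = ", ".join(f"|phi|={c}: {n}" for c, n in
                             sorted(report.cardinality_histogram.items()))
            lines.append(f"set sizes:         {hist}")
        except Exception:  # pragma: no cover - e.g. no matching subjects
            pass
        return "\n".join(lines)
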