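"""Dataset container, CSV I/O, propensity estimation, outcome transform.

The per-subject record is (covariates X, treatment A in {1..k}, positive
outcome Y with smaller preferred, propensity p(A|X)).  The learning weight
is the inverse-probability weight ``w_i = y_i / p(a_i | x_i)``; propensities
are floored and outcomes clipped away from zero so the weights stay bounded
and nonnegative, as the weighted-classification duals require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "load_csv",
    "save_csv",
    "estimate_propensity",
    "transform_outcome",
]

DEFAULT_PROPENSITY_FLOOR = 0.01
DEFAULT_OUTCOME_FLOOR = 1e-6


@dataclass
class Dataset:
    """Tabular data for outcome-weighted learning.

    Attributes
    ----------
    X : ndarray (n, p)
        Numeric covariates.
    A : ndarray (n,) of int
        Treatments, labelled 1..k.
    y : ndarray (n,)
        Observed outcomes; positive, smaller preferred.
    propensity : ndarray (n,)
        ``p(a_i | x_i)`` in (0, 1]; floored at ``propensity_floor``.
    k : int
        Number of treatments (max label by default).
    """

    X: np.ndarray
    A: np.ndarray
    y: np.ndarray
    propensity: np.ndarray
    k: int = 0
    propensity_floor: float = DEFAULT_PROPENSITY_FLOOR
    outcome_floor: float = DEFAULT_OUTCOME_FLOOR

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.A = np.asarray(self.A, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.propensity = np.asarray(self.propensity, dtype=float)
        n = self.X.shape[0]
        if not (self.A.shape == (n,) and self.y.shape == (n,) and self.propensity.shape == (n,)):
            raise ValueError("X, A, y and propensity must share the same length")
        for name, arr in (("X", self.X), ("y", self.y), ("propensity", self.propensity)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if n and self.A.min() < 1:
            raise ValueError("treatment labels must be integers starting at 1")
        if self.k == 0:
            self.k = int(self.A.max()) if n else 2
        if n and len(np.unique(self.A)) < self.k:
            logger.warning("not all treatment labels 1..%d are present", self.k)
        low = self.propensity < self.propensity_floor
        if low.any():
            logger.warning(
                "%d propensities below the floor %.3g were truncated",
                int(low.sum()), self.propensity_floor,
            )
            self.propensity = np.maximum(self.propensity, self.propensity_floor)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def weights(self) -> np.ndarray:
        """IPW learning weights ``max(y, floor) / propensity`` (bounded, >= 0)."""
        clipped = np.maximum(self.y, self.outcome_floor)
        nclip = int((self.y < self.outcome_floor).sum())
        if nclip:
            logger.warning("%d outcomes clipped up to %.1g for the solver weights",
                           nclip, self.outcome_floor)
        w = clipped / self.propensity
        if w.size:
            logger.debug("max IPW weight %.4g", float(w.max()))
        return w

    def subset(self, idx) -> "Dataset":
        return Dataset(
            X=self.X[idx], A=self.A[idx], y=self.y[idx],
            propensity=self.propensity[idx], k=self.k,
            propensity_floor=self.propensity_floor,
            outcome_floor=self.outcome_floor,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{j + 1}": self.X[:, j] for j in range(self.p)}
        cols["treatment"] = self.A
        cols["outcome"] = self.y
        cols["propensity"] = self.propensity
        return pd.DataFrame(cols)


def load_csv(
    path,
    column_map: dict | None = None,
    randomized: bool = False,
    propensity_floor: float = DEFAULT_PROPENSITY_FLOOR,
) -> Dataset:
    """Load a Dataset from CSV.

    ``column_map`` may rename the special columns, e.g.
    ``{"treatment": "arm", "outcome": "y", "propensity": "ps"}``; all other
    numeric columns are taken as covariates (in file order).  A missing
    propensity column is filled with 1/k when ``randomized`` is true, and
    estimated by multinomial logistic regression otherwise.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cmap = {"treatment": "treatment", "outcome": "outcome", "propensity": "propensity"}
    if column_map:
        cmap.update(column_map)
    for role in ("treatment", "outcome"):
        if cmap[role] not in df.columns:
            raise ValueError(f"missing required column {cmap[role]!r} for {role}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}")
    a_raw = df[cmap["treatment"]]
    A = a_raw.to_numpy()
    if not np.issubdtype(A.dtype, np.integer):
        if not np.allclose(A, np.round(A)):
            raise ValueError(f"treatment column {cmap['treatment']!r} is not integer")
        A = np.round(A).astype(int)
    if A.min() < 1:
        row = int(np.argmin(A))
        raise ValueError(
            f"treatment labels must be 1..k; found {A.min()} at row {row}"
        )
    k = int(A.max())
    special = {cmap["treatment"], cmap["outcome"], cmap["propensity"]}
    xcols = [c for c in df.columns if c not in special]
    try:
        X = df[xcols].to_numpy(dtype=float)
    except ValueError as e:
        raise ValueError(f"non-numeric covariate data: {e}") from e
    y = df[cmap["outcome"]].to_numpy(dtype=float)
    if cmap["propensity"] in df.columns:
        prop = df[cmap["propensity"]].to_numpy(dtype=float)
    elif randomized:
        prop = np.full(len(df), 1.0 / k)
    else:
        logger.info("no propensity column; fitting multinomial logistic regression")
        prop = estimate_propensity(X, A, floor=propensity_floor)
    return Dataset(X=X, A=A, y=y, propensity=prop, k=k,
                   propensity_floor=propensity_floor)


def save_csv(data: Dataset, path) -> None:
    data.to_frame().to_csv(path, index=False)


def estimate_propensity(X, A, floor: float = DEFAULT_PROPENSITY_FLOOR) -> np.ndarray:
    """Fitted ``p(a_i | x_i)`` by (multinomial) logistic regression.

    Probabilities across arms sum to one before the floor is applied.  If
    the fit fails (e.g. separation), falls back to the marginal arm
    frequencies with a warning.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.asarray(A, dtype=int)
    try:
        model = LogisticRegression(max_iter=2000)
        model.fit(X, A)
        proba = model.predict_proba(X)
        own = proba[np.arange(len(A)), np.searchsorted(model.classes_, A)]
    except Exception as e:  # pragma: no cover - defensive
        logger.warning("propensity model failed (%s); using arm frequencies", e)
        freqs = pd.Series(A).value_counts(normalize=True)
        own = freqs.reindex(A).to_numpy()
    return np.maximum(own, floor)


def transform_outcome(y_raw, X, tau: float = 5.0) -> np.ndarray:
    """Map an arbitrary real outcome to a positive one.

    Centres ``y_raw`` by an ordinary-least-squares fit ``m(x)`` on the
    covariates (plus intercept) and exponentiates the residual on scale
    ``tau``: ``y = exp((y_raw - m(x)) / tau)``.  With this transform, a
    multiplicative near-optimality factor ``c`` on the new scale corresponds
    to an additive band ``tau * log(c)`` on the original scale.
    """
    import statsmodels.api as sm

    if tau <= 0:
        raise ValueError("tau must be positive")
    y_raw = np.asarray(y_raw, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    design = sm.add_constant(X, has_constant="add")
    mhat = sm.OLS(y_raw, design).fit().fittedvalues
    return np.exp((y_raw - mhat) / tau)
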