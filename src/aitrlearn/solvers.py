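"""Regularized outcome-weighted minimization in linear and kernel classes.

The objective is

    (1/n) sum_i w_i * loss(<W_{a_i}, f(x_i)>) + lambda * J(f),

with IPW weights ``w_i = y_i / p(a_i|x_i)``.  ``f`` is either linear,
``f_j(x) = x^T beta_j`` with a prepended constant and ridge penalty
``J = sum_j ||beta_j||^2``, or a kernel expansion
``f_j(x) = sum_i K(x_i, x) alpha_ij + alpha_0j`` with
``J = sum_j alpha_j^T K alpha_j + alpha_0j^2`` (the intercept is penalized,
which keeps the duals box-constrained with no equality constraint).

Two solvers:

* :func:`fit_dual_cd` — exact coordinate ascent on the box-constrained dual
  of the (bent) hinge problem; each coordinate has a closed-form clipped
  Newton step.
* :func:`fit_admm` — ADMM splitting for bent losses with a differentiable
  smooth part; at ``c = 1`` the bent block vanishes and the problem is
  solved by plain quasi-Newton minimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .data import Dataset
from .geometry import SimplexGeometry
from .losses import LossSpec, loss_value

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "SolverConfig",
    "FitResult",
    "gram_matrix",
    "primal_objective",
    "fit_dual_cd",
    "fit_admm",
    "predict_f",
]

_JITTER = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice and hyperparameters.

    gaussian: ``exp(-||x - x'||^2 / (2 sigma^2))``; ``bandwidth`` (sigma)
    defaults to the median pairwise distance of the training covariates.
    polynomial: ``(offset + <x, x'> / p)^degree`` with degree 2, offset 1
    by default (the inner product is scaled by the dimension so the kernel
    stays O(1) as p grows).
    """

    kind: str
    bandwidth: float | None = None
    degree: int = 2
    offset: float = 1.0

    def __post_init__(self):
        if self.kind not in ("gaussian", "polynomial"):
            raise ValueError(f"unknown kernel {self.kind!r}")

    def resolve(self, X: np.ndarray) -> "KernelSpec":
        """Fill the data-dependent default bandwidth from training X."""
        if self.kind == "gaussian" and self.bandwidth is None:
            from scipy.spatial.distance import pdist

            d = pdist(X)
            bw = float(np.median(d[d > 0])) if (d > 0).any() else 1.0
            return KernelSpec(kind=self.kind, bandwidth=bw,
                              degree=self.degree, offset=self.offset)
        return self


@dataclass(frozen=True)
class SolverConfig:
    rho: float = 1.0            # ADMM step size
    tol: float = 1e-5           # ADMM primal/change tolerance
    max_iter: int = 1000        # ADMM iterations
    cd_tol: float = 1e-6        # dual CD: max coordinate change per epoch
    cd_max_epochs: int = 2000
    inner_gtol: float = 1e-8    # gradient norm for smooth subproblems
    seed: int = 0

    def __post_init__(self):
        if self.rho <= 0 or self.tol <= 0:
            raise ValueError("rho and tol must be positive")


@dataclass
class FitResult:
    """A fitted decision function plus its provenance.

    ``B`` holds linear coefficients ((p+1) x (k-1), intercept row first);
    in kernel mode ``alphas`` (n x (k-1)) and ``intercepts`` (k-1,) hold the
    representer coefficients and ``training_X`` the retained covariates.
    ``objective_trace`` is non-increasing: the per-iteration objective for
    ADMM / quasi-Newton, and the negated dual objective for coordinate
    ascent (which converges to the primal optimum by strong duality).
    """

    mode: str
    loss: LossSpec
    lam: float
    k: int
    B: np.ndarray | None = None
    alphas: np.ndarray | None = None
    intercepts: np.ndarray | None = None
    kernel_spec: KernelSpec | None = None
    training_X: np.ndarray | None = None
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    n_iter: int = 0

    def penalty(self) -> float:
        """J(f) for this fit (intercepts included)."""
        if self.mode == "linear":
            return float((self.B ** 2).sum())
        K = gram_matrix(self.training_X, self.training_X, self.kernel_spec)
        return float(np.einsum("ij,ik,kj->", self.alphas, K, self.alphas)
                     + (self.intercepts ** 2).sum())

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        return predict_f(self, Xnew)


def gram_matrix(X: np.ndarray, X2: np.ndarray, kernel_spec: KernelSpec) -> np.ndarray:
    """Kernel gram matrix between the rows of X (n x p) and X2 (m x p)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X.shape[1] != X2.shape[1]:
        raise ValueError("covariate dimensions do not match")
    if kernel_spec.kind == "gaussian":
        bw = kernel_spec.bandwidth
        if bw is None:
            raise ValueError("gaussian bandwidth unresolved; call spec.resolve(X)")
        sq = (
            (X ** 2).sum(1)[:, None]
            - 2.0 * X @ X2.T
            + (X2 ** 2).sum(1)[None, :]
        )
        return np.exp(-np.maximum(sq, 0.0) / (2.0 * bw ** 2))
    # polynomial
    p = X.shape[1]
    return (kernel_spec.offset + X @ X2.T / p) ** kernel_spec.degree


def primal_objective(
    data: Dataset,
    geom: SimplexGeometry,
    f_at_X: np.ndarray,
    loss: LossSpec,
    lam: float,
    penalty: float,
) -> float:
    """Evaluate the regularized outcome-weighted objective."""
    f_at_X = np.asarray(f_at_X, dtype=float)
    if not np.all(np.isfinite(f_at_X)):
        raise ValueError("non-finite decision values")
    margins = np.einsum("ij,ij->i", geom.vertices[data.A - 1], f_at_X)
    obj = float(np.mean(data.weights * loss_value(loss, margins)) + lam * penalty)
    if not np.isfinite(obj):
        raise ValueError("non-finite objective")
    return obj


@njit(cache=True)
def _cd_sweeps(H, w, lam, slope, alpha, gamma, u, max_epochs, tol, seed):
    """Exact coordinate ascent on the box-constrained dual.

    Sweeps visit the coordinates in a freshly shuffled order each epoch
    (cyclic sweeps can zig-zag for thousands of epochs at small lambda).
    Maintains ``u_i = <W_{a_i}, f(x_i)>`` for the primal iterate recovered
    from the dual variables, and the (negated) dual objective per epoch.
    """
    n = H.shape[0]
    t = 1.0 / (2.0 * lam * n)
    trace = np.empty(max_epochs)
    n_ep = 0
    np.random.seed(seed)
    order = np.arange(n)
    for ep in range(max_epochs):
        maxd = 0.0
        if ep > 0:
            order = np.random.permutation(n)
        for i in order:
            hii = H[i, i]
            if hii <= 0.0 or w[i] <= 0.0:
                continue
            # alpha block: dD/dalpha_i = (1 + u_i)/n, curvature -t*hii/n
            new = alpha[i] + (1.0 + u[i]) / (t * hii)
            if new < 0.0:
                new = 0.0
            elif new > w[i]:
                new = w[i]
            d = new - alpha[i]
            if d != 0.0:
                alpha[i] = new
                for m in range(n):
                    u[m] -= t * d * H[i, m]
                if abs(d) > maxd:
                    maxd = abs(d)
            if slope > 0.0:
                # gamma block: dD/dgamma_i = slope*u_i/n
                new = gamma[i] + u[i] / (slope * t * hii)
                if new < 0.0:
                    new = 0.0
                elif new > w[i]:
                    new = w[i]
                d = new - gamma[i]
                if d != 0.0:
                    gamma[i] = new
                    dd = slope * d
                    for m in range(n):
                        u[m] -= t * dd * H[i, m]
                    if abs(d) > maxd:
                        maxd = abs(d)
        asum = 0.0
        su = 0.0
        ploss = 0.0
        for i in range(n):
            asum += alpha[i]
            su += (alpha[i] + slope * gamma[i]) * u[i]
            li = 1.0 + u[i]
            if li < 0.0:
                li = 0.0
            if slope > 0.0 and u[i] > 0.0:
                li += slope * u[i]
            ploss += w[i] * li
        dual = asum / n + su / (2.0 * n)
        primal = ploss / n - su / (2.0 * n)
        trace[ep] = -dual
        n_ep = ep + 1
        gap = primal - dual
        if maxd < tol or gap <= 1e-9 * max(1.0, abs(dual)):
            break
    return n_ep, trace


@njit(cache=True)
def _prox_cd(H, mC, cbox, gamma, rho, max_epochs, tol):
    """Exact dual coordinate ascent for the positive-part prox subproblem.

    Solves ``min_G sum_i c_i (m_i(G))_+ + rho/2 ||G - C||^2`` through its
    box dual (``0 <= gamma_i <= c_i``); ``mC`` holds ``m_i(C)`` and the
    margins of the current iterate are ``mC - (1/rho) H gamma``.
    """
    n = H.shape[0]
    m = mC.copy()
    for i in range(n):
        if gamma[i] != 0.0:
            for j in range(n):
                m[j] -= H[i, j] * gamma[i] / rho
    for _ in range(max_epochs):
        maxd = 0.0
        for i in range(n):
            hii = H[i, i]
            if hii <= 0.0 or cbox[i] <= 0.0:
                continue
            new = gamma[i] + rho * m[i] / hii
            if new < 0.0:
                new = 0.0
            elif new > cbox[i]:
                new = cbox[i]
            d = new - gamma[i]
            if d != 0.0:
                gamma[i] = new
                for j in range(n):
                    m[j] -= H[i, j] * d / rho
                if abs(d) > maxd:
                    maxd = abs(d)
        if maxd < tol:
            break
    return gamma, m


def _design(data: Dataset, kernel_spec: KernelSpec | None):
    """Return (Q, resolved_spec): inner-product matrix incl. intercept feature."""
    if kernel_spec is None:
        Xt = np.hstack([np.ones((data.n, 1)), data.X])
        return Xt @ Xt.T, None
    spec = kernel_spec.resolve(data.X)
    K = gram_matrix(data.X, data.X, spec)
    return K + 1.0, spec


def fit_dual_cd(
    data: Dataset,
    geom: SimplexGeometry,
    loss: LossSpec,
    lam: float,
    config: SolverConfig | None = None,
    kernel_spec: KernelSpec | None = None,
) -> FitResult:
    """Solve the (bent-)hinge problem by dual coordinate descent.

    The dual has one box ``0 <= alpha_i <= w_i`` per observation (hinge
    part) and, for the bent hinge, a second box ``0 <= gamma_i <= w_i``.
    Each sweep applies the closed-form clipped Newton step per coordinate;
    observations with zero weight have degenerate boxes and stay inactive.
    The primal solution is recovered as
    ``beta_j = -(1/(2 n lambda)) sum_i (alpha_i + (c-1) gamma_i) W_{a_i,j} x_i``
    (in kernel mode, with the gram row standing in for ``x_i`` plus an
    intercept feature, per the representer form).
    """
    if loss.family not in ("hinge", "bent_hinge"):
        raise ValueError("dual CD handles hinge and bent_hinge losses only")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    config = config or SolverConfig()
    slope = loss.bent_slope
    w = data.weights
    V = geom.vertices[data.A - 1]  # (n, k-1)
    Q, spec = _design(data, kernel_spec)
    H = (V @ V.T) * Q
    alpha = np.zeros(data.n)
    gamma = np.zeros(data.n)
    u = np.zeros(data.n)
    # small instances get extra sweeps on the same flop budget: ill-
    # conditioned duals (tiny lambda) can need thousands of epochs, each
    # costing only O(n^2)
    max_epochs = max(config.cd_max_epochs,
                     min(500_000, int(2e8 / max(data.n ** 2, 1))))
    n_ep, trace = _cd_sweeps(
        H, w, float(lam), float(slope), alpha, gamma, u,
        max_epochs, config.cd_tol, config.seed,
    )
    converged = n_ep < max_epochs or max_epochs == 0
    if not converged:
        logger.warning(
            "dual CD hit %d epochs without converging (last dual obj %.6g)",
            n_ep, -trace[n_ep - 1],
        )
    s = alpha + slope * gamma
    t = 1.0 / (2.0 * lam * data.n)
    coeff = -t * V * s[:, None]  # (n, k-1)
    if kernel_spec is None:
        Xt = np.hstack([np.ones((data.n, 1)), data.X])
        B = Xt.T @ coeff
        return FitResult(mode="linear", loss=loss, lam=lam, k=geom.k, B=B,
                         objective_trace=trace[:n_ep], converged=converged,
                         n_iter=n_ep)
    return FitResult(
        mode="kernel", loss=loss, lam=lam, k=geom.k,
        alphas=coeff, intercepts=coeff.sum(axis=0),
        kernel_spec=spec, training_X=data.X.copy(),
        objective_trace=trace[:n_ep], converged=converged, n_iter=n_ep,
    )


def _smooth_value_grad(family: str, u: np.ndarray):
    if family in ("squared", "bent_squared"):
        return (1.0 + u) ** 2, 2.0 * (1.0 + u)
    if family in ("exponential", "bent_exponential"):
        e = np.exp(u)
        return e, e
    raise ValueError(f"loss family {family!r} has no differentiable smooth part")


def fit_admm(
    data: Dataset,
    geom: SimplexGeometry,
    loss: LossSpec,
    lam: float,
    config: SolverConfig | None = None,
    kernel_spec: KernelSpec | None = None,
) -> FitResult:
    """Minimize the objective for losses with a differentiable smooth part.

    For the plain families (no bent slope) the coefficient copies are tied
    (``B = G``) and the whole problem is smooth, solved directly by L-BFGS.
    For bent families, ADMM alternates the smooth block B, the bent block G
    (holding the ``(c-1) u_+`` term), and the scaled multipliers Z, with
    fixed step ``rho``.  Kernel mode runs the same updates on a Cholesky
    feature map of the gram matrix, which reproduces the RKHS penalty
    exactly, then converts back to representer coefficients.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    config = config or SolverConfig()
    slope = loss.bent_slope
    w = data.weights
    V = geom.vertices[data.A - 1]
    if kernel_spec is None:
        Phi = np.hstack([np.ones((data.n, 1)), data.X])
        spec = None
        R = None
    else:
        spec = kernel_spec.resolve(data.X)
        K = gram_matrix(data.X, data.X, spec)
        R = np.linalg.cholesky(K + _JITTER * np.eye(data.n))
        Phi = np.hstack([np.ones((data.n, 1)), R])
    n, d = Phi.shape
    km1 = geom.k - 1
    shape = (d, km1)

    def margins(M):
        return np.einsum("id,dl,il->i", Phi, M, V)

    def smooth_obj_grad(bflat):
        B = bflat.reshape(shape)
        u = margins(B)
        val, dval = _smooth_value_grad(loss.family, u)
        obj = np.mean(w * val) + lam * (B ** 2).sum()
        gu = w * dval / n
        grad = Phi.T @ (gu[:, None] * V) + 2.0 * lam * B
        return obj, grad.ravel()

    trace = []
    if slope == 0.0:
        res = minimize(
            smooth_obj_grad, np.zeros(d * km1), jac=True, method="L-BFGS-B",
            callback=lambda xk: trace.append(smooth_obj_grad(xk)[0]),
            options=dict(maxiter=config.max_iter, gtol=config.inner_gtol,
                         ftol=1e-14),
        )
        B = res.x.reshape(shape)
        converged = bool(res.success)
        n_iter = int(res.nit)
    else:
        rho = config.rho
        B = np.zeros(shape)
        G = np.zeros(shape)
        Z = np.zeros(shape)
        H = (V @ V.T) * (Phi @ Phi.T)
        cbox = slope * w / n
        gamma = np.zeros(n)

        def b_obj_grad(bflat):
            Bm = bflat.reshape(shape)
            u = margins(Bm)
            val, dval = _smooth_value_grad(loss.family, u)
            diff = Bm - G
            obj = (np.mean(w * val) + lam * (Bm ** 2).sum()
                   + (Z * diff).sum() + 0.5 * rho * (diff ** 2).sum())
            gu = w * dval / n
            grad = (Phi.T @ (gu[:, None] * V) + 2.0 * lam * Bm + Z + rho * diff)
            return obj, grad.ravel()

        converged = False
        n_iter = 0
        for it in range(config.max_iter):
            B_prev = B.copy()
            B = minimize(b_obj_grad, B.ravel(), jac=True, method="L-BFGS-B",
                         options=dict(gtol=config.inner_gtol, ftol=1e-14),
                         ).x.reshape(shape)
            # G-step: prox of the bent block at C = B + Z/rho, solved
            # exactly through its box-constrained dual
            C = B + Z / rho
            mC = margins(C)
            gamma, _ = _prox_cd(H, mC, cbox, gamma, rho, 500, 1e-12)
            G = C - (Phi.T @ (gamma[:, None] * V)) / rho
            Z = Z + rho * (B - G)
            u = margins(B)
            trace.append(float(np.mean(w * loss_value(loss, u))
                               + lam * (B ** 2).sum()))
            n_iter = it + 1
            r_primal = np.linalg.norm(B - G)
            r_change = np.linalg.norm(B - B_prev)
            if r_primal < config.tol and r_change < config.tol:
                converged = True
                break
        if not converged:
            logger.warning(
                "ADMM hit %d iterations (||B-G||=%.3g, ||dB||=%.3g)",
                n_iter, float(np.linalg.norm(B - G)),
                float(np.linalg.norm(B - B_prev)),
            )

    trace = np.asarray(trace, dtype=float)
    if kernel_spec is None:
        return FitResult(mode="linear", loss=loss, lam=lam, k=geom.k, B=B,
                         objective_trace=trace, converged=converged,
                         n_iter=n_iter)
    # convert feature-space coefficients back to representer form:
    # f_j = R b_j + b0_j = K c_j + b0_j  with  c_j = R^{-T} b_j
    from scipy.linalg import solve_triangular

    b0 = B[0]
    alphas = solve_triangular(R.T, B[1:], lower=False)
    return FitResult(
        mode="kernel", loss=loss, lam=lam, k=geom.k,
        alphas=alphas, intercepts=b0, kernel_spec=spec,
        training_X=data.X.copy(), objective_trace=trace,
        converged=converged, n_iter=n_iter,
    )


def predict_f(model: FitResult, Xnew: np.ndarray) -> np.ndarray:
    """Decision-function values (n_new, k-1) at new covariates."""
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if model.mode == "linear":
        if Xnew.shape[1] != model.B.shape[0] - 1:
            raise ValueError(
                f"expected {model.B.shape[0] - 1} covariates, got {Xnew.shape[1]}"
            )
        return np.hstack([np.ones((Xnew.shape[0], 1)), Xnew]) @ model.B
    if Xnew.shape[1] != model.training_X.shape[1]:
        raise ValueError(
            f"expected {model.training_X.shape[1]} covariates, got {Xnew.shape[1]}"
        )
    G = gram_matrix(Xnew, model.training_X, model.kernel_spec)
    return G @ model.alphas + model.intercepts
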