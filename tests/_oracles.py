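"""Independent oracles for cross-checking the solvers.

These deliberately take different routes than the package solvers:
generic SLSQP on a slack (QP-style) reformulation, an exact linear-algebra
solve for the squared loss, a linear program for the pointwise bent-hinge
population problem, and BFGS for the exponential one.
"""

import numpy as np
from scipy.linalg import cholesky
from scipy.optimize import linprog, minimize

from aitrlearn.geometry import SimplexGeometry
from aitrlearn.losses import LossSpec
from aitrlearn.solvers import KernelSpec, gram_matrix, primal_objective

_JITTER = 1e-8


def _features(data, kernel_spec):
    if kernel_spec is None:
        return np.hstack([np.ones((data.n, 1)), data.X])
    spec = kernel_spec.resolve(data.X)
    K = gram_matrix(data.X, data.X, spec)
    R = cholesky(K + _JITTER * np.eye(data.n), lower=True)
    return np.hstack([np.ones((data.n, 1)), R])


def oracle_objective(data, geom: SimplexGeometry, loss: LossSpec, lam: float,
                     kernel_spec: KernelSpec | None = None) -> float:
    """Optimal value of the regularized outcome-weighted objective."""
    Phi = _features(data, kernel_spec)
    V = geom.vertices[data.A - 1]
    w = data.weights
    n, d = Phi.shape
    km1 = geom.k - 1
    nb = d * km1
    slope = loss.bent_slope
    nonsmooth = loss.family in ("hinge", "bent_hinge")

    if loss.family == "squared":
        # exact ridge solve: (1/n)(1 + M b)' W (1 + M b) + lam b'b
        M = np.einsum("id,il->idl", Phi, V).reshape(n, nb)
        A = M.T @ (w[:, None] * M) / n + lam * np.eye(nb)
        b = np.linalg.solve(A, -M.T @ w / n)
        B = b.reshape(d, km1)
        return primal_objective(data, geom, Phi @ B, loss, lam,
                                float((B ** 2).sum()))

    n_xi = n if nonsmooth else 0
    n_eta = n if slope > 0 else 0
    nz = nb + n_xi + n_eta

    def unpack(z):
        return z[:nb].reshape(d, km1), z[nb:nb + n_xi], z[nb + n_xi:]

    def margins(B):
        return np.einsum("id,dl,il->i", Phi, B, V)

    def fun(z):
        B, xi, eta = unpack(z)
        u = margins(B)
        obj = lam * (B ** 2).sum()
        if nonsmooth:
            obj += float(w @ xi) / n
        elif loss.family in ("bent_squared",):
            obj += float(np.mean(w * (1.0 + u) ** 2))
        elif loss.family in ("exponential", "bent_exponential"):
            obj += float(np.mean(w * np.exp(u)))
        if slope > 0:
            obj += slope * float(w @ eta) / n
        return obj

    cons = []
    if nonsmooth:
        def c_xi(z):
            B, xi, _ = unpack(z)
            return xi - (1.0 + margins(B))
        cons.append({"type": "ineq", "fun": c_xi})
    if slope > 0:
        def c_eta(z):
            B, _, eta = unpack(z)
            return eta - margins(B)
        cons.append({"type": "ineq", "fun": c_eta})
    bounds = [(None, None)] * nb + [(0, None)] * (n_xi + n_eta)
    res = minimize(fun, np.zeros(nz), method="SLSQP", bounds=bounds,
                   constraints=cons,
                   options=dict(maxiter=2000, ftol=1e-12))
    B = unpack(res.x)[0]
    return primal_objective(data, geom, Phi @ B, loss, lam,
                            float((B ** 2).sum()))


def pointwise_bent_hinge_margins(mu, geom: SimplexGeometry, c: float):
    """Margins of argmin_f sum_j mu_j * bent_hinge(<W_j, f>) via an LP."""
    mu = np.asarray(mu, dtype=float)
    k = geom.k
    km1 = k - 1
    W = geom.vertices
    # variables: f (km1, free), xi (k), eta (k)
    n_var = km1 + 2 * k
    cost = np.concatenate([np.zeros(km1), mu, (c - 1.0) * mu])
    # xi_j >= 1 + <W_j, f>  ->  <W_j, f> - xi_j <= -1
    A1 = np.hstack([W, -np.eye(k), np.zeros((k, k))])
    b1 = -np.ones(k)
    # eta_j >= <W_j, f>  ->  <W_j, f> - eta_j <= 0
    A2 = np.hstack([W, np.zeros((k, k)), -np.eye(k)])
    b2 = np.zeros(k)
    bounds = [(None, None)] * km1 + [(0, None)] * (2 * k)
    res = linprog(cost, A_ub=np.vstack([A1, A2]), b_ub=np.concatenate([b1, b2]),
                  bounds=bounds, method="highs")
    assert res.success
    return W @ res.x[:km1]


def pointwise_exponential_margins(mu, geom: SimplexGeometry):
    """Margins of argmin_f sum_j mu_j * exp(<W_j, f>) via BFGS."""
    mu = np.asarray(mu, dtype=float)
    W = geom.vertices

    def fg(f):
        u = W @ f
        e = mu * np.exp(u)
        return e.sum(), W.T @ e

    res = minimize(fg, np.zeros(geom.k - 1), jac=True, method="BFGS",
                   options=dict(gtol=1e-12, maxiter=1000))
    return W @ res.x
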