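import numpy as np
import pytest

from aitrlearn.data import Dataset
from aitrlearn.geometry import angle_margins, simplex_vertices
from aitrlearn.losses import LossSpec, ratio_estimate
from aitrlearn.solvers import (
    FitResult,
    KernelSpec,
    SolverConfig,
    fit_admm,
    fit_dual_cd,
    gram_matrix,
    predict_f,
    primal_objective,
)

from _oracles import (
    oracle_objective,
    pointwise_bent_hinge_margins,
    pointwise_exponential_margins,
)
from conftest import random_dataset


def _fit_objective(data, geom, fit):
    return primal_objective(data, geom, fit.predict(data.X), fit.loss,
                            fit.lam, fit.penalty())


class TestGram:
    def test_gaussian_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        K = gram_matrix(X, X, KernelSpec("gaussian", bandwidth=1.3))
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_polynomial_at_origin(self):
        z = np.zeros((1, 4))
        K = gram_matrix(z, z, KernelSpec("polynomial", degree=2, offset=1.0))
        assert K[0, 0] == 1.0

    @pytest.mark.parametrize("spec", [KernelSpec("gaussian", bandwidth=0.8),
                                      KernelSpec("polynomial", degree=3)])
    def test_psd(self, spec):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(30, 4))
        K = gram_matrix(X, X, spec)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("sigmoid")


class TestPrimalObjective:
    def test_zero_function_hinge(self):
        rng = np.random.default_rng(2)
        data = random_dataset(rng, 15, 3)
        geom = simplex_vertices(3)
        obj = primal_objective(data, geom, np.zeros((15, 2)),
                               LossSpec("hinge"), 1.0, 0.0)
        assert obj == pytest.approx(data.weights.mean())

    def test_single_subject_zero_loss(self):
        geom = simplex_vertices(2)
        data = Dataset(X=[[1.0]], A=[1], y=[2.0], propensity=[0.5], k=2)
        # margin -1: f = -W_1 -> loss (1-1)_+ = 0
        f = -geom.vertices[[0]]
        assert primal_objective(data, geom, f, LossSpec("hinge"), 1.0, 0.0) == 0.0

    def test_nonfinite_rejected(self):
        geom = simplex_vertices(2)
        data = Dataset(X=[[1.0]], A=[1], y=[2.0], propensity=[0.5], k=2)
        with pytest.raises(ValueError):
            primal_objective(data, geom, np.array([[np.inf]]),
                             LossSpec("hinge"), 1.0, 0.0)


# a spread of small instances: modes x losses x k
_CD_CASES = [
    (0, 2, "hinge", None, 1.0),
    (1, 3, "hinge", None, 0.5),
    (2, 3, "bent_hinge", None, 0.2),
    (3, 4, "bent_hinge", None, 1.0),
    (4, 3, "hinge", KernelSpec("gaussian"), 0.5),
    (5, 3, "bent_hinge", KernelSpec("polynomial"), 0.3),
    (6, 2, "bent_hinge", KernelSpec("gaussian"), 1.0),
]


@pytest.mark.parametrize("seed,k,family,kernel,lam", _CD_CASES)
def test_dual_cd_matches_convex_oracle(seed, k, family, kernel, lam):
    """Recovered primal objective agrees with a generic convex solve."""
    rng = np.random.default_rng(100 + seed)
    data = random_dataset(rng, 30, k)
    geom = simplex_vertices(k)
    loss = LossSpec(family, c=1.3 if family == "bent_hinge" else 1.0)
    fit = fit_dual_cd(data, geom, loss, lam, kernel_spec=kernel)
    obj = _fit_objective(data, geom, fit)
    ref = oracle_objective(data, geom, loss, lam, kernel_spec=kernel)
    assert obj == pytest.approx(ref, rel=1e-4, abs=1e-8)


def test_dual_cd_zero_outcomes_give_zero_fit():
    geom = simplex_vertices(3)
    data = Dataset(X=np.eye(3), A=[1, 2, 3], y=[0.0, 0.0, 0.0],
                   propensity=[1 / 3] * 3, k=3)
    data.outcome_floor = 0.0  # keep the weights exactly zero
    fit = fit_dual_cd(data, geom, LossSpec("hinge"), 1.0)
    np.testing.assert_array_equal(fit.B, 0.0)


def test_bent_hinge_c1_reproduces_hinge():
    rng = np.random.default_rng(5)
    data = random_dataset(rng, 25, 3)
    geom = simplex_vertices(3)
    f1 = fit_dual_cd(data, geom, LossSpec("hinge"), 0.5)
    f2 = fit_dual_cd(data, geom, LossSpec("bent_hinge", c=1.0), 0.5)
    np.testing.assert_allclose(f1.B, f2.B, atol=1e-8)


def test_dual_cd_rejects_bad_lambda_and_loss():
    rng = np.random.default_rng(6)
    data = random_dataset(rng, 10, 2)
    geom = simplex_vertices(2)
    with pytest.raises(ValueError):
        fit_dual_cd(data, geom, LossSpec("hinge"), 0.0)
    with pytest.raises(ValueError):
        fit_dual_cd(data, geom, LossSpec("squared"), 1.0)


class TestADMM:
    def test_squared_c1_matches_ridge_closed_form(self):
        rng = np.random.default_rng(7)
        data = random_dataset(rng, 30, 3)
        geom = simplex_vertices(3)
        loss = LossSpec("squared")
        fit = fit_admm(data, geom, loss, 0.5)
        obj = _fit_objective(data, geom, fit)
        ref = oracle_objective(data, geom, loss, 0.5)
        assert obj == pytest.approx(ref, rel=1e-4)

    @pytest.mark.parametrize("kernel", [None, KernelSpec("gaussian")])
    def test_bent_exponential_matches_oracle(self, kernel):
        rng = np.random.default_rng(8)
        data = random_dataset(rng, 20, 3)
        geom = simplex_vertices(3)
        loss = LossSpec("bent_exponential", c=1.2)
        fit = fit_admm(data, geom, loss, 0.5, kernel_spec=kernel)
        obj = _fit_objective(data, geom, fit)
        ref = oracle_objective(data, geom, loss, 0.5, kernel_spec=kernel)
        assert obj == pytest.approx(ref, rel=1e-4)

    def test_huge_lambda_shrinks_to_zero(self):
        rng = np.random.default_rng(9)
        data = random_dataset(rng, 30, 3)
        geom = simplex_vertices(3)
        fit = fit_admm(data, geom, LossSpec("squared"), 1e6)
        assert np.abs(fit.B).max() < 1e-4
        obj = _fit_objective(data, geom, fit)
        assert obj == pytest.approx(data.weights.mean(), rel=1e-3)

    def test_trace_settles_at_the_optimum(self):
        """The recorded objective converges to the independent optimum.

        ADMM is not a descent method (the split iterate can undershoot the
        optimum while infeasible), so the trace is checked for
        convergence, not monotonicity.
        """
        rng = np.random.default_rng(10)
        data = random_dataset(rng, 25, 3)
        geom = simplex_vertices(3)
        loss = LossSpec("bent_squared", c=1.3)
        fit = fit_admm(data, geom, loss, 0.3)
        tr = fit.objective_trace
        ref = oracle_objective(data, geom, loss, 0.3)
        assert tr[-1] == pytest.approx(ref, rel=1e-4)
        assert np.abs(np.diff(tr[-5:])).max() < 1e-6


def test_cd_trace_non_increasing(example1_small):
    data, _ = example1_small
    geom = simplex_vertices(3)
    fit = fit_dual_cd(data, geom, LossSpec("bent_hinge", c=1.2), 0.1)
    assert (np.diff(fit.objective_trace) <= 1e-10).all()


def test_outcome_and_lambda_scale_invariance():
    """Doubling all outcomes and lambda leaves the minimizer unchanged."""
    rng = np.random.default_rng(11)
    data = random_dataset(rng, 30, 3)
    geom = simplex_vertices(3)
    data2 = Dataset(X=data.X, A=data.A, y=2 * data.y,
                    propensity=data.propensity, k=3)
    f1 = fit_dual_cd(data, geom, LossSpec("bent_hinge", c=1.2), 0.4)
    f2 = fit_dual_cd(data2, geom, LossSpec("bent_hinge", c=1.2), 0.8)
    np.testing.assert_allclose(f1.B, f2.B, atol=1e-6)


class TestPredict:
    def test_zero_coefficients(self):
        fit = FitResult(mode="linear", loss=LossSpec("hinge"), lam=1.0, k=3,
                        B=np.zeros((4, 2)))
        np.testing.assert_array_equal(predict_f(fit, np.ones((5, 3))), 0.0)

    def test_linear_recovers_covariate(self):
        B = np.zeros((4, 2))
        B[2, 0] = 1.0  # f_1 = x2
        fit = FitResult(mode="linear", loss=LossSpec("hinge"), lam=1.0, k=3, B=B)
        X = np.random.default_rng(0).normal(size=(6, 3))
        np.testing.assert_allclose(predict_f(fit, X)[:, 0], X[:, 1])

    def test_kernel_in_sample_consistency(self):
        rng = np.random.default_rng(12)
        data = random_dataset(rng, 20, 3)
        geom = simplex_vertices(3)
        fit = fit_dual_cd(data, geom, LossSpec("hinge"), 0.5,
                          kernel_spec=KernelSpec("gaussian"))
        f1 = fit.predict(data.X)
        f2 = predict_f(fit, data.X)
        np.testing.assert_array_equal(f1, f2)

    def test_dimension_mismatch(self):
        fit = FitResult(mode="linear", loss=LossSpec("hinge"), lam=1.0, k=3,
                        B=np.zeros((4, 2)))
        with pytest.raises(ValueError):
            predict_f(fit, np.ones((2, 5)))


class TestPopulationFixedPoint:
    """Pointwise population minimizers reproduce the consistency results."""

    def test_bent_hinge_margin_pattern(self):
        # mu = (1, 1.1, 1.3), c = 1.2: treatment 2 near-optimal, 3 not
        geom = simplex_vertices(3)
        m = pointwise_bent_hinge_margins([1.0, 1.1, 1.3], geom, c=1.2)
        assert m[0] > 0
        assert abs(m[1]) <= 1e-4
        assert m[2] < 0

    def test_bent_hinge_all_near_optimal(self):
        geom = simplex_vertices(3)
        m = pointwise_bent_hinge_margins([1.0, 1.05, 1.1], geom, c=1.2)
        # no split index exists: all margins collapse to zero
        np.testing.assert_allclose(m, 0.0, atol=1e-8)

    def test_exponential_ratio_recovery(self):
        mu = np.array([1.0, 1.1, 1.3])
        geom = simplex_vertices(3)
        m = pointwise_exponential_margins(mu, geom)
        ratios = ratio_estimate(LossSpec("exponential"), m)
        np.testing.assert_allclose(ratios, mu / mu[0], atol=1e-3)
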