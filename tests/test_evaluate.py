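import numpy as np
import pytest

from aitrlearn.data import Dataset
from aitrlearn.evaluate import (
    MCEstimate,
    UndefinedValueError,
    empirical_value,
    empirical_weighted_outcome,
    performance_interval,
    population_oracle,
    region_partition,
    tune_delta,
    tune_lambda,
)
from aitrlearn.geometry import simplex_vertices
from aitrlearn.losses import LossSpec
from aitrlearn.recommend import RecommendationSet
from aitrlearn.simulate import DGPSpec, draw_dataset
from aitrlearn.solvers import fit_dual_cd


def _dataset(A, y, p):
    n = len(A)
    X = np.zeros((n, 1))
    return Dataset(X=X, A=A, y=y, propensity=p, k=int(max(A)))


class TestEmpiricalValue:
    def test_single_subject_reduces_to_outcome(self):
        data = _dataset([1], [2.0], [0.5])
        assert empirical_value(data, [1]) == 2.0

    def test_no_match_raises(self):
        data = _dataset([1, 1], [2.0, 1.0], [0.5, 0.5])
        with pytest.raises(UndefinedValueError):
            empirical_value(data, [2, 2])  # k inferred as 1? use A=2 anyway

    def test_equal_propensity_is_plain_mean(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 3, size=20)
        A = rng.integers(1, 4, size=20)
        data = _dataset(A, y, np.full(20, 1 / 3))
        assert empirical_value(data, A) == pytest.approx(y.mean())


class TestWeightedOutcome:
    def test_singleton_sets_reduce_to_value(self):
        rng = np.random.default_rng(1)
        n = 30
        A = rng.integers(1, 4, size=n)
        y = rng.uniform(0.5, 3, size=n)
        p = rng.uniform(0.2, 0.5, size=n)
        data = _dataset(A, y, p)
        d = rng.integers(1, 4, size=n)
        memb = np.zeros((n, 3), dtype=bool)
        memb[np.arange(n), d - 1] = True
        phi = RecommendationSet(memb, "one_step")
        assert empirical_weighted_outcome(data, phi, 1.2) == pytest.approx(
            empirical_value(data, d))

    def test_worked_single_subject(self):
        data = _dataset([1], [2.0], [0.5])
        phi = RecommendationSet.from_lists([[1, 2]], 2, "one_step")
        # numerator 2/(0.5*2.2), denominator 1/(0.5*2)
        assert empirical_weighted_outcome(data, phi, 1.2) == pytest.approx(
            (2 / (0.5 * 2.2)) / (1 / (0.5 * 2)))

    def test_full_sets_denominator(self):
        data = _dataset([1, 2], [2.0, 4.0], [0.5, 0.25])
        phi = RecommendationSet.from_lists([[1, 2], [1, 2]], 2, "one_step")
        num = 2 / (0.5 * 2) + 4 / (0.25 * 2)
        den = 1 / (0.5 * 2) + 1 / (0.25 * 2)
        assert empirical_weighted_outcome(data, phi, 1.0) == pytest.approx(num / den)

    def test_no_membership_raises(self):
        data = _dataset([1], [2.0], [0.5])
        phi = RecommendationSet.from_lists([[2]], 2, "one_step")
        with pytest.raises(UndefinedValueError):
            empirical_weighted_outcome(data, phi, 1.2)


class TestRegions:
    def test_labels(self):
        mu = np.array([
            [1.0, 3.0, 3.0],    # singleton -> R1
            [1.0, 1.1, 1.3],    # pair -> R2
            [1.0, 1.1, 1.15],   # all -> R3
        ])
        np.testing.assert_array_equal(region_partition(mu, 1.2),
                                      ["R1", "R2", "R3"])

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(0.5, 3, size=(100, 3))
        labels = region_partition(mu, 1.2)
        assert set(labels) <= {"R1", "R2", "R3"}

    def test_region_growth_in_c(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(0.5, 3, size=(2000, 3))
        f1 = (region_partition(mu, 1.1) == "R1").mean()
        f2 = (region_partition(mu, 1.4) == "R1").mean()
        r1 = (region_partition(mu, 1.1) == "R3").mean()
        r2 = (region_partition(mu, 1.4) == "R3").mean()
        assert f2 <= f1 and r1 <= r2


class TestPerformanceInterval:
    def test_singletons_degenerate(self):
        ystar = np.array([[1.0, 3.0], [2.0, 0.5]])
        phi = RecommendationSet.from_lists([[1], [2]], 2, "one_step")
        labels = np.array(["R1", "R1"])
        intervals, missing = performance_interval(phi, ystar, labels)
        lo, hi = intervals["R1"]
        assert lo == hi == pytest.approx((1.0 + 0.5) / 2)
        assert missing == ["R2", "R3"]

    def test_full_sets(self):
        ystar = np.array([[1.0, 3.0], [2.0, 2.0]])
        phi = RecommendationSet.from_lists([[1, 2], [1, 2]], 2, "one_step")
        labels = np.array(["R3", "R3"])
        intervals, _ = performance_interval(phi, ystar, labels)
        assert intervals["R3"] == (pytest.approx(1.5), pytest.approx(2.5))

    def test_widening_under_set_growth(self):
        rng = np.random.default_rng(4)
        ystar = rng.normal(size=(50, 3))
        labels = np.full(50, "R2")
        small = RecommendationSet.from_lists([[1]] * 50, 3, "one_step")
        big = RecommendationSet.from_lists([[1, 2]] * 50, 3, "one_step")
        s, _ = performance_interval(small, ystar, labels)
        b, _ = performance_interval(big, ystar, labels)
        assert b["R2"][0] <= s["R2"][0] and b["R2"][1] >= s["R2"][1]


@pytest.fixture(scope="module")
def small_train():
    data, _ = draw_dataset(DGPSpec(example_id=1, p=2), 150, seed=11)
    return data


class TestTuning:
    def _fit_fn(self, data, lam):
        geom = simplex_vertices(data.k)
        return fit_dual_cd(data, geom, LossSpec("bent_hinge", c=1.2), lam)

    def test_single_point_grid(self, small_train):
        t = tune_lambda(small_train, self._fit_fn, [0.5], folds=3, seed=0)
        assert t.best_lambda == 0.5

    def test_duplicates_equivalent(self, small_train):
        t1 = tune_lambda(small_train, self._fit_fn, [0.1, 1.0], folds=3, seed=0)
        t2 = tune_lambda(small_train, self._fit_fn, [0.1, 1.0, 0.1], folds=3,
                         seed=0)
        assert t1.best_lambda == t2.best_lambda

    def test_reproducible(self, small_train):
        kw = dict(lambda_grid=[0.01, 0.1, 1.0], folds=3, seed=7)
        t1 = tune_lambda(small_train, self._fit_fn, **kw)
        t2 = tune_lambda(small_train, self._fit_fn, **kw)
        assert t1.best_lambda == t2.best_lambda
        assert t1.cv_values == t2.cv_values

    def test_delta_degenerate_grid(self, small_train):
        t = tune_lambda(small_train, self._fit_fn, [0.1], folds=3, seed=0)
        best, cv = tune_delta(small_train, t.fold_fits, [0.0], c=1.2)
        assert best == 0.0 and set(cv) == {0.0}

    def test_delta_reproducible(self, small_train):
        t = tune_lambda(small_train, self._fit_fn, [0.1], folds=3, seed=0)
        grid = np.linspace(-0.2, 0.2, 9)
        b1, cv1 = tune_delta(small_train, t.fold_fits, grid, c=1.2)
        b2, cv2 = tune_delta(small_train, t.fold_fits, grid, c=1.2)
        assert b1 == b2 and cv1 == cv2


class TestPopulationOracle:
    def test_full_set_rule_closed_form(self):
        """The always-everything rule's value is E[sum_j mu_j]/(1+(k-1)c)."""
        spec = DGPSpec(example_id=1, p=2, c=1.2)
        est = population_oracle(spec, lambda mu: np.ones_like(mu, bool),
                                n_mc=50_000, seed=0)
        assert isinstance(est, MCEstimate)
        # E[mu_1 + mu_2 + mu_3] on [-1,1]^2: (1+2) + (3-1/3) + 3 = 8.667
        expected = (3.0 + (3.0 - 1.0 / 3.0) + 3.0) / (1.0 + 2 * 1.2)
        assert est.value == pytest.approx(expected, abs=4 * est.stderr)

    def test_example2_closed_form(self):
        """Best-arm value for the cosine design: 2 - 8/pi^2."""
        est = population_oracle(DGPSpec(example_id=2, p=2), "bayes_itr",
                                n_mc=400_000, seed=1)
        assert est.value == pytest.approx(2 - 8 / np.pi ** 2, abs=4 * est.stderr)

    def test_ipw_denominator_calibration(self):
        """E[ 1[A in phi]/(p |phi|) ] = 1 under correct propensities."""
        spec = DGPSpec(example_id=1, p=2)
        data, po = draw_dataset(spec, 100_000, seed=5)
        from aitrlearn.recommend import bayes_phi_star

        memb = bayes_phi_star(po.mu, spec.c)
        card = memb.sum(1)
        match = memb[np.arange(data.n), data.A - 1]
        terms = match / (data.propensity * card)
        se = terms.std(ddof=1) / np.sqrt(data.n)
        assert terms.mean() == pytest.approx(1.0, abs=3 * se)
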