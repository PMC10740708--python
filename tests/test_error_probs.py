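import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from celldecide import (
    DecisionProblem,
    DecisionBoundary,
    ErrorReport,
    closed_form_errors,
    empirical_count_errors,
    monte_carlo_errors,
    overall_error,
    q_function,
    solve_univariate_threshold,
)
from conftest import model_1d, random_problem_1d, random_problem_2d


class TestQFunction:
    def test_symmetry_point(self):
        assert q_function(0.0) == pytest.approx(0.5)

    def test_limits(self):
        assert q_function(np.inf) == 0.0
        assert q_function(-np.inf) == 1.0

    def test_matches_tail_quadrature(self):
        # independent oracle: adaptive quadrature of the Gaussian tail
        expected, _ = quad(lambda u: np.exp(-u * u / 2) / np.sqrt(2 * np.pi), 1, np.inf)
        assert q_function(1.0) == pytest.approx(expected, abs=1e-12)
        assert q_function(1.0) == pytest.approx(0.158655, abs=1e-6)


class TestOverallError:
    def test_weighted_sum(self):
        assert overall_error(0.18, 0.31, 0.5, 0.5) == pytest.approx(0.245)
        assert overall_error(0.0, 0.0, 0.5, 0.5) == 0.0
        assert overall_error(1.0, 0.0, 0.3, 0.7) == pytest.approx(0.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            overall_error(0.1, 0.1, 0.6, 0.6)
        with pytest.raises(ValueError):
            overall_error(1.5, 0.0, 0.5, 0.5)


class TestClosedForm:
    def test_symmetric_problem(self):
        p = DecisionProblem(model_1d(0, 1), model_1d(2, 1))
        r = closed_form_errors(p)
        assert r.p_fa == pytest.approx(q_function(1.0), abs=1e-12)
        assert r.p_m == pytest.approx(q_function(1.0), abs=1e-12)

    def test_two_root_case_matches_quadrature(self):
        # mu equal, sd 1 vs 2: H1 decided in both tails beyond +/- x_th
        p = DecisionProblem(model_1d(0, 1), model_1d(0, 2))
        x_th = np.sqrt(8.0 / 3.0 * np.log(2.0))
        expected_fa = 2 * quad(norm(0, 1).pdf, x_th, np.inf)[0]
        expected_m = quad(norm(0, 2).pdf, -x_th, x_th)[0]
        r = closed_form_errors(p)
        assert r.p_fa == pytest.approx(expected_fa, abs=1e-12)
        assert r.p_fa == pytest.approx(0.173970, abs=1e-6)
        assert r.p_m == pytest.approx(expected_m, abs=1e-12)

    def test_identical_models_no_separability(self):
        m = model_1d(1.0, 1.0)
        with pytest.warns(UserWarning):
            r = closed_form_errors(DecisionProblem(m, m))
        assert r.p_fa + r.p_m == pytest.approx(1.0)
        assert r.p_e == pytest.approx(0.5)

    @pytest.mark.parametrize("d,sd", [(1.0, 0.5), (2.0, 1.0), (0.3, 1.7)])
    def test_symmetric_identity_q_d_over_2sigma(self, d, sd):
        p = DecisionProblem(model_1d(0, sd), model_1d(d, sd))
        r = closed_form_errors(p)
        expected = float(q_function(d / (2 * sd)))
        assert r.p_fa == pytest.approx(expected, abs=1e-9)
        assert r.p_m == pytest.approx(expected, abs=1e-9)

    def test_monotone_separation(self):
        """P_E strictly decreases as the mean separation grows."""
        errs = [
            closed_form_errors(DecisionProblem(model_1d(0, 1), model_1d(d, 1))).p_e
            for d in np.linspace(0.2, 4.0, 12)
        ]
        assert np.all(np.diff(errs) < 0)

    def test_optimal_threshold_minimizes_p_e(self, rng):
        """Shifting every root of the optimal boundary away never lowers P_E."""
        for _ in range(10):
            p = random_problem_1d(rng)
            bnd = solve_univariate_threshold(p)
            base = closed_form_errors(p, bnd).p_e
            for delta in np.linspace(0.05, 0.5, 20):
                for sign in (-1, 1):
                    shifted = DecisionBoundary(
                        dim=1,
                        roots=[r + sign * delta for r in bnd.roots],
                        intervals=[
                            ((lo + sign * delta, hi + sign * delta), d)
                            for (lo, hi), d in bnd.intervals
                        ],
                    )
                    assert closed_form_errors(p, shifted).p_e >= base - 1e-12


class TestMonteCarlo:
    def test_1d_agrees_with_closed_form(self):
        p = DecisionProblem(model_1d(0, 1), model_1d(2, 1))
        r = monte_carlo_errors(p, n=200_000, seed=11)
        exact = float(q_function(1.0))
        assert abs(r.p_fa - exact) < 4 * r.stderr_fa
        assert abs(r.p_m - exact) < 4 * r.stderr_m

    def test_2d_separable_problem_matches_1d_oracle(self):
        import celldecide as cd

        p = DecisionProblem(
            cd.GaussianModel(np.zeros(2), np.eye(2)),
            cd.GaussianModel(np.array([2.0, 0.0]), np.eye(2)),
        )
        r = monte_carlo_errors(p, n=200_000, seed=5)
        exact = float(q_function(1.0))
        assert abs(r.p_fa - exact) < 4 * r.stderr_fa

    def test_identical_models_regions_are_complementary(self):
        m = model_1d(0, 1)
        r = monte_carlo_errors(DecisionProblem(m, m), n=2000, seed=3)
        assert r.p_fa + r.p_m == pytest.approx(1.0, abs=1e-12)

    def test_seed_required_and_recorded(self):
        p = DecisionProblem(model_1d(0, 1), model_1d(2, 1))
        with pytest.raises(ValueError):
            monte_carlo_errors(p, n=2000)
        assert monte_carlo_errors(p, n=2000, seed=9).seed == 9

    def test_minimum_n(self):
        p = DecisionProblem(model_1d(0, 1), model_1d(2, 1))
        with pytest.raises(ValueError):
            monte_carlo_errors(p, n=10, seed=1)


class TestEmpiricalCount:
    def test_points_far_from_boundary(self):
        p = DecisionProblem(model_1d(0, 1), model_1d(10, 1))
        data0 = np.full((5, 1), 0.0)
        data1 = np.full((5, 1), 10.0)
        r = empirical_count_errors(p, data0, data1)
        assert r.p_fa == 0.0 and r.p_m == 0.0

    def test_tie_point_counts_as_h0(self):
        # midpoint of a symmetric problem is exactly on the boundary
        p = DecisionProblem(model_1d(0, 1), model_1d(2, 1))
        r = empirical_count_errors(p, np.array([[1.0]]), np.array([[1.0]]))
        assert r.p_fa == 0.0  # not a false alarm
        assert r.p_m == 1.0  # H0 decided under H1 -> miss

    def test_equals_monte_carlo_on_shared_draws(self, rng):
        """The two estimators are the same statistic given the same points."""
        for _ in range(5):
            p = random_problem_2d(rng)
            seed = int(rng.integers(2**31))
            g = np.random.default_rng(seed)
            z0 = p.h0.sample(5000, g)
            z1 = p.h1.sample(5000, g)
            mc = monte_carlo_errors(p, n=5000, seed=seed)
            ec = empirical_count_errors(p, z0, z1)
            assert mc.p_fa == ec.p_fa and mc.p_m == ec.p_m and mc.p_e == ec.p_e

    def test_empty_data_raises(self):
        p = DecisionProblem(model_1d(0, 1), model_1d(2, 1))
        with pytest.raises(ValueError):
            empirical_count_errors(p, np.empty((0, 1)), np.array([[1.0]]))


def test_error_report_enforces_weighted_sum():
    with pytest.raises(ValueError):
        ErrorReport(p_fa=0.1, p_m=0.2, p_e=0.9, method="closed_form")
    with pytest.raises(ValueError):
        ErrorReport(p_fa=1.2, p_m=0.2, p_e=0.7, method="closed_form")
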