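import numpy as np
import pytest

from celldecide import DecisionProblem, GaussianModel


def model_1d(mu: float, sd: float) -> GaussianModel:
    return GaussianModel(np.array([mu]), np.array([[sd**2]]))


def random_problem_1d(rng: np.random.Generator) -> DecisionProblem:
    """A random nondegenerate univariate low-vs-high problem."""
    mu0 = rng.uniform(-1, 1)
    mu1 = mu0 + rng.uniform(0.3, 3.0)
    sd0 = rng.uniform(0.3, 1.5)
    sd1 = rng.uniform(0.3, 1.5)
    return DecisionProblem(model_1d(mu0, sd0), model_1d(mu1, sd1))


def random_problem_2d(rng: np.random.Generator) -> DecisionProblem:
    """A random bivariate problem with well-conditioned covariances."""

    def rand_model(shift):
        mu = rng.uniform(-1, 1, size=2) + shift
        a = rng.uniform(-0.8, 0.8, size=(2, 2))
        sigma = a @ a.T + np.diag(rng.uniform(0.2, 1.0, size=2))
        return GaussianModel(mu, sigma)

    return DecisionProblem(rand_model(0.0), rand_model(rng.uniform(0.5, 2.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(20231461)
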