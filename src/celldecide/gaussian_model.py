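"""Gaussian models of log-concentrations and the binary decision problem.

Under each hypothesis H_i about the input level, the vector z of
log-concentrations is modelled as N-variate Gaussian with mean mu_i and
covariance Sigma_i.  The optimal (minimum-error-probability) rule
compares the likelihood ratio L(z) = p(z|H1)/p(z|H0) with the threshold
gamma = P(H0)/P(H1), deciding H1 iff L(z) > gamma.  Ties (L = gamma)
decide H0, consistently across every estimator in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

#: covariance condition numbers above this are treated as singular
COND_LIMIT = 1e12


class DegenerateModelError(ValueError):
    """Covariance is singular or too ill-conditioned to invert reliably."""


@dataclass(frozen=True)
class GaussianModel:
    """A fitted N-variate Gaussian in log-concentration space.

    ``mu`` is the mean vector (length N); ``sigma`` the N×N covariance.
    Scalars are accepted for N=1.  The Cholesky factor, log-determinant
    and inverse are precomputed; construction fails with
    :class:`DegenerateModelError` if the covariance is not symmetric
    positive definite (condition number ≤ 1e12).
    """

    mu: np.ndarray
    sigma: np.ndarray
    _chol: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.ndim == 0:
            sigma = sigma.reshape(1, 1)
        if sigma.shape != (mu.size, mu.size):
            raise ValueError(f"sigma shape {sigma.shape} does not match mu ({mu.size})")
        if not np.allclose(sigma, sigma.T, rtol=1e-10, atol=0):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        try:
            chol = linalg.cholesky(sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise DegenerateModelError(f"covariance is not positive definite: {exc}")
        if np.linalg.cond(sigma) > COND_LIMIT:
            raise DegenerateModelError(
                f"covariance condition number exceeds {COND_LIMIT:g}"
            )
        object.__setattr__(self, "_chol", chol)

    @property
    def dim(self) -> int:
        return self.mu.size

    @property
    def log_det(self) -> float:
        """ln |Sigma|, from the Cholesky factor."""
        return 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    @property
    def inv_sigma(self) -> np.ndarray:
        """Sigma^{-1} (dense; N ≤ a few here)."""
        eye = np.eye(self.dim)
        return linalg.cho_solve((self._chol, True), eye)

    @property
    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.sigma))

    @property
    def rho(self) -> float:
        """Correlation coefficient (N=2 only)."""
        if self.dim != 2:
            raise ValueError("rho is defined for bivariate models only")
        sx, sy = self.marginal_sd
        return float(self.sigma[0, 1] / (sx * sy))

    def log_pdf(self, z: np.ndarray) -> np.ndarray | float:
        """ln p(z|H_i) for a point (length N) or batch (m, N).

        Evaluated in log form throughout:
        -N/2 ln 2π - 1/2 ln|Sigma| - 1/2 (z-mu)^T Sigma^{-1} (z-mu),
        with the quadratic form computed through the Cholesky factor.
        """
        z = np.asarray(z, dtype=float)
        scalar_in = z.ndim <= 1
        pts = np.atleast_2d(z)
        if pts.shape[1] != self.dim:
            raise ValueError(f"points have dim {pts.shape[1]}, model has {self.dim}")
        dev = pts - self.mu
        w = linalg.solve_triangular(self._chol, dev.T, lower=True)
        maha = np.sum(w * w, axis=0)
        out = -0.5 * (self.dim * np.log(2.0 * np.pi) + self.log_det + maha)
        return float(out[0]) if scalar_in else out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points, shape (n, N)."""
        std = rng.standard_normal((n, self.dim))
        return self.mu + std @ self._chol.T


def fit_gaussian(samples: np.ndarray, names: list[str] | None = None) -> GaussianModel:
    """Fit a Gaussian to an (n, N) sample matrix of log-concentrations.

    Uses the sample mean and the unbiased (n−1 denominator) sample
    covariance.  ``names`` (optional output names) improve the error
    message when a column is degenerate.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, dim = x.shape
    if n < dim + 1:
        raise ValueError(f"need at least {dim + 1} samples to fit a {dim}-D Gaussian")
    if np.isnan(x).any():
        raise ValueError("samples contain missing values")
    mu = x.mean(axis=0)
    sigma = np.cov(x, rowvar=False, ddof=1).reshape(dim, dim)
    var = np.diag(sigma)
    if np.any(var <= 0):
        bad = [
            (names[j] if names else f"column {j}") for j in np.nonzero(var <= 0)[0]
        ]
        raise DegenerateModelError(f"constant output(s) give zero variance: {bad}")
    try:
        return GaussianModel(mu, sigma)
    except DegenerateModelError as exc:
        raise DegenerateModelError(f"sample covariance is degenerate: {exc}")


@dataclass(frozen=True)
class DecisionProblem:
    """A pair of Gaussian hypotheses with prior probabilities.

    H0 is the low-input hypothesis, H1 the high-input one.  The
    likelihood threshold is gamma = P(H0)/P(H1); all computations use
    equal priors unless told otherwise.
    """

    h0: GaussianModel
    h1: GaussianModel
    prior0: float = 0.5
    prior1: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.prior0 < 1.0 and 0.0 < self.prior1 < 1.0):
            raise ValueError("priors must lie strictly in (0, 1)")
        if abs(self.prior0 + self.prior1 - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        if self.h0.dim != self.h1.dim:
            raise ValueError("both hypotheses must have the same dimension")

    @property
    def dim(self) -> int:
        return self.h0.dim

    @property
    def gamma(self) -> float:
        """Likelihood threshold gamma = P(H0)/P(H1)."""
        return self.prior0 / self.prior1

    @property
    def log_gamma(self) -> float:
        return float(np.log(self.gamma))

    def swapped(self) -> DecisionProblem:
        """The problem with hypotheses (and priors) exchanged."""
        return DecisionProblem(self.h1, self.h0, self.prior1, self.prior0)


def log_likelihood_ratio(
    problem: DecisionProblem, z: np.ndarray
) -> np.ndarray | float:
    """ln L(z) = ln p(z|H1) − ln p(z|H0) for a point or batch.

    The optimal rule decides H1 iff ln L(z) > ln gamma.
    """
    return problem.h1.log_pdf(z) - problem.h0.log_pdf(z)


def decide_h1(problem: DecisionProblem, z: np.ndarray) -> np.ndarray | bool:
    """Boolean decision(s): True where H1 is decided (ties go to H0)."""
    llr = log_likelihood_ratio(problem, z)
    return llr > problem.log_gamma
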