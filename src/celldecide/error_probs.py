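"""False-alarm, miss and overall decision error probabilities.

Three mutually cross-validating estimators:

* ``closed_form_errors`` — univariate only; integrates each Gaussian
  tail over the decision intervals with the Q function.
* ``monte_carlo_errors`` — any dimension; draws from each hypothesis
  and scores the fraction landing in the wrong decision region.
* ``empirical_count_errors`` — applies the discriminant functions
  g_i(z) = ln p(z|H_i) + ln P(H_i) to observed data and counts
  misclassifications.

All three use the same tie rule (ln L = ln gamma decides H0), so the
Monte Carlo and counting estimators agree exactly when given the same
draws.  P_E is always the prior-weighted sum P(H0) P_FA + P(H1) P_M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .gaussian_model import DecisionProblem, log_likelihood_ratio
from .thresholds import DecisionBoundary, solve_univariate_threshold


@dataclass(frozen=True)
class ErrorReport:
    """P_FA, P_M and P_E with the estimator used and its uncertainty.

    ``stderr_fa``/``stderr_m``/``stderr_e`` are binomial standard errors
    for sampling-based methods (None for closed form); ``seed`` is the
    Monte Carlo seed.
    """

    p_fa: float
    p_m: float
    p_e: float
    method: str  # closed_form | monte_carlo | empirical_count
    prior0: float = 0.5
    prior1: float = 0.5
    n_samples: int | None = None
    stderr_fa: float | None = None
    stderr_m: float | None = None
    stderr_e: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_fa", "p_m", "p_e"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        expected = self.prior0 * self.p_fa + self.prior1 * self.p_m
        if abs(self.p_e - expected) > 1e-12:
            raise ValueError("p_e must equal prior0*p_fa + prior1*p_m")


def q_function(eta):
    """Standard-normal upper-tail probability Q(eta) = P(Z > eta).

    Computed through the complementary error function,
    Q(eta) = erfc(eta / sqrt(2)) / 2, accurate to full double precision
    over the whole real line.
    """
    return 0.5 * special.erfc(np.asarray(eta, dtype=float) / np.sqrt(2.0))


def overall_error(p_fa: float, p_m: float, prior0: float, prior1: float) -> float:
    """Prior-weighted overall error P_E = P(H0) P_FA + P(H1) P_M."""
    for name, v in (("p_fa", p_fa), ("p_m", p_m), ("prior0", prior0), ("prior1", prior1)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if abs(prior0 + prior1 - 1.0) > 1e-9:
        raise ValueError(f"priors must sum to 1, got {prior0 + prior1}")
    return prior0 * p_fa + prior1 * p_m


def closed_form_errors(
    problem: DecisionProblem, boundary: DecisionBoundary | None = None
) -> ErrorReport:
    """Exact univariate error probabilities from Gaussian tail integrals.

    With a single threshold x_th this is
    P_FA = Q((x_th - mu0)/sigma0), P_M = Q((mu1 - x_th)/sigma1);
    with two roots the Q-function terms are summed over each decision
    interval.  A boundary-free problem yields 0/1 error probabilities
    according to the dominant hypothesis.
    """
    if problem.dim != 1:
        raise ValueError("closed_form_errors requires a 1-D problem")
    if boundary is None:
        boundary = solve_univariate_threshold(problem)
    if boundary.dim != 1:
        raise ValueError("boundary does not belong to a 1-D problem")

    if boundary.boundary_free:
        p_fa = 1.0 if boundary.dominant == 1 else 0.0
        p_m = 1.0 if boundary.dominant == 0 else 0.0
    else:
        m0, s0 = problem.h0.mu[0], float(np.sqrt(problem.h0.sigma[0, 0]))
        m1, s1 = problem.h1.mu[0], float(np.sqrt(problem.h1.sigma[0, 0]))
        p_fa = 0.0  # mass of p(.|H0) on H1-decided intervals
        p_m = 0.0   # mass of p(.|H1) on H0-decided intervals
        for (lo, hi), decision in boundary.intervals:
            if decision == 1:
                p_fa += _interval_mass(lo, hi, m0, s0)
            else:
                p_m += _interval_mass(lo, hi, m1, s1)
        p_fa = min(max(p_fa, 0.0), 1.0)
        p_m = min(max(p_m, 0.0), 1.0)

    return ErrorReport(
        p_fa=p_fa,
        p_m=p_m,
        p_e=overall_error(p_fa, p_m, problem.prior0, problem.prior1),
        method="closed_form",
        prior0=problem.prior0,
        prior1=problem.prior1,
    )


def _interval_mass(lo: float, hi: float, mu: float, sd: float) -> float:
    """P(lo < X <= hi) for X ~ N(mu, sd^2), as a difference of Q values."""
    q_lo = 1.0 if np.isinf(lo) and lo < 0 else float(q_function((lo - mu) / sd))
    q_hi = 0.0 if np.isinf(hi) and hi > 0 else float(q_function((hi - mu) / sd))
    return q_lo - q_hi


def monte_carlo_errors(
    problem: DecisionProblem, n: int = 1_000_000, seed: int | None = None
) -> ErrorReport:
    """Monte Carlo integration of the region integrals, any dimension.

    Draws ``n`` points from p(z|H0); P_FA is the fraction falling in the
    false-alarm region {ln L > ln gamma}.  Draws ``n`` from p(z|H1); P_M
    is the fraction in the miss region {ln L <= ln gamma}.  Binomial
    standard errors sqrt(p(1-p)/n) are reported, and the seed recorded
    for reproducibility.
    """
    if n < 1000:
        raise ValueError("monte_carlo_errors requires n >= 1000")
    if seed is None:
        raise ValueError("a seed must be provided (and is recorded in the report)")
    rng = np.random.default_rng(seed)
    z0 = problem.h0.sample(n, rng)
    z1 = problem.h1.sample(n, rng)
    return _count_report(
        problem, z0, z1, method="monte_carlo", seed=seed, mc_n=n
    )


def empirical_count_errors(
    problem: DecisionProblem, data0: np.ndarray, data1: np.ndarray
) -> ErrorReport:
    """Discriminant-function error counting on observed data.

    With g_i(z) = ln p(z|H_i) + ln P(H_i), a false alarm is counted for
    each H0-condition point with g_1(z) > g_0(z) and a miss for each
    H1-condition point with g_1(z) <= g_0(z); the counts are divided by
    the respective sample sizes.  Since
    g_1 - g_0 = ln L(z) - ln gamma (the -ln 2π terms cancel), this is
    the same statistic the Monte Carlo estimator computes on its own
    draws.
    """
    data0 = np.atleast_2d(np.asarray(data0, dtype=float).T).T
    data1 = np.atleast_2d(np.asarray(data1, dtype=float).T).T
    if data0.shape[0] == 0 or data1.shape[0] == 0:
        raise ValueError("empirical_count_errors requires nonempty data sets")
    # internal consistency: the discriminant margin equals lnL - lngamma
    g_margin = (
        problem.h1.log_pdf(data0[:1]) + np.log(problem.prior1)
        - problem.h0.log_pdf(data0[:1]) - np.log(problem.prior0)
    )
    llr_margin = log_likelihood_ratio(problem, data0[:1]) - problem.log_gamma
    assert np.allclose(g_margin, llr_margin, rtol=0, atol=1e-9)
    return _count_report(problem, data0, data1, method="empirical_count")


def _count_report(
    problem: DecisionProblem,
    z0: np.ndarray,
    z1: np.ndarray,
    method: str,
    seed: int | None = None,
    mc_n: int | None = None,
) -> ErrorReport:
    lg = problem.log_gamma
    fa = log_likelihood_ratio(problem, z0) > lg  # deciding H1 under H0
    miss = log_likelihood_ratio(problem, z1) <= lg  # deciding H0 under H1 (ties -> H0)
    n0, n1 = len(z0), len(z1)
    p_fa = float(np.count_nonzero(fa)) / n0
    p_m = float(np.count_nonzero(miss)) / n1
    se_fa = float(np.sqrt(p_fa * (1.0 - p_fa) / n0))
    se_m = float(np.sqrt(p_m * (1.0 - p_m) / n1))
    return ErrorReport(
        p_fa=p_fa,
        p_m=p_m,
        p_e=overall_error(p_fa, p_m, problem.prior0, problem.prior1),
        method=method,
        prior0=problem.prior0,
        prior1=problem.prior1,
        n_samples=mc_n if mc_n is not None else n0 + n1,
        stderr_fa=se_fa,
        stderr_m=se_m,
        stderr_e=float(
            np.sqrt((problem.prior0 * se_fa) ** 2 + (problem.prior1 * se_m) ** 2)
        ),
        seed=seed,
    )


def univariate_errors_exact(mu0, sigma0, mu1, sigma1, prior0=0.5) -> ErrorReport:
    """Convenience wrapper: closed-form errors for scalar Gaussian params.

    ``sigma0``/``sigma1`` are standard deviations.
    """
    from .gaussian_model import GaussianModel

    problem = DecisionProblem(
        GaussianModel(np.array([mu0]), np.array([[sigma0**2]])),
        GaussianModel(np.array([mu1]), np.array([[sigma1**2]])),
        prior0,
        1.0 - prior0,
    )
    return closed_form_errors(problem)
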