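"""Optimal decision thresholds: scalar roots and the bivariate DTC.

Setting the log-likelihood ratio equal to ln gamma gives, for Gaussian
hypotheses, a quadratic equation.  In one dimension

    (1/s1 - 1/s0) x^2 - 2 (mu1/s1 - mu0/s0) x
        + mu1^2/s1 - mu0^2/s0 + ln(s1/s0) + 2 ln gamma = 0,

with s_i the variances; in two dimensions the zero set of

    z^T (S1i - S0i) z - 2 (mu1^T S1i - mu0^T S0i) z
        + mu1^T S1i mu1 - mu0^T S0i mu0 + ln(|S1|/|S0|) + 2 ln gamma,

with S_ii the inverse covariances, is the optimal decision threshold
curve (DTC) — a conic section.  The curve is extracted numerically
(marching squares on a grid of log-likelihood-ratio values, then 1-D
root polishing along grid lines) rather than by closed-form conic
parameterisation, which keeps every degenerate case uniform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from skimage import measure

from .gaussian_model import DecisionProblem, log_likelihood_ratio

logger = logging.getLogger("celldecide")

#: |ln L - ln gamma| tolerance for polished curve vertices
TOL_CURVE = 1e-6
#: target residual for the 1-D polishing root finder
POLISH_TOL = 1e-9
#: default contouring grid (per axis)
DEFAULT_RESOLUTION = 512
#: default bounding box: union of mu +/- BBOX_SDS marginal SDs
BBOX_SDS = 5.0


class DegenerateBoundaryWarning(UserWarning):
    """The two hypotheses are (numerically) identical: no boundary exists."""


@dataclass
class DecisionBoundary:
    """The solved decision boundary of a 1-D or 2-D problem.

    For ``dim == 1``: ``roots`` holds the threshold value(s) (0, 1 or 2)
    and ``intervals`` the resulting partition of the line as
    ``((lo, hi), hypothesis)`` pairs, hypothesis ∈ {0, 1}.  For
    ``dim == 2``: ``curves`` holds ordered polylines (k, 2 arrays of
    (x, y) vertices) tracing {z : ln L(z) = ln gamma} inside ``bbox``,
    and ``conic_type`` classifies the underlying quadratic.  A problem
    where one hypothesis wins everywhere yields empty roots/curves and
    ``dominant`` set to that hypothesis.
    """

    dim: int
    roots: list[float] = field(default_factory=list)
    intervals: list[tuple[tuple[float, float], int]] = field(default_factory=list)
    curves: list[np.ndarray] = field(default_factory=list)
    conic_type: str | None = None
    bbox: tuple[float, float, float, float] | None = None
    dominant: int | None = None

    @property
    def boundary_free(self) -> bool:
        return self.dominant is not None


def _univariate_coeffs(problem: DecisionProblem) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the threshold quadratic a x² + b x + c = 0.

    Note ln L(x) - ln gamma = -(a x² + b x + c) / 2.
    """
    m0, m1 = problem.h0.mu[0], problem.h1.mu[0]
    s0, s1 = problem.h0.sigma[0, 0], problem.h1.sigma[0, 0]
    a = 1.0 / s1 - 1.0 / s0
    b = -2.0 * (m1 / s1 - m0 / s0)
    c = m1**2 / s1 - m0**2 / s0 + np.log(s1 / s0) + 2.0 * problem.log_gamma
    return a, b, c


def solve_univariate_threshold(problem: DecisionProblem) -> DecisionBoundary:
    """Solve the 1-D threshold quadratic and label the decision intervals.

    Returns all real roots (0, 1 or 2).  Equal variances degenerate the
    quadratic to a linear equation with a single root.  When the
    log-likelihood ratio never crosses ln gamma the result is
    boundary-free with the dominant hypothesis recorded; identical
    hypotheses additionally raise :class:`DegenerateBoundaryWarning`
    (ties decide H0).
    """
    if problem.dim != 1:
        raise ValueError("solve_univariate_threshold requires a 1-D problem")
    a, b, c = _univariate_coeffs(problem)
    scale = max(
        abs(a) * max(problem.h0.mu[0] ** 2, problem.h1.mu[0] ** 2, 1.0),
        abs(b), abs(c), 1e-300,
    )
    tiny = 1e-13

    roots: list[float]
    if abs(a) / max(abs(b), abs(c), abs(a), 1e-300) < tiny or a == 0.0:
        if abs(b) / max(abs(c), 1e-300) < tiny or b == 0.0:
            # ln L - ln gamma is constant: one hypothesis everywhere
            if abs(c) <= 1e-12 * scale:
                warnings.warn(
                    "hypotheses are identical: decision boundary undefined "
                    "(ties decide H0)",
                    DegenerateBoundaryWarning,
                )
                return DecisionBoundary(dim=1, dominant=0)
            return DecisionBoundary(dim=1, dominant=1 if c < 0 else 0)
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            # no real crossing; sign of lnL - lngamma = sign of -a at infinity
            return DecisionBoundary(dim=1, dominant=0 if a > 0 else 1)
        sq = np.sqrt(disc)
        # numerically stable quadratic roots
        q = -0.5 * (b + np.copysign(sq, b)) if b != 0.0 else 0.5 * sq
        r1 = q / a
        r2 = c / q if q != 0.0 else r1
        roots = sorted({float(r1), float(r2)})

    roots = sorted(float(r) for r in roots)
    edges = [-np.inf, *roots, np.inf]
    intervals: list[tuple[tuple[float, float], int]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo) and np.isinf(hi):
            mid = 0.0
        elif np.isinf(lo):
            mid = hi - 1.0
        elif np.isinf(hi):
            mid = lo + 1.0
        else:
            mid = 0.5 * (lo + hi)
        llr = log_likelihood_ratio(problem, np.array([mid]))
        decision = 1 if llr > problem.log_gamma else 0
        intervals.append(((lo, hi), decision))
    return DecisionBoundary(dim=1, roots=roots, intervals=intervals)


# ---------------------------------------------------------------------------
# bivariate DTC
# ---------------------------------------------------------------------------

def _bivariate_coeffs(problem: DecisionProblem):
    """(M, b, c) with ln L(z) - ln gamma = -(z^T M z + b^T z + c) / 2."""
    s0i = problem.h0.inv_sigma
    s1i = problem.h1.inv_sigma
    m0, m1 = problem.h0.mu, problem.h1.mu
    M = s1i - s0i
    b = -2.0 * (s1i @ m1 - s0i @ m0)
    c = (
        float(m1 @ s1i @ m1 - m0 @ s0i @ m0)
        + problem.h1.log_det
        - problem.h0.log_det
        + 2.0 * problem.log_gamma
    )
    return M, b, c


def classify_conic(problem: DecisionProblem) -> str:
    """Classify the DTC's conic type from the quadratic-form coefficients.

    One of ``line``, ``parallel_lines``, ``intersecting_lines``,
    ``point``, ``ellipse``, ``parabola``, ``hyperbola``, ``degenerate``
    (no solution set / identical hypotheses).
    """
    M, bvec, c = _bivariate_coeffs(problem)
    A, B, C = M[0, 0], 2.0 * M[0, 1], M[1, 1]
    D, E, F0 = bvec[0], bvec[1], c
    qscale = max(abs(A), abs(B), abs(C))
    lscale = max(abs(D), abs(E), abs(F0), qscale, 1e-300)
    if qscale <= 1e-12 * lscale:
        if max(abs(D), abs(E)) <= 1e-12 * max(abs(F0), 1e-300):
            return "degenerate"
        return "line"
    disc = B * B - 4.0 * A * C
    full = np.array([[A, B / 2, D / 2], [B / 2, C, E / 2], [D / 2, E / 2, F0]])
    det_full = np.linalg.det(full)
    degenerate_full = abs(det_full) <= 1e-10 * max(qscale, 1.0) ** 3 * max(
        1.0, lscale / max(qscale, 1e-300)
    ) ** 2
    if disc < -1e-12 * qscale**2:
        return "point" if degenerate_full else "ellipse"
    if disc > 1e-12 * qscale**2:
        return "intersecting_lines" if degenerate_full else "hyperbola"
    return "parallel_lines" if degenerate_full else "parabola"


def default_bbox(problem: DecisionProblem, k: float = BBOX_SDS):
    """Union of the two models' mu ± k marginal-SD boxes."""
    lo = np.minimum(
        problem.h0.mu - k * problem.h0.marginal_sd,
        problem.h1.mu - k * problem.h1.marginal_sd,
    )
    hi = np.maximum(
        problem.h0.mu + k * problem.h0.marginal_sd,
        problem.h1.mu + k * problem.h1.marginal_sd,
    )
    return float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1])


def trace_dtc(
    problem: DecisionProblem,
    bbox: tuple[float, float, float, float] | None = None,
    resolution: int = DEFAULT_RESOLUTION,
) -> DecisionBoundary:
    """Trace the decision threshold curve {z : ln L(z) = ln gamma}.

    The log-likelihood ratio (minus ln gamma) is evaluated on a
    ``resolution`` × ``resolution`` grid over ``bbox`` (default: union
    of the two cluster boxes mu ± 5 marginal SDs), its zero-level
    contours extracted by marching squares, and every vertex polished by
    a 1-D Brent root search along its grid line to a residual of 1e-9.
    Returns ordered polylines in (x, y) log-concentration coordinates
    plus the conic classification of the underlying quadratic.
    """
    if problem.dim != 2:
        raise ValueError("trace_dtc requires a 2-D problem")
    if bbox is None:
        bbox = default_bbox(problem)
    x_lo, x_hi, y_lo, y_hi = bbox
    xs = np.linspace(x_lo, x_hi, resolution)
    ys = np.linspace(y_lo, y_hi, resolution)
    xx, yy = np.meshgrid(xs, ys)  # shape (ny, nx); row i is y = ys[i]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    f_grid = (
        log_likelihood_ratio(problem, pts) - problem.log_gamma
    ).reshape(resolution, resolution)

    scale = float(np.max(np.abs(f_grid)))
    if scale < 1e-12:
        warnings.warn(
            "hypotheses are identical on this box: decision boundary undefined "
            "(ties decide H0)",
            DegenerateBoundaryWarning,
        )
        return DecisionBoundary(dim=2, bbox=bbox, dominant=0, conic_type="degenerate")

    contours = measure.find_contours(f_grid, 0.0)
    if not contours:
        dominant = 1 if float(f_grid.mean()) > 0 else 0
        return DecisionBoundary(
            dim=2, bbox=bbox, dominant=dominant, conic_type=classify_conic(problem)
        )

    def f_point(x: float, y: float) -> float:
        return float(
            log_likelihood_ratio(problem, np.array([x, y])) - problem.log_gamma
        )

    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    curves = []
    for cont in contours:  # cont[:, 0] = fractional row (y), cont[:, 1] = col (x)
        verts = np.empty((len(cont), 2))
        for k, (ri, ci) in enumerate(cont):
            x = x_lo + ci * dx
            y = y_lo + ri * dy
            # marching-squares vertices sit on grid lines: one index is integral
            if abs(ri - round(ri)) <= 1e-9:  # polish along x at fixed y
                y = y_lo + round(ri) * dy
                lo, hi = x_lo + np.floor(ci) * dx, x_lo + np.ceil(ci) * dx
                x = _polish(lambda t: f_point(t, y), x, lo, hi)
            else:  # polish along y at fixed x
                x = x_lo + round(ci) * dx
                lo, hi = y_lo + np.floor(ri) * dy, y_lo + np.ceil(ri) * dy
                y = _polish(lambda t: f_point(x, t), y, lo, hi)
            verts[k] = (x, y)
        curves.append(verts)

    boundary = DecisionBoundary(
        dim=2,
        curves=curves,
        conic_type=classify_conic(problem),
        bbox=bbox,
    )
    worst = max(
        float(np.max(np.abs(log_likelihood_ratio(problem, c) - problem.log_gamma)))
        for c in curves
    )
    if worst > TOL_CURVE:
        logger.warning("DTC vertex residual %.2e exceeds tolerance %.0e", worst, TOL_CURVE)
    return boundary


def _polish(f, t0: float, lo: float, hi: float) -> float:
    """Refine a grid-edge crossing to |f| <= POLISH_TOL with Brent's method."""
    if abs(f(t0)) <= POLISH_TOL:
        return t0
    if lo == hi:
        return t0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:  # linear-interp vertex already closest representable
        return t0
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16))
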