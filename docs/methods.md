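# Methods

## Model and decision rule

Per-cell output concentrations are modelled, after a natural-log
transform, as N-variate Gaussians under each hypothesis about the
input: **z** | Hᵢ ~ N(μᵢ, Σᵢ), i = 0 (low input) or 1 (high input).
The log transform is fixed (natural base, no alternative offered)
because the downstream algebra — the quadratic threshold equations —
is written in ln-concentration space.  Nonpositive or missing
concentrations make the transform undefined; they are excluded at read
time with a logged count rather than pseudo-count shifted, since any
shift would bias the fitted moments.

Parameters are estimated by the sample mean and the unbiased (n−1)
sample covariance.  At the intended scale (thousands of cells per
condition) the difference from the MLE is negligible; the estimator's
sampling error is covered by tests that verify 1/√n shrinkage against
the theoretical standard errors (Var(μ̂ⱼ) = Σⱼⱼ/n,
Var(Σ̂ᵢⱼ) = (ΣᵢᵢΣⱼⱼ + Σᵢⱼ²)/(n−1)).

The decision rule is the likelihood-ratio test: decide H1 iff
ln L(**z**) > ln γ with γ = P(H0)/P(H1), which minimises the overall
error P_E = P(H0)P_FA + P(H1)P_M.  Priors default to ½/½ (γ = 1) and
are configurable.  Exact ties ln L = ln γ decide H0 — a measure-zero
convention, fixed so that the Monte Carlo and counting estimators are
comparable draw for draw.

## Thresholds and the decision threshold curve

Setting ln L = ln γ for 1-D Gaussians gives the quadratic

(σ₁⁻²−σ₀⁻²)x² − 2(μ₁σ₁⁻²−μ₀σ₀⁻²)x + μ₁²σ₁⁻² − μ₀²σ₀⁻² + ln(σ₁²/σ₀²) + 2 ln γ = 0.

The sign of the prior term matters: +2 ln γ makes the threshold move
toward the H1 cluster when P(H0) grows, lowering P_FA at the cost of
P_M, as it must.  All real roots are returned (unequal variances
generically give two), each interval of the line annotated with the
winning hypothesis by evaluating the rule at interval midpoints.  Equal
variances degenerate the equation to a single linear root; a quadratic
with no real root means one hypothesis dominates the whole line, which
is reported as a boundary-free result (not an error).  Identical
hypotheses yield a boundary-free result with a
`DegenerateBoundaryWarning` (H0 everywhere, by the tie rule).

In 2-D the same level set is a conic.  Rather than parameterising each
conic family in closed form, the curve is traced numerically — the
route that treats all degeneracies uniformly: ln L − ln γ is evaluated
on a 512×512 grid over a bounding box (default: union of the two
μ ± 5 marginal-SD boxes, covering > 0.9999 of each density's mass),
zero contours are extracted by marching squares
(`skimage.measure.find_contours`), and every vertex is polished by a
Brent root search along its grid line to a residual of 1e-9 in
log-likelihood-ratio units (tolerance declared: 1e-6).  The conic type
is classified independently from the quadratic-form coefficients (the
discriminant B²−4AC together with the determinant of the full 3×3
conic matrix, with relative tolerances ~1e-10 for the degeneracy
tests): line, ellipse, parabola, hyperbola, or the degenerate point /
parallel-lines / intersecting-lines cases.

## Error probabilities — three routes

* **Closed form (1-D).**  P_FA is the mass of p(·|H0) over the
  H1-decided intervals, written as differences of
  Q(η) = ½ erfc(η/√2) terms; single-threshold problems reduce to
  P_FA = Q((x_th−μ₀)/σ₀), P_M = Q((μ₁−x_th)/σ₁).  Interval
  decomposition covers the two-root case, which a single-threshold
  formula cannot.
* **Monte Carlo (any N).**  n draws from each hypothesis; P_FA is the
  fraction of H0 draws with ln L > ln γ, P_M the fraction of H1 draws
  with ln L ≤ ln γ.  Binomial standard errors √(p(1−p)/n) and the seed
  are recorded in every report.  Default n = 10⁶ per hypothesis
  (standard error ≤ 5·10⁻⁴); a seed is mandatory, never implicit.
* **Discriminant counting (observed data).**  gᵢ(**z**) = ln p(**z**|Hᵢ)
  + ln P(Hᵢ); false alarms are H0-condition cells with g₁ > g₀, misses
  H1-condition cells with g₁ ≤ g₀.  Since g₁ − g₀ = ln L − ln γ
  identically (asserted internally), this is the same statistic as the
  Monte Carlo estimator, so the two agree *exactly* on shared draws —
  the basis of one acceptance check.

P_E is always computed as the prior-weighted sum, and `ErrorReport`
enforces that identity to 1e-12 at construction.

## MRMR importance

Relevance of an output is its mutual information with the binary
hypothesis label; redundancy is its mean MI with already-ranked
outputs; MIQ = relevance/redundancy ranks the rest after the
max-relevance first pick.  Scores follow the recursive rule
score(1) = relevance(1), score(k) = score(k−1)·MIQ(k)/MIQ(k−1).

MI is the plug-in estimator on quantile bins (default 16 per continuous
output; ≤ 32 distinct values are treated as already discrete), reported
in bits (log₂; nats available).  Quantile binning makes every score
invariant under strictly monotone transforms of an output, so linear
vs log scale is immaterial here.  Two conventions the recursion leaves
open are fixed as follows: the top-ranked output, whose selected set is
empty, takes as redundancy floor its mean MI against the remaining
outputs (keeping its MIQ finite); ties in relevance or MIQ break by
input order with a logged warning.  A consequence worth noting: with
exactly two outputs the recursion telescopes and the second score
equals the second output's relevance — which is why near-zero second
scores track near-zero relevance.  The plug-in estimator is biased
upward at finite n; tests bound that bias at 0.02 bit for independent
variables at n = 10⁴.

## Synthetic data

The generator draws, per condition (input level × timepoint), n cells
from a bivariate Gaussian in log space and exponentiates, so emitted
tables hold linear-scale concentrations and exercise the full pipeline
including the log transform.  The default scenario has 8 conditions
(TNF ∈ {0.013, 0.082, 3.2, 50} ng/mL × {30 min, 4 h}), 3000 cells
each — the "thousands of cells per condition" scale of real
immunocytochemistry screens.  Log-space means and covariances are
fixtures chosen once to realise three qualitative features of such
data: (a) at 30 min the high-dose cluster moves away from the low-dose
cluster monotonically with dose (mean shifts of roughly 1, 3 and 4
pooled SDs); (b) at 4 h all responses are pulled back toward baseline
(≈ 50–55 % of the 30-min shift) with mildly wider spreads, modelling
the negative A20 feedback, so every error probability exceeds its
30-min counterpart; (c) the shift is always larger on the NFκB axis
(in SD units) than on the ATF-2 axis, so NFκB carries more decision
information.  Correlations (ρ ∈ [0.30, 0.38]) are mild and positive.
The exact numbers live in `synthetic_data._DEFAULT_GEOMETRY` and are
exported with every simulated file.

What the generator does *not* emulate: non-Gaussian tails, cell-cycle
or imaging artefacts, batch effects, or any mechanistic pathway
kinetics.  Tests passing on this scenario therefore demonstrate the
correctness of the decision-theoretic machinery under its own
distributional assumptions, not the Gaussianity of any particular real
dataset.

## Numerical choices

* Covariances are validated by Cholesky factorisation plus a condition
  number limit of 1e12; beyond it a `DegenerateModelError` names the
  offending output when known.  Densities are always evaluated in log
  form through the Cholesky factor.
* Quadratic roots use the numerically stable `q = −(b + sign(b)√disc)/2`
  formulation.
* Problem sizes in the test suite and acceptance script (Monte Carlo
  n between 2·10⁵ and 10⁶, 3000 cells per synthetic condition,
  contour grids of 128–512) were chosen so the whole suite runs in
  well under a minute while keeping every stochastic assertion at
  ≥ 4 standard errors of headroom.

## Known limitations

* Closed-form error integration exists only for N = 1; higher
  dimensions rely on Monte Carlo (with reported standard errors) and
  counting.
* The DTC is traced inside a bounding box; branches of an unbounded
  conic outside the box (beyond ±5 SDs) are not represented, though
  their probability mass is negligible by construction.
* The importance module is binary-hypothesis only and implements the
  MIQ scheme; other MRMR variants (difference-based, multi-class) are
  out of scope.
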