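# celldecide

Decision-theoretic analysis of single-cell signaling measurements for a
one-input, multi-output system.

A cell senses an extracellular input (here: TNF, in ng/mL) through the
noisy concentrations of downstream outputs (here: nuclear NFκB and
ATF-2, measured per cell by immunocytochemistry).  Framing "was the
input low or high?" as binary hypothesis testing,

```
H0: input level is low        H1: input level is high
```

`celldecide` fits Gaussian models to the log-concentrations *x* = ln(NFκB),
*y* = ln(ATF-2) under each hypothesis and applies the likelihood-ratio
rule: decide H1 iff L(**z**) = p(**z**|H1)/p(**z**|H0) > γ, with
γ = P(H0)/P(H1).  From this it computes:

* **Decision thresholds** — the scalar roots of the univariate
  quadratic in one dimension, and in two dimensions the *decision
  threshold curve* (DTC), the conic zero set of
  **z**ᵀ(Σ₁⁻¹−Σ₀⁻¹)**z** − 2(μ₁ᵀΣ₁⁻¹−μ₀ᵀΣ₀⁻¹)**z** + μ₁ᵀΣ₁⁻¹μ₁ − μ₀ᵀΣ₀⁻¹μ₀ + ln(|Σ₁|/|Σ₀|) + 2 ln γ,
  traced numerically (marching squares + root polishing) and classified
  (line / ellipse / parabola / hyperbola / degenerate).
* **Error probabilities** — the false-alarm probability
  P_FA = P(decide H1 | H0), miss probability P_M = P(decide H0 | H1)
  and overall error P_E = P(H0)·P_FA + P(H1)·P_M, by three mutually
  cross-validating routes: closed-form Q-function integrals
  (univariate, e.g. P_FA = Q((x_th−μ₀)/σ₀)), Monte Carlo integration
  over the decision regions (any dimension), and discriminant-function
  counting gᵢ(**z**) = ln p(**z**|Hᵢ) + ln P(Hᵢ) on observed cells.
* **Output importance** — minimum-redundancy maximum-relevance (MRMR)
  ranking with the mutual-information quotient (MIQ = relevance /
  redundancy) and its recursive importance scores, quantifying how much
  each output contributes to the decision.

Because real single-cell immunocytochemistry tables of this kind are
rarely deposited, the package ships a synthetic-data generator that
draws per-condition bivariate log-normal clusters (thousands of cells
per condition) with the canonical dose/time geometry: separation grows
with dose at 30 min, overlap grows again at 4 h, and NFκB responds more
strongly than ATF-2.

## Worked example

```python
import numpy as np
from celldecide import (GaussianModel, DecisionProblem,
                        solve_univariate_threshold, closed_form_errors,
                        monte_carlo_errors, overall_error)

# ln-concentration models under low / high input
h0 = GaussianModel(np.array([0.0]), np.array([[1.0]]))
h1 = GaussianModel(np.array([2.0]), np.array([[1.0]]))
problem = DecisionProblem(h0, h1)           # equal priors

b = solve_univariate_threshold(problem)
print(b.roots)                              # [1.0]  (equal-variance midpoint)

r = closed_form_errors(problem, b)
print(round(r.p_fa, 4), round(r.p_m, 4))    # 0.1587 0.1587  (= Q(1))

mc = monte_carlo_errors(problem, n=200_000, seed=11)
print(round(mc.p_fa, 4))                    # 0.1585  (within 4 SE of Q(1))

print(overall_error(0.18, 0.31, 0.5, 0.5))  # 0.245
```

The threshold sits midway between the class means, so both error rates
equal the Gaussian tail probability Q(1) ≈ 0.159; the Monte Carlo route
reproduces the closed form within its binomial standard error, and the
overall error is the prior-weighted average of the two error types.

Full pipeline from the shell:

```
celldecide simulate --seed 1 --out data.csv
celldecide analyze --data data.csv --low 0.013 --high 0.082,3.2,50 \
    --time 30,240 --mc-n 1000000 --mc-seed 1 --out results/
celldecide importance --data data.csv --high 0.082,3.2,50 --time 30,240
```

`analyze` writes `results/results.json` (fitted models, boundaries,
error reports from every method, MRMR scores, full provenance) plus
DTC heatmaps and error-probability bar charts.

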