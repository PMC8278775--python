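# Methods

This note records the models, the numerical choices and the design
decisions behind `incval`, in the order a reader meets them in the code.

## Score-distribution pairs

All rank-based quantities are functionals of the pair `(F1, F0)` of
conditional risk-score CDFs for events and non-events.  Three
representations share one interface (`cdf1/cdf0`, survival functions,
quantiles):

* **closed form** — scipy frozen distributions; quantiles are exact, and
  tail survival probabilities come from `logsf`, so upper-tail ratios
  never lose precision;
* **grid** — tabulated CDF values with piecewise-linear interpolation.
  Grid pairs optionally carry *survival tables* built by integrating from
  the right: `1 − F(c)` computed by subtraction is pure cancellation once
  `F` is within 1e−16 of one, while the survival integral keeps full
  relative precision arbitrarily far into the tail.  Upper-tail quantile
  inversion runs through the survival table for the same reason;
* **empirical** — step ECDFs from sorted class-specific scores, with the
  left-continuous inverse `q̂_α = inf{c : F̂1(c) ≥ α}`.

**Binormal convention.**  `BinormalSpec(mu1, sd1, mu0, sd0)` reads the
second parameter of each class as a **standard deviation**.  The choice
is load-bearing: for the reference scores `r1` (events `N(1.8, sd 2)`)
and `r2` (events `N(1.5, sd 1.5)`), the SD reading gives
`AUC_r2 − AUC_r1 = +0.0077`, while a variance reading flips the sign
(−0.022) and destroys the AUC/AP disagreement the scores exist to
exhibit.

## Integration of the α-functionals

AUC and AP are integrals over the event-quantile level α ∈ (0,1).  For
closed-form pairs they are evaluated by composite trapezoid on a
20,001-point grid over `[1e−6, 1 − 1e−6]`, extended to the full unit
interval by end slabs carrying the boundary values (both integrands are
bounded in [0,1] and smooth at the ends, so the slab error is O(1e−12);
the documented overall tolerance is 1e−5).  The AP integrand's tail ratio
`[1 − F0(q_α)]/(1 − α)` is a 0/0 limit as α → 1 and is computed as
`exp(log_sf0(q_α) − log(1 − α))`.

For grid pairs the same integrals are evaluated in threshold space via
the substitution α = F1(c) — `AUC = ∫ F0 dF1` and
`AP = ∫ {1 + k·S0/S1}⁻¹ dF1` with `k = π⁻¹ − 1` — which avoids inverting
a tabulated CDF and uses the survival tables directly.  For empirical
pairs both integrals are evaluated *exactly*: AUC as the mean of `F̂0`
over event scores (equal to the strict Mann–Whitney statistic on tie-free
data), and AP by the closed-form antiderivative
`∫ t/(t+b) dt = t − b·log(t+b)` on each inter-order-statistic interval,
where the survival ratio is constant.

`incv` always returns the direct difference `Ψ_new − Ψ_old`, but also
evaluates the weighted-integral identity `∫ w_Ψ(α) Δ(α) dα` and raises if
the two routes differ by more than 1e−4 — the identity is exact
mathematics, so a gap means a numerical defect, not a modelling one.
The sign convention is new-minus-old everywhere.  An independent
quadrature route `ap_from_pr_curve` (literal `∫ PPV dTPR` on the
threshold grid) backs the cross-checks in the tests.

## The probit numerical study

True model: `X, Y` iid `N(0,1)`,
`π(X,Y) = Φ(β₀ + β₁X + β₂Y + β₃XY)`, with β₀ calibrated so that
`E[π(X,Y)]` equals the target event rate π.  Working models: probit in
`X` only, and probit in `X` and `Y` (no interaction), with *population*
coefficients — maximisers of the expected probit log likelihood under the
true joint law.  Because neither working class contains the truth when
β₃ ≠ 0, all three IncVs of the two-marker-versus-one-marker comparison
are genuine comparisons of misspecified models.

Numerical scheme, chosen for accuracy per unit cost:

* **Dimension reduction.**  `E_Y[Φ(a + bY)] = Φ(a/√(1+b²))` collapses the
  calibration integral and every one-marker expectation to one dimension
  in `X`.  The calibration solves a bracketed Brent root in β₀ (the rate
  is strictly increasing in β₀) with Simpson quadrature on a 4,001-point
  grid over ±12 SD; the achieved rate matches the target to well below
  1e−8.
* **Rotation for the CDFs.**  For a working model with linear predictor
  `η = γ₀ + γ₁X + γ₂Y`, rotate to coordinates `(U, V)` with
  `η = γ₀ + sU`, `s = √(γ₁²+γ₂²)`.  The conditional mean risk
  `m(u) = E[π(X,Y)|U=u]` is a 1-D Gauss–Hermite integral (100 nodes) in
  `V`; then `π·F1(c) = ∫_{−∞}^{u_c} m(u)φ(u)du` and
  `(1−π)·F0(c) = ∫_{−∞}^{u_c} [1−m(u)]φ(u)du`, accumulated by cumulative
  Simpson on a uniform 4,001-point grid over ±12 SD of `U`, with the
  matching survival integrals accumulated from the right.  The
  event/non-event MSPEs for the Brier components are Simpson integrals on
  the same grid.
* **Self-check.**  By total probability the mixture
  `π·F1 + (1−π)·F0` must equal the exactly normal marginal CDF of η;
  `score_distribution_pair` verifies this at every grid point and raises
  beyond 1e−6.  In practice the deviation is ~1e−10.
* **Population coefficients.**  Fisher-scoring Newton on the
  quadrature-weighted probit likelihood (fractional targets = true risks
  at the nodes), run to gradient norm ≤ 1e−10 with step halving; the
  two-marker objective uses a 100×100 tensor Gauss–Hermite rule.  All
  tail quantities go through `log Φ` so nodes with |η| ≈ 40 stay finite.
  The same solver fits binary samples (`fit_probit`), which keeps the
  Monte-Carlo oracle for the population limits free of extra
  dependencies.

Doubling every resolution knob moves each scenario's three IncVs by far
less than the tested stability budget of 5e−4, and a scenario costs
roughly 0.08 s, so the full 3,200-scenario sweep (β₁, β₂ ∈ 0.3…1.0 by
0.1; β₃ ∈ ±0.1…0.5; π ∈ {0.01, 0.05, 0.1, 0.2, 0.5}) runs in about five
minutes on one CPU.  The sweep is deterministic and resumable through a
per-row CSV cache; failures are collected and raised together, never
silently dropped.

**Score scale.**  Rank metrics use the working linear predictor η
(monotone-invariant, so equivalent to using `Φ(η)`); Brier components use
the working risk `Φ(η)`.

**Summary conventions.**  Quartiles use linear interpolation of order
statistics (numpy's default, R type 7).  The sign-concordance of an IncV
pair counts a scenario as concordant when both values are > 0 or both
are ≤ 0, and equals the concordant share minus the discordant share;
exact zeros fall in the "≤ 0" class and no tolerance band is applied,
since the values are deterministic integrals.  Pearson correlations and
concordances are computed over the 640 scenarios at each event rate.

## Estimators

* `estimate_auc`: Mann–Whitney double sum with strict `>`; tied pairs
  count 0 by default, 1/2 under the optional midrank correction.  The
  O(n log n) implementation (sort + binary search) equals the O(n²)
  brute force exactly, ties included.
* `estimate_ap`: mean over events of precision at the event's own score.
  The default "≥" convention counts each event's own record in both
  numerator and denominator, so every term is well defined (denominator
  ≥ 1) and ties are handled naturally; the literal strictly-greater
  variant (top-ranked event's 0/0 term dropped) is available as an
  option.  Both converge to the population AP for continuous scores.
* `estimate_brier_sbrs`: plug-in `n⁻¹Σ(Dᵢ−p̂ᵢ)²` with the event/non-event
  MSPE split and `sBrS = 1 − BrS/[π̂(1−π̂)]`; undefined when the sample
  has a single outcome class.
* `empirical_pair` feeds the estimators' data into the analytic
  machinery; with step ECDFs the Δ(α) curve of two fitted models is a
  step function in α, which is the documented behaviour (the population
  Δ(α) is smooth; no smoothing is applied).

## Synthetic data

The generators emulate exactly the two mechanisms above: binormal scores
with Bernoulli(π) outcomes, and the calibrated probit model with its true
risks in the `risk` column.  A single master seed drives
`numpy.random.default_rng`; identical seeds give identical samples.  What
the generators deliberately do not emulate: covariate measurement error,
censored or time-dependent outcomes, non-Gaussian markers, miscalibrated
risk columns.  Passing tests therefore demonstrate correctness of the
estimators and engines under the stated mechanisms, not robustness of the
metrics on messier real cohorts.

## Known limitations

* Analytic quantities come without uncertainty statements; the empirical
  estimators come without confidence intervals or tests.
* Discrete/tied scores are first-class only in the empirical module;
  the analytic representations assume continuous scores.
* Case-control designs are supported only through the analytic `ap`
  accepting an external event rate; there is no inverse-probability
  weighting.
* Net benefit is provided as a single operating-point formula
  `NB = π·TPR − (1−π)·FPR·p_t/(1−p_t)`, not a decision-curve analysis.
* The strict upper tail (α within ~1e−2 of 1) of `F0(q_α)` comparisons
  can invert for scores whose event spread differs: dominance claims are
  only meaningful away from the degenerate corner where both CDFs are
  within ~1e−11 of one.
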