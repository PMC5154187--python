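# Methods

## Model

For two binary exposures X and Z and a binary outcome observed over a fixed
follow-up interval with complete follow-up, the sufficient-component cause
model distinguishes nine classes of sufficient causes: U1 (no exposure
requirement), U2/U3 (require X = 1 / X = 0), U4/U5 (require Z = 1 / Z = 0),
and the interaction classes U6–U9 requiring (x, z) = (1,1), (1,0), (0,1),
(0,0) respectively. Class i has completion risk rᵢ ∈ [0, 1) — the
probability that its unknown complementary components are completed during
follow-up — and completion peril Qᵢ = 1/(1 − rᵢ).

Treating class completions as mutually independent events (our
operationalisation of the no-redundancy assumption; it is the generative
reading under which the decomposition below is exact), the survival
probability of a cell is the product of (1 − rᵢ) over the four classes
applicable in that cell, equivalently

log Peril(x, z) = Σ log Qᵢ over applicable classes,

which is the linear predictor of a binomial GLM with link
g(μ) = −log(1 − μ). In the saturated 2×2 parameterisation
η = β₀ + β₁x + β₂z + β₃xz:

- β₀ = log Q₁ + log Q₃ + log Q₅ + log Q₉ (reference-cell log peril),
- β₁ = log Q₂ + log Q₇ − log Q₃ − log Q₉ (log peril ratio for X),
- β₂ = log Q₄ + log Q₈ − log Q₅ − log Q₉ (log peril ratio for Z),
- β₃ = log Q₆ + log Q₉ − log Q₇ − log Q₈ = log PRISM.

Only these four sums are identifiable from a 2×2 cohort; individual class
perils are not. β₃ ≠ 0 implies at least one interaction class is present,
which is what the PRISM test asserts on rejection. The class labelling
inside the X-only/Z-only/interaction groups is a convention; any labelling
satisfying the four cell sums is observationally identical.
`true_betas_from_spec` computes the coefficients directly from the log
completion perils, so absent classes contribute exactly zero; the
cell-contrast route through `CellRiskSet` agrees to numerical precision.

## Fitting

Maximum likelihood by Fisher scoring (IRLS) with working weight
n(1 − μ)/μ per grouped row. The link maps (0, 1) to (0, ∞), so every
linear predictor must stay strictly positive; this is handled by:

- **Initialisation**: empirical cell log perils with a (y + 0.5)/(n + 1)
  continuity correction, projected onto the design by least squares; if
  that start is infeasible, fall back to the intercept-only start
  β₀ = −log(1 − pooled risk), which is always feasible.
- **Step-halving**: a proposed update that drives any η ≤ 0 or increases
  the negative log-likelihood is halved toward the current iterate, up to
  50 times. Accepted iterations therefore never increase the negative
  log-likelihood.
- **Convergence**: max |Δβ| < 1e-8 and relative deviance change < 1e-10,
  within 100 iterations; a stalled iterate is still flagged converged if
  the gradient max-norm is below 1e-6. Non-convergence is reported in the
  result (`converged=False` with a message), never raised.

The stored negative log-likelihood is the kernel (binomial coefficients
dropped), making it invariant to grouped vs individual representation, so
likelihood-ratio statistics 2·(nll_reduced − nll_full) are identical either
way. The covariance is the inverse expected information at the estimate.

Cells with cases = n have infinite log peril; the fitter refuses them with
an error naming the cell rather than silently correcting
(`allow_boundary=True` overrides). Rank-deficient designs are rejected at
fit time as collinear.

**Prediction.** The raw inverse link 1 − exp(−η̂) can be negative for
profiles outside the convex hull of the fitted data. The default
prediction clamps the linear predictor at zero, 1 − exp(−max(0, η̂)),
guaranteeing a value in [0, 1); the clamping event is logged. The clamp at
zero is this package's design choice for out-of-hull prediction.

## Inference

- 95% intervals use the normal quantile 1.959964; transformed intervals
  exp(−β) swap endpoints (exp is decreasing in −β).
- The PRISM test is the Wald test of the cross-product coefficient; with a
  multi-level interaction block it is the joint Wald chi-square on the
  coefficient subvector (df = number of terms), chosen over per-term
  Bonferroni; per-term CIs are also reported.
- `reri(v11, v10, v01)` computes v₁₁ − v₁₀ − v₀₁ + 1 on any ratio scale.
  Two null thresholds are in circulation: 0 (the conventional additivity
  null, our default for the standalone function) and 1 (the stringent
  threshold that makes the RERI test specific to the (1,1) interaction
  class and explains its lower power). Both are exposed; the simulator's
  comparator defaults to threshold 1 because that is the test whose power
  the PRISM test is claimed to dominate.
- `gamma_from_beta` maps to the rare-disease linear-odds scale
  γᵢ = βᵢ/β₀ (excess odds ratios); it refuses β₀ ≤ 0, where the
  approximation is meaningless.

## Simulator

`simulate_cohort` draws exposure cells multinomially (default uniform 1/4
per cell) and cases binomially with the cell risks implied by the
generative spec — a fixed-interval, fully-followed cohort with no loss to
follow-up, competing risks, confounding, or measurement error. Passing
tests on these data therefore validate the estimator and tests *under the
model's own assumptions*; they say nothing about censoring, selection bias
or exposure misclassification in real cohorts, which are out of scope.

Randomness discipline: one root seed; per-replicate generators are spawned
from `numpy.random.SeedSequence`, so any replicate is reproducible in
isolation and studies are bit-reproducible.

`rejection_rate_study` fits the saturated 2×2 model per replicate and runs
the PRISM and/or RERI tests at level α. Replicates whose fit fails
(boundary cell, empty cell, non-convergence) are counted and excluded from
the denominator, with a warning above 1% failures. The RERI comparator
uses empirical risk ratios with a delta-method standard error assembled
from the log-RR covariances (the three ratios share the reference-cell
denominator) and a 0.5 continuity correction when any cell has zero cases.

Study sizes are desk-scale by choice: the recovery study uses 500
replicates of n = 20 000; size and power studies use n = 5000 with 2000
and 500 replicates respectively. Completion risks in the default study
specs (background 0.02–0.10, interaction classes 0.04–0.10) give cell
risks of a few percent — typical of cohort outcomes such as incident
hypertension — so Wald inference is comfortably in its asymptotic regime.

## Numerical choices

- Risks at or above 1 − 1e-12 are clipped before log transforms, with a
  RuntimeWarning.
- The likelihood kernel treats 0·log 0 as 0 at boundary counts.
- p-values below the printing resolution are reported as e.g. "<0.0001";
  printed numbers round half-even at 4 decimals by default.
- Levels of a categorical exposure are sorted ascending when numeric
  (making 0 the reference under 0/1 coding) and taken in order of first
  appearance otherwise; the reference is the first level.

## Known limitations

- No censored follow-up or competing risks; the model requires complete
  follow-up over a fixed interval.
- Confounding control is limited to covariates entered in the linear
  predictor.
- Tests for *individually specified* interaction classes (rather than the
  presence of any) are not implemented.
- Case-control data are supported only through the rare-disease odds
  mapping; the model does not apply to case-control studies of common
  diseases.
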