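# Methods

## Data model and eligibility

The unit of analysis is a singleton delivery, keyed by an opaque
`mother_id` and a within-mother `birth_index` (contiguous from 1).
Eligibility filters run in a fixed order — records missing a mother
identifier, multiple gestations, then records of unknown plurality — and
the survivor count plus per-step tallies are reported, mirroring the usual
cohort flow chart. Gestational age is accepted only inside a plausibility
window of [20, 45] completed weeks; this window is the package's own choice
(registry practice varies and no canonical bound exists), and values
outside it are rejected rather than truncated so that coding errors surface
at load.

Preterm birth is gestational age < 37 completed weeks; perinatal death is a
recorded binary; the co-occurrence outcome maps the pair to {0 = neither,
1 = both, 2 = death only, 3 = preterm only}, with missingness in either
component propagating. Two maternal-age partitions coexist in registry
practice (a pooled 25–34 group for description, a split 25–29/30–34 with
25–29 as modelling reference); the code books accept both, and the
modelling partition is the default because odds ratios are reported against
it. Category code books are closed sets: an unrecognised string is an
error, never silently coerced.

Deliveries can have exactly one of the two outcomes observed (gestational
age is the more frequently missing field). Such records are retained; in
the joint likelihood they contribute only the observed outcome's factor.
This reconciles unequal per-outcome denominators within a single fit; a
`complete_case` switch restricts to doubly observed deliveries for strict
complete-case runs.

## Models

Let `Y_1ik`, `Y_2ik` be preterm birth and perinatal death for delivery `k`
of mother `i`. All four variants assume conditional independence of all
factors given the mother's random effect, so the per-mother marginal
likelihood is a single integral over the random-effects density:

```
L_i(theta) = Int [ prod_{j,k observed} f(y_jik | b_i) ] phi(b_i; 0, D) db_i
```

- Bivariate shared: scalar `b_i`, entering both logit predictors with
  coefficient 1; `psi = log sigma`.
- Bivariate correlated: `b_i = (b_i1, b_i2) ~ N(0, D)`, outcome `j` loads
  on component `j`. `D` is parameterised by its Cholesky factor with
  logged diagonal (log-Cholesky), making the parameter space unconstrained
  and `D` positive semi-definite by construction. An optional
  equal-variance constraint (`D = sigma^2 [[1, rho], [rho, 1]]`,
  `psi = (log sigma, atanh rho)`) is provided because registry fits of this
  kind sometimes report a common variance for both outcomes; the free
  parameterisation is the default.
- Multinomial shared / separate-correlated: three non-reference category
  logits against "neither event", with one scalar `b_i` shared across the
  logits, or `b_i in R^3 ~ N(0, D)` with category `c` loading on component
  `c`.

A note on the likelihood's structure: with outcomes conditionally
independent given `b_i`, the product over outcomes and deliveries belongs
*inside* the per-mother integral; writing the integral per outcome would
make the outcomes marginally independent and defeat the purpose of the
shared parameter. The implementation integrates the full per-mother
product.

## Numerical integration

Gauss–Hermite quadrature in probabilist normalisation (weights sum to 1
against the standard normal kernel), tensorised per dimension for d = 2, 3.
Adaptive integration recentres the rule at each cluster's posterior mode
`m_i = argmax log f(y_i | b) phi(b; 0, D)` with scale from the inverse
Cholesky of the curvature there — the standard construction in mixed-model
software. Modes are found by a damped Newton iteration vectorised across
clusters (gradient tolerance 1e-8, at most 50 steps, step-halving
safeguard), warm-started from the previous likelihood evaluation, and
refreshed at every evaluation so the likelihood is a deterministic function
of theta. All quadrature weights are carried in log space and per-cluster
integrals accumulate via log-sum-exp, so large clusters cannot underflow.

Default order: 10 points per dimension (so 100 nodes at d = 2, 1000 at
d = 3). The order is configurable; the scaled comparison study fits the
d = 3 model at 4 points per dimension, which changes the fitted BIC by less
than 0.1 on those data while cutting cost ~15-fold. Validation: on
randomized small clusters of every variant, the adaptive 10-point rule
agrees with dense trapezoid tensor grids (201 points per dimension for
d <= 2, 41 for d = 3, over ±8 SD) to better than 1e-5 relative — typically
1e-7 — and degenerate limits close exactly: variance → 0 reduces every
joint likelihood to its fixed-effects counterpart, and a rank-one
(perfectly correlated) D reproduces the shared-scalar model.

## Estimation, inference, model comparison

Quasi-Newton (L-BFGS-B) maximisation over the encoded theta. Starting
values are deterministic: outcome-wise logistic (or plain multinomial)
fits for the fixed effects and log-SD = log 0.3 for variance parameters,
so refitting identical data is bit-for-bit reproducible. Box bounds keep
the search in a numerically safe region: |beta| <= 30, random-effect SDs in
[e^-8, e^1.5 ≈ 4.5]. The upper variance bound (~20) sits an order of
magnitude above any plausible mother-level heterogeneity for these
outcomes; beyond it, fixed-order quadrature of near-saturated clusters
degrades and can spuriously inflate the approximate likelihood, so the
bound is a guard rail, not a scientific constraint. Convergence requires
the optimizer's relative function-change and projected-gradient criteria
(1e-10 / 1e-5); non-convergence is flagged on the result, not raised, and
|beta| escaping 15 triggers a separation warning naming the coefficient.

Standard errors come from the inverse observed information (central finite
differences of the log-likelihood, relative step 1e-5, symmetrised), and
cluster-robust variances from the sandwich `A^-1 B A^-1` with `B` the sum
of per-mother score outer products (scores by central differences of
per-cluster contributions) and a `G/(G-1)` small-sample factor. Wald
intervals use z = 1.959964; odds-ratio tables print at two decimals with
significance stars at 0.05/0.01/0.001. BIC uses N = number of delivery
records in the fit; the alternative N = number of mothers is a documented
ambiguity for clustered data — the package reports record-count N because
the structures being compared share the same records, so the choice cannot
flip a comparison between them.

## Synthetic registry generator

The generator emulates the data-generating process the models assume,
at the scale of a large referral-hospital registry: deliveries per mother
on {1..4} with mean ~1.34 (matching ~60,800 deliveries from ~45,300
mothers), calendar years 2000–2017 with logit-linear trends (+0.04/yr for
preterm, −0.03/yr for death, i.e. odds ratios 1.04 and 0.97 per year),
covariate marginals loosely matching published registry tables (e.g. 31%
with <4 ANC visits), shared random-intercept variance 0.18, and missingness
rates (12% for gestational age, 0.3% for perinatal status) that reproduce
the unequal per-outcome denominators of real registries. The default
coefficient preset echoes the direction and rough magnitude of published
joint-model estimates (strong adverse effect of inadequate ANC on preterm
birth, protective adolescent-age effect on death) but is not a copy of any
fitted table. Intercepts were set so the marginal prevalences land near
13% (preterm) and 4–5% (death).

Covariates are drawn independently of each other and of the random effect.
The fitted models condition on covariates, so independence is sufficient
for parameter-recovery and coverage testing; it does mean the generator
under-represents real-data features such as confounding among exposures,
within-mother covariate evolution across pregnancies, and outcome-dependent
missingness. Passing tests therefore demonstrate correctness of the
estimation machinery under the assumed model, not robustness to those
violations. A multinomial outcome mode draws the four-category outcome
directly from the random-effects multinomial model (the binary outcomes are
then derived from the category), which is what the BIC structure-selection
study simulates from.

Randomness flows through named substreams spawned from the single seed,
with covariate streams keyed by a CRC of the covariate name, so adding a
covariate to a configuration leaves the outcome draws of the existing
columns unchanged.

## Descriptive layer

Chi-square tests on the stratum × outcome contingency tables are
deliberately naive to mother-level clustering — that is how registry
descriptive tables are conventionally produced, and the model layer is
where clustering is handled. No continuity correction by default (the
tables are large-sample); a flag enables it. Annual trends regress the
unweighted per-year percentage on calendar year by OLS, one point per
year, so the slope reads in percentage points per year; the reported
interval is the normal-theory ±1.96·SE band. Percentages print at one
decimal; full precision is kept internally.

## Validation studies and problem sizes

- Oracle equivalence: 24 randomized clusters (six per model variant, 1–5
  deliveries each), adaptive 10-point rule vs dense grids; threshold 1e-5
  relative.
- Recovery: 20 replicates × 2,000 mothers (deliveries 1–3, sigma^2 = 0.5,
  three binary covariates of which three coefficients are truly zero),
  refit with the generating model; per-coefficient mean bias below 0.05 and
  ≥90% Wald coverage of the null coefficients.
- Structure selection: 10 replicates × 2,000 mothers simulated from the
  shared-effect multinomial model; shared (Q = 10) and separate-correlated
  (Q = 4 per dimension) fits compared by BIC, expecting the generating
  structure to win in at least 8.

These sizes were chosen as the smallest at which the Monte-Carlo noise of
the checks is comfortably below their thresholds; they complete in minutes
on a single core.

## Known limitations

- Finite-difference information matrices cost O(p^2) likelihood
  evaluations; for the covariate-rich fits practitioners run on full
  registries an analytic-gradient implementation would be preferable.
- Dimensions above 3 (e.g. random slopes) and sparse-grid quadrature are
  out of scope; the d = 3 tensor grid is the practical ceiling.
- BIC for clustered random-effects models is a blunt instrument; the
  conditional AIC literature argues for effective-degrees-of-freedom
  penalties, which are not implemented here.
- The chi-square layer inherits the usual caveat that it ignores
  clustering; its p-values are anti-conservative for mother-level
  exposures.
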