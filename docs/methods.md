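# Methods

## The problem

In settings where fertility above the two-child ideal is concentrated among
poorer households, the policy question is not only *how much* inequality
there is but *where it comes from*: individual circumstances (education,
early marriage, child loss, unmet need for contraception) or the character
of the areas women live in (gender norms, environmental development,
health-system reach).  This package measures wealth-based inequality in
**3+ parity** — the number of living children a woman has beyond her first
two — and decomposes it over a multilevel model so that individual-level,
area-level and per-area random-effect contributions are separated exactly.

## Outcome and analytic sample

The outcome `outcome_parity3plus` is the count of living children beyond
the first two for women aged 30 and older with at least two living
children.  The age-30 floor gives women time to have had their first two
children and to have acted on any plans for more; the filter
(`filter_model_sample`) keeps exactly the records with `age_years >= 30`
and `n_living_children >= 2`.  Area contextual scales, by contrast, are
computed from **all** ever-married women aged 15–49 in each area — two
distinct input tables, merged by `area_id`.

By default the synthetic outcome is a real-valued linear-model response
rather than a rounded count.  A linear outcome keeps every identity of the
decomposition exact, which is what the test suite leans on; a `count_mode`
exists for realism (outcome rounded and truncated at zero,
`n_living_children = outcome + 2`) but is excluded from identity-based
tests because truncation breaks the linear-model algebra.

## Concentration index

For woman *i* with outcome `h_i`, sampling weight `w_i` and weighted
fractional wealth rank `r_i`,

    CI = 2 * cov_w(h, r) / mu,

with `mu` the weighted mean of `h` and `cov_w` the total-weight-normalized
covariance.  Ranks are midpoints of each record's weight interval after
sorting by wealth score; tied scores share the rank at the midpoint of the
tie group's pooled weight (the standard convention — the data source is
silent on ties), which makes the weighted mean of ranks exactly 0.5.
CI is negative when the outcome is concentrated among the poor.  The
generalized index `GC = 2 * cov_w(v, r)` (no division by the mean) handles
zero-mean variables, i.e. regression residuals.

The CI's uncertainty is estimated by a case bootstrap: records are
resampled with replacement keeping their weights, ranks are recomputed
within each resample, and a percentile interval is read off.  The interval
construction is this package's choice; no method is attached to the
published interval it emulates.  Resamples with a zero-mean outcome are
skipped and counted.

## Multilevel model

The outcome for woman *i* in area *j* follows

    Y_ij = g00 + sum_p g_p0 X_pij + sum_q g_q0 Z_qj
           + U_0j + U_1j * EM_ij + e_ij,

where `X_pij` are the seven individual attributes (three age dummies with
30–34 as reference, less-than-secondary education for the woman and her
husband, no modern toilet, marriage before 18 (`EM`), child death, unmet
need), `Z_qj` are the three area lowest-quartile flags, `U_0j ~ N(0, tau00)`
is the area random intercept, `U_1j ~ N(0, tau11)` the area random slope on
early marriage, and `e_ij ~ N(0, sigma2)`.  Cross-level interaction terms
are out of scope.  Four nested specifications are fitted: null, +individual,
+area, +random slope.

Estimation is REML via `statsmodels` MixedLM (ML available for
fixed-effect likelihood-ratio tests).  The random intercept and slope are
independent by default — the fitted models report two variances and no
covariance — with a correlated option.  The optimizer falls back from BFGS
to Powell to CG; a fit whose restricted log-likelihood is non-finite (which
MixedLM can produce when the intercept variance collapses to the boundary)
is treated as a failure and retried, and a genuine zero-variance solution is
returned with a `boundary` flag.

BLUPs are computed directly from the mixed-model equations,
`U_j = (Z_j'Z_j/sigma2 + G^-1)^-1 Z_j' (y_j - X_j b) / sigma2` with
`G = diag(tau00, tau11)`; they agree with MixedLM's posterior means to
~1e-14 and remain defined at the variance boundary (a zero-variance
component has BLUP 0).  Residuals are defined as
`y - fixed part - random part`, so the per-record identity is exact by
construction.

Diagnostics follow the conventional arithmetic: ICC
`tau00 / (tau00 + sigma2)` (intercept-only convention — the random-slope
variance is excluded, so under the slope model this is the ICC at the
reference, not-early-married profile, the convention that reproduces the
published nested-model cells); percent of level-2 variance explained
`(tau00_null - tau00) / tau00_null * 100`; deviance difference
`-2 * (llf_a - llf_b)` between fits of the same estimation mode.

Sampling weights enter all descriptive statistics, ranks and concentration
computations.  The default model fit is unweighted (how weights entered the
published fit is unstated); a frequency-style weighted option replicates
rows by their rounded normalized weight.

## Decomposition

Writing the fitted model as `y = Xb + Zu + e`, the CI of the observed
outcome splits exactly:

    CI(y) = sum_k eta_k C_k  +  sum_j eta_0j C_0j + sum_j eta_1j C_1j
            + GC_e / mu,

where for each fixed covariate `eta_k = b_k * xbar_k / mu` (the
elasticity) and `C_k` its weighted CI; for each area the random intercept
BLUP acts as a coefficient on the area-membership indicator `D_j`
(`xbar` = the area's weighted population share) and the slope BLUP on
`D_j * EM`.  Two denominator conventions matter and are deliberate:

* `mu` in every elasticity is the weighted mean of the **observed**
  outcome — the convention that reproduces the published elasticities;
* percent contributions divide by `CI_hat = sum of all contributions`
  (the CI of the full predicted outcome, random parts included).

The intercept carries no inequality (`cov(const, r) = 0`) and is omitted.
Closure `CI(y) = sum contributions + GC_e/mu` is asserted to 1e-10 inside
`assemble_table`; a violation raises rather than reporting an inconsistent
table.  All intermediates are carried at full precision; rounding happens
only at report time.  Because published tables round intermediates, the
worked-example tests compare percent cells at ±0.1 points.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular survey's microdata:

* **47 areas** (governorate × urban/rural in the emulated setting), with
  per-area sizes drawn uniformly from 150–750 so area population shares
  vary realistically (metropolitan areas dominate); about 21,000 women
  15–49 of whom ~12,000 pass the analytic filter.
* **Wealth**: `wealth_score = N(0, 0.8) area mean + N(0, 0.8) within-area`,
  i.e. roughly half the wealth variance is between areas — a strong
  regional wealth divide.  Ranks are weighted fractional ranks of the
  score, so generated gradients translate directly into concentration
  indices.
* **Covariates**: each binary covariate is Bernoulli with probability
  `logit^-1(a_k + b_k * rank)`.  `calibrate_logit` inverts the map from
  `(a_k, b_k)` to (prevalence, CI) under a uniform rank, so the defaults
  are stated directly as target prevalences and concentration indices
  patterned on the emulated survey's analytic sample (e.g. early marriage:
  prevalence 0.287, CI −0.272).  Negative `b_k` concentrates an attribute
  among the poor.
* **Scale indicators**: the twelve indicators behind the three area scales
  are generated the same way; indicators that are complements of model
  covariates (early marriage, education, toilet) are derived, never drawn
  twice.  Scale-only indicators additionally carry a per-area logit offset
  shared across their scale (sd 0.5, plus half-sd indicator texture):
  areas differ idiosyncratically in gender norms and health-system reach
  beyond what wealth predicts.  Without this, all three scales would be
  monotone in area wealth and their lowest-quartile flags collinear —
  a degenerate design no survey exhibits.
* **Outcome**: built from the model equation with the fixed effects,
  `tau00 = 0.032`, `tau11 = 0.067`, `sigma2 = 1.237` of the full published
  specification as defaults, using the generator's own computed area flags,
  so the generated data carry complete ground truth (realized `U_0j`,
  `U_1j` are retained for recovery tests).
* **Weights**: log-normal with sd 0.3 on the log scale, normalized to mean
  one — normalized survey weights with mild dispersion.
* Age is 18–49 with 62% aged 30+ and the 30+ age-group mix
  (0.299/0.270/0.221/0.210); 91.5% of 30+ women have two or more living
  children, so the filter retains ~57% of the population, matching the
  emulated survey's analytic-sample fraction.  `all_eligible=True`
  generates only filter-passing women (used for exact-size recovery
  studies).  A `marriage_duration_years` column is generated for
  completeness but no default model includes it.

What the generator does **not** emulate: multi-stage cluster sampling and
design effects, non-response, item missingness, spatial correlation between
neighboring areas, and any non-linearity of the outcome in its
determinants.  Passing tests therefore demonstrate the correctness of the
estimators and identities under the model's own assumptions — not that the
linear multilevel model is adequate for any particular real survey.

## Numerical and design choices

* Quartile flags use the linear-interpolation 25th percentile across the
  (unweighted) area values; with 47 areas the 12 lowest are flagged.
  Boundary ties fall in the lowest quartile.  Flags are invariant to
  monotone transforms of the scales.
* Per-area proportions are weight-weighted by default (all published
  analysis is weighted); an unweighted option exists since the source is
  silent for this step.
* Areas with one woman are retained; their BLUPs shrink toward zero.
* Degenerate inputs: empty samples, non-positive weights, fewer than four
  areas, zero-mean outcomes, and closure violations all raise typed errors;
  the CLI maps them to distinct exit codes (2 config, 3 schema,
  4 convergence, 5 closure).
* Parameter recovery is checked at 47 areas × 250 women over three fixed
  seeds, comparing the **mean** estimate across seeds with the generating
  values (coefficient within ±0.05, variance components within 30%
  relative error).  With `tau11 = 0.067` and 47 areas the sampling sd of
  the early-marriage coefficient is ≈ 0.04, so single-seed comparisons at
  that tolerance would reflect seed luck rather than estimator quality;
  averaging three seeds is the meaningful recovery check at this design
  size.
* Problem sizes in the test suite: most tests run on 16–20 areas with
  60–120 women per area; study-scale checks (47 areas, ~12,000 women) run
  once as session fixtures and in the end-to-end test.  The full default
  pipeline completes in a few seconds.

## Known limitations

* The bootstrap CI resamples records independently, ignoring the clustered
  design; with 47 areas a cluster bootstrap would be noisy, but intervals
  here are best read as descriptive.
* MixedLM's REML variance estimates at small `tau00` are boundary-prone;
  the package surfaces a `boundary` flag rather than testing variances
  against zero.
* The decomposition attributes inequality through a linear model; if the
  real outcome process is non-linear in wealth-graded determinants, the
  residual term absorbs the discrepancy and tier shares shift accordingly.
* `count_mode` outcomes break the exact identities by construction
  (truncation); decomposition on counts is approximate and reported as
  such.
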