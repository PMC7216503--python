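# parityineq

Wealth-based inequality in **3+ parity** — the number of living children a
woman has beyond her first two — measured with the concentration index and
decomposed over a random-slope linear multilevel model.  The package is for
demographers and health-equity analysts who want to split an outcome's
socioeconomic inequality into the parts carried by individual attributes,
by area-level context, and by each area's own random effect.

## What it computes

For woman *i* in area *j* with sampling weight *w*, wealth rank *r* and
outcome *h*, the concentration index is

    CI = (2 / μ) cov_w(h, r),       μ = weighted mean of h,

negative when the outcome is concentrated among the poor.  A multilevel
model

    Y_ij = γ00 + Σ_p γ_p0 X_pij + Σ_q γ_q0 Z_qj + U_0j + U_1j·EM_ij + e_ij

(individual attributes X, area lowest-quartile context flags Z, random
intercept U_0j and random slope U_1j on early marriage EM) yields an exact
decomposition

    CI = Σ_k η_k C_k + Σ_j η_0j C_0j + Σ_j η_1j C_1j + GC_e / μ,

where η_k = β_k·x̄_k/μ is each determinant's elasticity, C_k its own
concentration index, each area's BLUP acts as a coefficient on its
membership indicator, and GC_e/μ is the residual term.  The package checks
the closure identity to 1e-10 on every run and refuses to report an
inconsistent table.

A synthetic-data module generates DHS-style hierarchical survey populations
(women nested in 47 areas, weights, wealth-graded covariates, area
contextual scales, known random effects) so the whole chain is testable
without restricted survey microdata.

## Worked example

```
$ parityineq run --seed 3 --out results
```

or, step by step, the numbered scripts under `analysis/`:

```
$ python analysis/01_simulate.py --seed 1 --out results/data
generated 20212 women in 47 areas; 11321 enter the 30+/2-children model sample

$ python analysis/03_fit_models.py --data results/data --out results
  model1_null: tau00=0.1700 icc=10.4% loglik=-18290.3
  model2_individual: tau00=0.1093 icc=8.1% loglik=-17396.9
  model3_area: tau00=0.0280 icc=2.2% loglik=-17372.8
  model4_random_slope: tau00=0.0231 icc=1.8% loglik=-17346.7
level-2 variance explained by the full model: 86.4%
deviance drop from the early-marriage random slope: 52.0
early-marriage coefficient: 0.637 (se 0.042)

$ python analysis/04_decompose.py --data results/data --out results
observed CI of 3+ parity: -0.1165 (bootstrap 95% CI -0.1258 to -0.1073)
predicted CI: -0.1146 (98.3% of observed)
tier shares of the predicted CI:
  individual: 61.5%
  area: 38.3%
  random_intercept: 3.5%
  random_slope: -3.3%
closure check |CI_obs - (sum + residual)| = 1.39e-17
```

Reading the output: 3+ parity is concentrated among poorer women
(CI ≈ −0.12).  The nested models show the area clustering of the outcome
(ICC 10.4% in the null model) being absorbed almost entirely by the
individual attributes and the three area context flags (86% of level-2
variance explained), with strong evidence that the early-marriage effect
varies across areas (deviance drop 52 for one extra variance parameter).
The decomposition attributes ~61% of the predicted inequality to
individual attributes — early marriage alone carries about a quarter — and
~38% to the area flags, with small per-area random-effect contributions
that identify which specific areas push inequality up or down.

`analysis/02_area_scales.py` builds the three per-area contextual scales
(gendered context, environmental development, health-system performance)
from the full ever-married 15–49 sample, and `05_descriptives.py` writes
the weighted descriptive tables.  See `docs/methods.md` for the model,
conventions and generator details.

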