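"""Random-intercept / random-slope linear multilevel models of 3+ parity.

Fits the nested sequence used throughout the analysis:

1. null (intercept + area random intercept);
2. + individual covariates;
3. + area lowest-quartile flags;
4. + a random slope on early marriage (independent of the intercept).

Estimation is REML by default (ML available for fixed-effect likelihood
ratio tests) via ``statsmodels`` MixedLM.  Diagnostics follow the usual
variance-component arithmetic: the intra-class correlation
``tau00 / (tau00 + sigma2)`` (intercept-only convention, the random-slope
variance excluded), the proportion of level-2 variance explained relative
to a null fit, and deviance differences ``-2 * (llf_a - llf_b)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .synthetic import AREA_COVARIATES, MODEL_COVARIATES

__all__ = [
    "ModelSpec",
    "MixedFit",
    "NonConvergenceError",
    "nested_model_specs",
    "fit_model",
    "icc",
    "level2_explained",
    "compare_deviance",
]

_BOUNDARY_TOL = 1e-8


class NonConvergenceError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one multilevel linear model."""

    outcome: str = "outcome_parity3plus"
    individual_covariates: tuple[str, ...] = ()
    area_covariates: tuple[str, ...] = ()
    random_slope: str | None = None
    estimation: str = "reml"                 # "reml" or "ml"
    re_covariance: str = "diagonal"          # "diagonal" or "correlated"
    weights: str = "none"                    # "none" or "frequency"
    name: str = "model"

    def __post_init__(self):
        if self.random_slope is not None and (
                self.random_slope not in self.individual_covariates):
            raise ValueError(
                "random_slope must be one of the individual covariates")
        if self.estimation not in ("reml", "ml"):
            raise ValueError("estimation must be 'reml' or 'ml'")
        if self.re_covariance not in ("diagonal", "correlated"):
            raise ValueError("re_covariance must be 'diagonal' or 'correlated'")
        if self.weights not in ("none", "frequency"):
            raise ValueError("weights must be 'none' or 'frequency'")

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.individual_covariates) + tuple(self.area_covariates)

    def formula(self) -> str:
        rhs = " + ".join(self.covariates) if self.covariates else "1"
        return f"{self.outcome} ~ {rhs}"


def nested_model_specs(random_slope: str = "married_lt18",
                       individual: tuple[str, ...] | None = None,
                       area: tuple[str, ...] | None = None,
                       estimation: str = "reml") -> list[ModelSpec]:
    """The four nested specifications, null through full random-slope."""
    ind = tuple(individual) if individual is not None else tuple(MODEL_COVARIATES)
    ar = tuple(area) if area is not None else tuple(AREA_COVARIATES)
    return [
        ModelSpec(name="model1_null", estimation=estimation),
        ModelSpec(name="model2_individual", individual_covariates=ind,
                  estimation=estimation),
        ModelSpec(name="model3_area", individual_covariates=ind,
                  area_covariates=ar, estimation=estimation),
        ModelSpec(name="model4_random_slope", individual_covariates=ind,
                  area_covariates=ar, random_slope=random_slope,
                  estimation=estimation),
    ]


@dataclass
class MixedFit:
    """A fitted multilevel model, unpacked for downstream decomposition."""

    spec: ModelSpec
    fixed: pd.Series                 # coefficients, "intercept" first
    fixed_se: pd.Series
    tau00: float                     # level-2 intercept variance
    tau11: float                     # random-slope variance (0 if absent)
    sigma2: float                    # level-1 residual variance
    loglik: float                    # restricted (REML) or full (ML)
    converged: bool
    boundary: bool                   # level-2 variance estimated at ~0
    blup_intercepts: pd.Series       # predicted U_0j per area
    blup_slopes: pd.Series           # predicted U_1j per area (0 if absent)
    fitted_fixed: np.ndarray         # per-record fixed part (incl. intercept)
    fitted_random: np.ndarray        # per-record U_0j + U_1j * slope covariate
    residuals: np.ndarray            # outcome - fixed - random, exactly
    index: pd.Index = field(repr=False, default=None)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik


def _expand_frequency(data: pd.DataFrame) -> pd.DataFrame:
    reps = np.maximum(np.rint(data["weight"].to_numpy(float)), 1).astype(int)
    return data.loc[data.index.repeat(reps)]


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> MixedFit:
    """Fit ``spec`` on the model sample and unpack the result.

    ``data`` needs the outcome, covariates, ``area_id`` and (for the
    frequency-weight option) ``weight``.  Raises
    :class:`NonConvergenceError` if the optimizer fails; a level-2 variance
    estimated at the zero boundary is returned with ``boundary=True``.
    """
    if data["area_id"].nunique() < 2:
        raise ValueError("multilevel fit requires at least 2 areas")
    missing = [c for c in (spec.outcome, *spec.covariates, "area_id")
               if c not in data.columns]
    if missing:
        raise KeyError(f"model data is missing columns: {missing}")

    fit_data = _expand_frequency(data) if spec.weights == "frequency" else data

    vc, re_formula = None, "1"
    if spec.random_slope is not None:
        if spec.re_covariance == "diagonal":
            vc = {"slope": f"0 + {spec.random_slope}"}
        else:
            re_formula = f"1 + {spec.random_slope}"

    model = smf.mixedlm(spec.formula(), fit_data, groups=fit_data["area_id"],
                        re_formula=re_formula, vc_formula=vc)
    res, failures = None, []
    for method in (None, "powell", "cg"):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                cand = model.fit(reml=(spec.estimation == "reml"),
                                 method=method)
            except np.linalg.LinAlgError as err:
                failures.append(f"{method or 'bfgs'}: {err}")
                continue
        if bool(getattr(cand, "converged", True)) and np.isfinite(cand.llf):
            res = cand
            break
        failures.append(f"{method or 'bfgs'}: " + ("; ".join(
            str(w.message) for w in caught
            if issubclass(w.category, ConvergenceWarning))
            or f"non-finite log-likelihood ({cand.llf})"))
    if res is None:
        raise NonConvergenceError(
            f"{spec.name} did not converge ({'; '.join(failures)})")
    converged = True

    fe = res.fe_params.rename(index={"Intercept": "intercept"})
    se = res.bse_fe.rename(index={"Intercept": "intercept"})

    tau00 = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    if spec.random_slope is None:
        tau11 = 0.0
    elif spec.re_covariance == "diagonal":
        tau11 = float(res.vcomp[0])
    else:
        tau11 = float(np.asarray(res.cov_re)[1, 1])
    sigma2 = float(res.scale)

    exog = pd.DataFrame(
        {name: (np.ones(len(data)) if name == "intercept"
                else data[name].to_numpy(float)) for name in fe.index})
    fitted_fixed = exog.to_numpy() @ fe.to_numpy()

    # BLUPs from the mixed-model equations, U_j = (Z'Z/s2 + G^-1)^-1 Z'd/s2
    # with G = diag(tau00, tau11): exact posterior means, well defined even
    # when a variance sits on the zero boundary (that component's BLUP is 0).
    groups = pd.Index(sorted(data["area_id"].unique()), name="area_id")
    u0 = pd.Series(0.0, index=groups)
    u1 = pd.Series(0.0, index=groups)
    resid_fe = data[spec.outcome].to_numpy(float) - fitted_fixed
    slope_x = (data[spec.random_slope].to_numpy(float)
               if spec.random_slope is not None else None)
    active = [v for v, tau in (("i", tau00), ("s", tau11))
              if tau > _BOUNDARY_TOL and (v == "i" or slope_x is not None)]
    if active:
        gid = data["area_id"].to_numpy()
        for g in groups:
            sel = gid == g
            d = resid_fe[sel]
            cols = []
            taus = []
            if "i" in active:
                cols.append(np.ones(sel.sum()))
                taus.append(tau00)
            if "s" in active:
                cols.append(slope_x[sel])
                taus.append(tau11)
            z = np.column_stack(cols)
            lhs = z.T @ z / sigma2 + np.diag(1.0 / np.asarray(taus))
            sol = np.linalg.solve(lhs, z.T @ d / sigma2)
            k = 0
            if "i" in active:
                u0[g] = sol[k]
                k += 1
            if "s" in active:
                u1[g] = sol[k]
    aid = data["area_id"].to_numpy()
    fitted_random = u0.reindex(aid).to_numpy()
    if spec.random_slope is not None:
        fitted_random = fitted_random + (
            u1.reindex(aid).to_numpy() * data[spec.random_slope].to_numpy(float))
    outcome = data[spec.outcome].to_numpy(float)
    residuals = outcome - fitted_fixed - fitted_random

    return MixedFit(
        spec=spec, fixed=fe, fixed_se=se, tau00=tau00, tau11=tau11,
        sigma2=sigma2, loglik=float(res.llf), converged=converged,
        boundary=tau00 <= _BOUNDARY_TOL, blup_intercepts=u0, blup_slopes=u1,
        fitted_fixed=fitted_fixed, fitted_random=fitted_random,
        residuals=residuals, index=data.index)


def icc(fit: MixedFit) -> float:
    """Intra-class correlation tau00 / (tau00 + sigma2), as a proportion.

    Uses the intercept-only convention: the random-slope variance does not
    enter, so under a random-slope model this is the ICC for the
    reference (not early-married) covariate profile.
    """
    if isinstance(fit, MixedFit):
        tau00, sigma2 = fit.tau00, fit.sigma2
    else:  # (tau00, sigma2) pair, for worked-example arithmetic
        tau00, sigma2 = fit
    denom = tau00 + sigma2
    return 0.0 if tau00 == 0 else tau00 / denom


def level2_explained(fit_null: MixedFit | float, fit: MixedFit | float) -> float:
    """Percent of null-model level-2 variance explained by ``fit``."""
    t_null = fit_null.tau00 if isinstance(fit_null, MixedFit) else float(fit_null)
    t_fit = fit.tau00 if isinstance(fit, MixedFit) else float(fit)
    if t_null == 0:
        return 0.0
    return (t_null - t_fit) / t_null * 100.0


def compare_deviance(fit_a: MixedFit | float, fit_b: MixedFit | float) -> float:
    """Deviance difference ``-2 * (loglik_a - loglik_b)``.

    Positive when ``fit_b`` has the higher likelihood.  When comparing
    random-effect structures both fits should be REML with identical fixed
    effects; interpret against a boundary-corrected chi-square reference.
    """
    ll_a = fit_a.loglik if isinstance(fit_a, MixedFit) else float(fit_a)
    ll_b = fit_b.loglik if isinstance(fit_b, MixedFit) else float(fit_b)
    if isinstance(fit_a, MixedFit) and isinstance(fit_b, MixedFit):
        if fit_a.spec.estimation != fit_b.spec.estimation:
            raise ValueError("cannot compare fits across estimation modes")
    return -2.0 * (ll_a - ll_b)
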