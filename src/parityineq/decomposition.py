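"""Regression-based decomposition of the concentration index.

For a linear additive model ``h_i = alpha + sum_k beta_k x_ki + e_i`` the
concentration index of ``h`` splits exactly into determinant contributions
plus a residual::

    CI(h) = sum_k (beta_k * xbar_k / mu) * C_k  +  GC_e / mu

where ``mu`` is the weighted mean of the observed outcome, ``C_k`` the
concentration index of determinant ``k``, ``eta_k = beta_k * xbar_k / mu``
its elasticity, and ``GC_e`` the generalized concentration index of the
residuals.  Each determinant's percent contribution is its share of the
predicted-outcome concentration index ``CI_hat = sum_k eta_k C_k``.

With a multilevel model the predicted outcome carries a random part as
well: each area's predicted random intercept U_0j acts as a coefficient on
that area's membership indicator, and each predicted random slope U_1j as a
coefficient on (membership x early marriage).  Those per-area terms are
decomposed with the same elasticity formula, which partitions CI_hat into a
fixed-effect share and a per-area random-effect share while preserving the
exact closure identity above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concentration import (FractionalRanks, concentration_index,
                            generalized_concentration, weighted_mean)
from .multilevel import MixedFit

__all__ = [
    "DecompRow",
    "DecompTable",
    "ClosureError",
    "elasticity",
    "pct_contribution",
    "decompose_fixed",
    "decompose_random",
    "assemble_table",
    "rank_rows",
    "decompose",
]

CLOSURE_TOL = 1e-10

TIER_INDIVIDUAL = "individual"
TIER_AREA = "area"
TIER_RANDOM_INTERCEPT = "random_intercept"
TIER_RANDOM_SLOPE = "random_slope"


class ClosureError(AssertionError):
    """The exact decomposition identity failed beyond tolerance."""


@dataclass
class DecompRow:
    """One determinant's line of the decomposition table."""

    name: str
    tier: str
    beta: float          # fixed coefficient, or a BLUP for random tiers
    xbar: float          # weighted mean of the determinant
    elasticity: float    # beta * xbar / mu
    c_k: float           # concentration index of the determinant
    contribution: float  # elasticity * c_k
    pct: float | None = None  # contribution / CI_hat * 100


def elasticity(beta: float, xbar: float, mu: float) -> float:
    """Elasticity eta_k = beta_k * xbar_k / mu (mu = mean observed outcome)."""
    if mu == 0:
        raise ZeroDivisionError("elasticity undefined for zero mean outcome")
    return beta * xbar / mu


def pct_contribution(contribution: float, ci_hat: float) -> float:
    """A determinant's percent share of the predicted-outcome CI."""
    if ci_hat == 0:
        raise ZeroDivisionError(
            "% contribution undefined when the predicted CI is zero")
    return contribution / ci_hat * 100.0


def _covariate_row(name: str, tier: str, beta: float, x: np.ndarray,
                   ranks: FractionalRanks, weights: np.ndarray,
                   mu: float) -> DecompRow:
    xbar = weighted_mean(x, weights)
    if xbar == 0:
        # x is identically zero, so its covariance with rank — and hence its
        # exact contribution — is zero; closure is unaffected.
        if tier in (TIER_INDIVIDUAL, TIER_AREA):
            warnings.warn(f"determinant '{name}' has zero weighted mean; "
                          "its elasticity and contribution are zero")
        return DecompRow(name, tier, beta, 0.0, 0.0, 0.0, 0.0)
    c_k = concentration_index(x, ranks, weights).ci_value
    eta = elasticity(beta, xbar, mu)
    return DecompRow(name, tier, beta, xbar, eta, c_k, eta * c_k)


def decompose_fixed(fit: MixedFit, data: pd.DataFrame,
                    ranks: FractionalRanks,
                    weights: np.ndarray | None = None,
                    mu: float | None = None) -> list[DecompRow]:
    """Per-covariate rows for the fixed part of the model.

    One row per covariate dummy; the intercept carries no inequality
    (its concentration index is zero) and is omitted.  ``mu`` defaults to
    the weighted mean of the observed outcome in ``data``.
    """
    w = np.asarray(weights, float) if weights is not None else ranks.weights
    if mu is None:
        mu = weighted_mean(data[fit.spec.outcome].to_numpy(float), w)
    rows = []
    for name in fit.spec.individual_covariates:
        rows.append(_covariate_row(name, TIER_INDIVIDUAL, float(fit.fixed[name]),
                                   data[name].to_numpy(float), ranks, w, mu))
    for name in fit.spec.area_covariates:
        rows.append(_covariate_row(name, TIER_AREA, float(fit.fixed[name]),
                                   data[name].to_numpy(float), ranks, w, mu))
    return rows


def decompose_random(fit: MixedFit, data: pd.DataFrame,
                     ranks: FractionalRanks,
                     weights: np.ndarray | None = None,
                     mu: float | None = None) -> list[DecompRow]:
    """Per-area rows for the random part of the model.

    Each area j contributes a random-intercept row (BLUP U_0j on the area
    membership indicator) and, under a random slope, a random-slope row
    (BLUP U_1j on membership x slope covariate).
    """
    w = np.asarray(weights, float) if weights is not None else ranks.weights
    if mu is None:
        mu = weighted_mean(data[fit.spec.outcome].to_numpy(float), w)
    aid = data["area_id"].to_numpy()
    slope_x = (data[fit.spec.random_slope].to_numpy(float)
               if fit.spec.random_slope is not None else None)
    rows = []
    for area in fit.blup_intercepts.index:
        d_j = (aid == area).astype(float)
        rows.append(_covariate_row(f"area_{area}", TIER_RANDOM_INTERCEPT,
                                   float(fit.blup_intercepts[area]),
                                   d_j, ranks, w, mu))
        if slope_x is not None:
            rows.append(_covariate_row(
                f"area_{area}_x_{fit.spec.random_slope}", TIER_RANDOM_SLOPE,
                float(fit.blup_slopes[area]), d_j * slope_x, ranks, w, mu))
    return rows


@dataclass
class DecompTable:
    """The assembled decomposition with its closure diagnostics."""

    rows: list[DecompRow]
    mu: float                   # weighted mean of the observed outcome
    ci_observed: float          # CI of the observed outcome
    ci_hat: float               # sum of all contributions (predicted CI)
    ci_hat_fixed: float         # fixed-tier subtotal
    ci_hat_random: float        # random-tier subtotal
    residual_term: float        # GC_e / mu
    tier_totals: dict[str, float] = field(default_factory=dict)
    tier_pct: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"name": r.name, "tier": r.tier, "coef": r.beta,
              "average": r.xbar, "elasticity": r.elasticity, "CI": r.c_k,
              "contribution": r.contribution, "pct": r.pct}
             for r in self.rows])

    def summary(self) -> dict:
        return {
            "mu": self.mu,
            "ci_observed": self.ci_observed,
            "ci_hat": self.ci_hat,
            "ci_hat_fixed": self.ci_hat_fixed,
            "ci_hat_random": self.ci_hat_random,
            "residual_term": self.residual_term,
            "tier_totals": dict(self.tier_totals),
            "tier_pct": dict(self.tier_pct),
        }


def assemble_table(fixed_rows: list[DecompRow], random_rows: list[DecompRow],
                   observed: np.ndarray, ranks: FractionalRanks,
                   weights: np.ndarray | None = None,
                   predicted: np.ndarray | None = None,
                   tol: float = CLOSURE_TOL) -> DecompTable:
    """Assemble rows, compute subtotals and verify the closure identity.

    ``predicted`` (fixed + random fitted values) is required for the
    residual term; the identity
    ``CI(observed) = sum contributions + GC_e / mu`` is checked to ``tol``
    and a :class:`ClosureError` raised on violation — an inconsistent table
    is never returned.
    """
    w = np.asarray(weights, float) if weights is not None else ranks.weights
    observed = np.asarray(observed, float)
    mu = weighted_mean(observed, w)
    ci_obs = concentration_index(observed, ranks, w).ci_value

    rows = list(fixed_rows) + list(random_rows)
    ci_hat_fixed = sum(r.contribution for r in fixed_rows)
    ci_hat_random = sum(r.contribution for r in random_rows)
    ci_hat = ci_hat_fixed + ci_hat_random

    if predicted is None:
        raise ValueError("predicted outcome values are required")
    resid = observed - np.asarray(predicted, float)
    residual_term = generalized_concentration(resid, ranks, w) / mu

    gap = ci_obs - (ci_hat + residual_term)
    if abs(gap) > tol:
        raise ClosureError(
            f"decomposition does not close: CI(obs)={ci_obs:.12g}, "
            f"sum+residual={ci_hat + residual_term:.12g}, gap={gap:.3g}")

    for r in rows:
        r.pct = pct_contribution(r.contribution, ci_hat) if ci_hat != 0 else None

    tiers = {}
    for r in rows:
        tiers[r.tier] = tiers.get(r.tier, 0.0) + r.contribution
    tier_pct = ({t: v / ci_hat * 100.0 for t, v in tiers.items()}
                if ci_hat != 0 else {})

    return DecompTable(rows=rows, mu=mu, ci_observed=ci_obs, ci_hat=ci_hat,
                       ci_hat_fixed=ci_hat_fixed, ci_hat_random=ci_hat_random,
                       residual_term=residual_term, tier_totals=tiers,
                       tier_pct=tier_pct)


def rank_rows(table: DecompTable, tier: str, k: int) -> list[DecompRow]:
    """Top-``k`` rows of a tier by absolute contribution (stable, ties by name)."""
    rows = [r for r in table.rows if r.tier == tier]
    rows.sort(key=lambda r: (-abs(r.contribution), r.name))
    return rows[:max(k, 0)]


def decompose(fit: MixedFit, data: pd.DataFrame, ranks: FractionalRanks,
              weights: np.ndarray | None = None) -> DecompTable:
    """Full decomposition of the outcome CI for one fitted model."""
    w = np.asarray(weights, float) if weights is not None else ranks.weights
    observed = data[fit.spec.outcome].to_numpy(float)
    mu = weighted_mean(observed, w)
    fixed_rows = decompose_fixed(fit, data, ranks, w, mu)
    random_rows = decompose_random(fit, data, ranks, w, mu)
    return assemble_table(fixed_rows, random_rows, observed, ranks, w,
                          predicted=fit.fitted_fixed + fit.fitted_random)
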