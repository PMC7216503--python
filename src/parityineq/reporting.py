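"""Publication-style descriptive and model tables.

Everything descriptive is sampling-weight weighted: percentage
distributions of the individual and area attributes, and weighted means of
the 3+ parity outcome (with a weighted standard error) by attribute level.
Model tables mirror the nested-models layout: one column per model with
coefficients, coefficient/SE ratios, variance components, ICC, percent of
level-2 variance explained and the log-likelihood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concentration import weighted_mean
from .multilevel import MixedFit, icc, level2_explained

DESCRIPTIVE_ATTRIBUTES = [
    "age_group",
    "edu_lt_secondary",
    "husband_edu_lt_secondary",
    "no_modern_toilet",
    "married_lt18",
    "child_death",
    "unmet_need",
    "gendered_lowq",
    "env_lowq",
    "health_lowq",
]


def _weighted_se(x: np.ndarray, w: np.ndarray) -> float:
    xbar = np.sum(w * x) / np.sum(w)
    return float(np.sqrt(np.sum(w**2 * (x - xbar) ** 2)) / np.sum(w))


def run_descriptives(data: pd.DataFrame,
                     outcome: str = "outcome_parity3plus",
                     attributes: list[str] | None = None,
                     weight_col: str = "weight") -> dict[str, pd.DataFrame]:
    """Weighted attribute distribution and outcome means by attribute level.

    Returns ``{"distribution": ..., "outcome_by_level": ...}``; the
    distribution table has one row per (attribute, level) with the weighted
    percent, the outcome table adds the weighted mean and SE of the outcome.
    """
    attrs = [a for a in (attributes or DESCRIPTIVE_ATTRIBUTES)
             if a in data.columns]
    w = data[weight_col].to_numpy(float)
    y = data[outcome].to_numpy(float) if outcome in data.columns else None
    total_w = w.sum()

    dist_rows, mean_rows = [], []
    for attr in attrs:
        for level, idx in data.groupby(attr, sort=True).groups.items():
            sel = data.index.isin(idx)
            pct = w[sel].sum() / total_w * 100.0
            dist_rows.append({"attribute": attr, "level": level,
                              "weighted_pct": pct})
            if y is not None:
                mean_rows.append({
                    "attribute": attr, "level": level,
                    "weighted_mean": weighted_mean(y[sel], w[sel]),
                    "se": _weighted_se(y[sel], w[sel]),
                    "weighted_pct": pct})
    out = {"distribution": pd.DataFrame(dist_rows)}
    if y is not None:
        overall = pd.DataFrame([{
            "attribute": "total", "level": "",
            "weighted_mean": weighted_mean(y, w),
            "se": _weighted_se(y, w), "weighted_pct": 100.0}])
        out["outcome_by_level"] = pd.concat(
            [overall, pd.DataFrame(mean_rows)], ignore_index=True)
    return out


def model_comparison_table(fits: list[MixedFit]) -> pd.DataFrame:
    """Nested-models table: coefficients, z ratios, variance components.

    The first fit is treated as the null model for the percent of level-2
    variance explained.  Significance is reported as the coefficient/SE
    ratio rather than star labels.
    """
    null = fits[0]
    coef_names: list[str] = []
    for f in fits:
        for name in f.fixed.index:
            if name not in coef_names:
                coef_names.append(name)
    table = {}
    for f in fits:
        col = {}
        for name in coef_names:
            if name in f.fixed.index:
                se = f.fixed_se.get(name, np.nan)
                z = f.fixed[name] / se if se and np.isfinite(se) else np.nan
                col[name] = f"{f.fixed[name]:.3f} (z={z:.1f})"
            else:
                col[name] = ""
        col["level2_variance"] = f"{f.tau00:.3f}"
        col["pct_level2_explained"] = (
            "" if f is null else f"{level2_explained(null, f):.1f}%")
        col["random_slope_variance"] = (
            f"{f.tau11:.3f}" if f.spec.random_slope else "")
        col["level1_variance"] = f"{f.sigma2:.3f}"
        col["icc_pct"] = f"{icc(f) * 100:.1f}%"
        col["loglik"] = f"{f.loglik:.3f}"
        table[f.spec.name] = col
    return pd.DataFrame(table)


def blup_table(fit: MixedFit) -> pd.DataFrame:
    """Per-area predicted random intercepts and slopes."""
    return pd.DataFrame({
        "u0": fit.blup_intercepts,
        "u1": fit.blup_slopes.reindex(fit.blup_intercepts.index),
    })
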