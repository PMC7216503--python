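"""Synthetic hierarchical survey generator with known ground truth.

Emulates the structure of a DHS-style fertility survey: ever-married women
aged 15-49 nested in areas (governorate x urban/rural), each with a sampling
weight, a continuous household wealth score, wealth-graded binary covariates,
and a 3+ parity outcome (living children beyond the first two) that follows
a random-slope linear multilevel model:

    Y_ij = g00 + sum_p g_p0 X_pij + sum_q g_q0 Z_qj
           + U_0j + U_1j * married_lt18_ij + e_ij

with U_0j ~ N(0, tau00), U_1j ~ N(0, tau11), e_ij ~ N(0, sigma2).  The
area-level exposures Z_qj are the lowest-quartile flags of the three
contextual scales, computed inside the generator from the full scale sample
exactly as the analysis pipeline computes them, so the generated data carry
their own area-level ground truth.

Each binary covariate k is drawn with probability
``logit^-1(a_k + b_k * wealth_rank)`` where the rank is the weighted
fractional wealth rank across the whole generated population.  A negative
slope ``b_k`` concentrates the covariate among the poor; the helper
:func:`calibrate_logit` converts a target (prevalence, concentration index)
pair into ``(a_k, b_k)`` analytically, and the default configuration is
calibrated to the covariate prevalences and concentration indices of the
2014 Egypt DHS analytic sample.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from . import area_scales as _scales
from .concentration import weighted_fractional_rank

SCHEMA_VERSION = "1"

# Individual-level model covariates (0/1 dummies), reference = advantaged.
MODEL_COVARIATES = [
    "age_35_39",
    "age_40_44",
    "age_45_49",
    "edu_lt_secondary",
    "husband_edu_lt_secondary",
    "no_modern_toilet",
    "married_lt18",
    "child_death",
    "unmet_need",
]
AREA_COVARIATES = ["gendered_lowq", "env_lowq", "health_lowq"]

# Scale indicators that are complements of a model covariate.
_COMPLEMENTS = {
    "married_18plus": "married_lt18",
    "modern_toilet": "no_modern_toilet",
    "secondary_plus_education": "edu_lt_secondary",
}


class ConfigurationError(ValueError):
    """Invalid generator configuration; message names the offending field."""


class SchemaError(KeyError):
    """An input table is missing required columns."""


# ---------------------------------------------------------------------------
# Logistic wealth-gradient calibration

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)
_GL_R = 0.5 * (_GL_NODES + 1.0)       # map to (0, 1)
_GL_W = 0.5 * _GL_WEIGHTS


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def logit_prevalence(a: float, b: float) -> float:
    """E[x] for x ~ Bernoulli(logit^-1(a + b r)), r ~ Uniform(0, 1)."""
    return float(np.sum(_GL_W * _expit(a + b * _GL_R)))


def logit_ci(a: float, b: float) -> float:
    """Concentration index of the same Bernoulli covariate against r."""
    p = _expit(a + b * _GL_R)
    mean = np.sum(_GL_W * p)
    cov = np.sum(_GL_W * p * (_GL_R - 0.5))
    return float(2.0 * cov / mean)


def calibrate_logit(prevalence: float, ci: float) -> tuple[float, float]:
    """Solve for (a, b) hitting a target prevalence and concentration index.

    Works under the uniform-rank approximation (weighted fractional ranks of
    a continuous score are uniform up to discretization).
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")

    def equations(ab):
        a, b = ab
        return [logit_prevalence(a, b) - prevalence, logit_ci(a, b) - ci]

    a0 = float(np.log(prevalence / (1 - prevalence)))
    sol = optimize.root(equations, x0=[a0, 4.0 * ci], method="hybr")
    if not sol.success:  # pragma: no cover - smooth 2d system, always solves
        raise RuntimeError(f"calibration failed: {sol.message}")
    return float(sol.x[0]), float(sol.x[1])


# Calibration targets: (prevalence, concentration index) per binary
# covariate/indicator, patterned on the 2014 EDHS analytic sample.
DEFAULT_COVARIATE_TARGETS: dict[str, tuple[float, float]] = {
    "edu_lt_secondary": (0.436, -0.286),
    "husband_edu_lt_secondary": (0.377, -0.235),
    "no_modern_toilet": (0.414, -0.438),
    "married_lt18": (0.287, -0.272),
    "child_death": (0.134, -0.233),
    "unmet_need": (0.097, -0.094),
    # Scale-only indicators (favorable conditions, concentrated among the
    # better-off); prevalences are round EDHS-style figures.
    "never_fgc": (0.08, 0.35),
    "no_spousal_violence": (0.70, 0.08),
    "no_other_violence": (0.85, 0.05),
    "fgc_not_religious": (0.40, 0.25),
    "violence_never_justified": (0.55, 0.20),
    "marriage_age_18_attitude": (0.75, 0.10),
    "currently_using_contraception": (0.58, 0.05),
    "met_need": (0.87, 0.06),
    "postnatal_care_last2y": (0.60, 0.12),
}

# Fixed effects of the default data-generating model (full random-slope
# specification: individual dummies + area lowest-quartile flags).
DEFAULT_FIXED_EFFECTS: dict[str, float] = {
    "intercept": 0.553,
    "age_35_39": 0.434,
    "age_40_44": 0.665,
    "age_45_49": 0.855,
    "edu_lt_secondary": 0.221,
    "husband_edu_lt_secondary": 0.061,
    "no_modern_toilet": 0.142,
    "married_lt18": 0.710,
    "child_death": 0.080,
    "unmet_need": 0.180,
    "gendered_lowq": 0.097,
    "env_lowq": 0.184,
    "health_lowq": 0.495,
}

_CALIBRATION_CACHE: dict[tuple[float, float], tuple[float, float]] = {}


def _calibrated(target: tuple[float, float]) -> tuple[float, float]:
    if target not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[target] = calibrate_logit(*target)
    return _CALIBRATION_CACHE[target]


def default_gradients() -> tuple[dict[str, float], dict[str, float]]:
    """(intercepts a_k, slopes b_k) calibrated to the default targets."""
    a, b = {}, {}
    for name, target in DEFAULT_COVARIATE_TARGETS.items():
        a[name], b[name] = _calibrated(target)
    return a, b


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey population.

    Defaults mirror the scale and structure of the 2014 EDHS analytic
    setting: 47 areas, roughly 21,000 ever-married women 15-49 of whom about
    12,000 enter the 30+/2-children model sample, Model-4-style fixed
    effects, tau00 = 0.032, tau11 = 0.067 (random slope on early marriage),
    sigma2 = 1.237.
    """

    n_areas: int = 47
    women_per_area: int | tuple[int, int] = (150, 750)
    fixed_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    tau00: float = 0.032
    tau11: float = 0.067
    sigma2: float = 1.237
    wealth_gradient: dict[str, float] = field(
        default_factory=lambda: default_gradients()[1])
    logit_intercepts: dict[str, float] = field(
        default_factory=lambda: default_gradients()[0])
    weight_dispersion: float = 0.3
    seed: int = 0
    # Wealth score = area mean + within-area deviation; the between-area
    # share drives how strongly lowest-quartile flags track poverty.
    area_wealth_sd: float = 0.8
    within_wealth_sd: float = 0.8
    # Area-level heterogeneity of the scale-only indicators beyond wealth
    # (logit-scale sd).  Areas differ idiosyncratically in gender norms and
    # in health-system reach; the offset is shared by the indicators of a
    # scale (norms cluster), with half-sd indicator-level texture on top.
    # Without it the contextual scales would all be monotone in area wealth
    # and their lowest-quartile flags collinear by construction.
    indicator_area_sd: float = 0.5
    count_mode: bool = False
    all_eligible: bool = False
    include_marriage_duration: bool = True

    def validate(self) -> None:
        if not isinstance(self.n_areas, (int, np.integer)) or self.n_areas < 4:
            raise ConfigurationError("n_areas must be an integer >= 4")
        wpa = self.women_per_area
        if isinstance(wpa, (int, np.integer)):
            if wpa <= 0:
                raise ConfigurationError("women_per_area must be positive")
        else:
            try:
                lo, hi = wpa
            except (TypeError, ValueError):
                raise ConfigurationError(
                    "women_per_area must be an int or a (low, high) range")
            if lo <= 0 or hi < lo:
                raise ConfigurationError(
                    "women_per_area range must satisfy 0 < low <= high")
        for name in ("tau00", "tau11"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sigma2 <= 0:
            raise ConfigurationError("sigma2 must be > 0")
        if self.weight_dispersion < 0:
            raise ConfigurationError("weight_dispersion must be >= 0")
        if "intercept" not in self.fixed_effects:
            raise ConfigurationError("fixed_effects must include 'intercept'")
        known = set(MODEL_COVARIATES) | set(_scales.ALL_COMPONENTS)
        for name in self.wealth_gradient:
            if name not in known and name not in self.fixed_effects:
                raise ConfigurationError(
                    f"wealth_gradient names unknown covariate '{name}'")
            if name not in self.logit_intercepts:
                raise ConfigurationError(
                    f"wealth_gradient covariate '{name}' has no "
                    "logit_intercepts entry")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["women_per_area"], tuple):
            d["women_per_area"] = list(d["women_per_area"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SyntheticDataset:
    """One generated population plus the truth that produced it."""

    scale_sample: pd.DataFrame   # all ever-married women 15-49
    model_sample: pd.DataFrame   # filtered: age >= 30 and >= 2 children
    women: pd.DataFrame          # full woman-level table (superset columns)
    truth: GeneratorConfig
    area_truth: pd.DataFrame     # per-area U_0j, U_1j, scales, flags


# ---------------------------------------------------------------------------
# Generation

_AGE_GROUPS = ["30_34", "35_39", "40_44", "45_49"]
_AGE_GROUP_P = np.array([0.299, 0.270, 0.221, 0.210])
_P_AGE_30PLUS = 0.62           # share of ever-married 15-49 aged 30+
_P_LT2_GIVEN_30PLUS = 0.085    # 30+ women with fewer than 2 living children


def _draw_ages(rng: np.random.Generator, n: int,
               all_eligible: bool) -> np.ndarray:
    if all_eligible:
        group = rng.choice(4, size=n, p=_AGE_GROUP_P / _AGE_GROUP_P.sum())
        return 30 + 5 * group + rng.integers(0, 5, size=n)
    young = rng.random(n) >= _P_AGE_30PLUS
    ages = np.empty(n, dtype=int)
    ages[young] = rng.integers(18, 30, size=int(young.sum()))
    older = ~young
    grp = rng.choice(4, size=int(older.sum()), p=_AGE_GROUP_P / _AGE_GROUP_P.sum())
    ages[older] = 30 + 5 * grp + rng.integers(0, 5, size=int(older.sum()))
    return ages


def generate_population(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one population under ``config``; same seed, same bytes.

    Returns the full woman table, the scale sample (all women, indicator
    columns only), the filtered model sample, and the realized per-area
    random effects alongside the configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_areas = int(config.n_areas)
    wpa = config.women_per_area
    if isinstance(wpa, (int, np.integer)):
        sizes = np.full(n_areas, int(wpa))
    else:
        sizes = rng.integers(int(wpa[0]), int(wpa[1]) + 1, size=n_areas)
    n = int(sizes.sum())
    area_id = np.repeat(np.arange(n_areas), sizes)

    # Area wealth levels and random effects.
    area_mu = rng.normal(0.0, config.area_wealth_sd, size=n_areas)
    u0 = rng.normal(0.0, np.sqrt(config.tau00), size=n_areas)
    u1 = rng.normal(0.0, np.sqrt(config.tau11), size=n_areas)

    # Sampling weights: log-normal, normalized to mean 1.
    if config.weight_dispersion > 0:
        weight = rng.lognormal(mean=-config.weight_dispersion**2 / 2,
                               sigma=config.weight_dispersion, size=n)
        weight /= weight.mean()
    else:
        weight = np.ones(n)

    wealth = area_mu[area_id] + rng.normal(0.0, config.within_wealth_sd, size=n)
    rank = weighted_fractional_rank(wealth, weight).ranks

    age = _draw_ages(rng, n, config.all_eligible)
    df = pd.DataFrame({
        "woman_id": np.arange(n),
        "area_id": area_id,
        "weight": weight,
        "age_years": age,
        "wealth_score": wealth,
    })

    # Wealth-graded binary draws; complements derived, never drawn twice.
    # Scale-only indicators get an area-level logit offset shared within
    # their scale plus indicator-level texture, so each contextual scale
    # carries variation of its own beyond area wealth.
    scale_only = (set(_scales.ALL_COMPONENTS) - set(_COMPLEMENTS)
                  ) - set(MODEL_COVARIATES)
    scale_of = {c: "gendered" for c in _scales.GENDERED_COMPONENTS}
    scale_of.update({c: "env" for c in _scales.ENV_COMPONENTS})
    scale_of.update({c: "health" for c in _scales.HEALTH_COMPONENTS})
    sd = config.indicator_area_sd
    shared = {s: rng.normal(0.0, sd, size=n_areas)
              for s in ("gendered", "env", "health")}
    for name, b in config.wealth_gradient.items():
        a = config.logit_intercepts[name]
        logit = a + b * rank
        if name in scale_only and sd > 0:
            texture = rng.normal(0.0, sd / 2.0, size=n_areas)
            logit = logit + (shared[scale_of[name]] + texture)[area_id]
        df[name] = (rng.random(n) < _expit(logit)).astype(int)
    for indicator, covariate in _COMPLEMENTS.items():
        if covariate in df.columns:
            df[indicator] = 1 - df[covariate]
    missing = [c for c in MODEL_COVARIATES[3:] if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"wealth_gradient must cover model covariates; missing {missing}")
    for c in _scales.ALL_COMPONENTS:
        if c not in df.columns:
            raise ConfigurationError(
                f"wealth_gradient must cover scale indicator '{c}'")

    # Age dummies (reference 30-34; under-30 women carry zero dummies and
    # never enter the model sample).
    cut = pd.cut(df["age_years"], [0, 34, 39, 44, np.inf],
                 labels=_AGE_GROUPS).astype(str)
    df["age_group"] = cut.where(df["age_years"] >= 30, "under_30")
    for g in _AGE_GROUPS[1:]:
        df[f"age_{g}"] = ((age >= 30) & (df["age_group"] == g)).astype(int)

    if config.include_marriage_duration:
        m_age = np.where(df["married_lt18"] == 1,
                         rng.integers(13, 18, size=n),
                         18 + np.round(rng.exponential(3.0, size=n)))
        m_age = np.minimum(m_age, age)
        df["marriage_duration_years"] = age - m_age.astype(int)

    # Area scales and lowest-quartile flags from the full scale sample.
    scale_sample = df[["woman_id", "area_id", "weight"]
                      + _scales.ALL_COMPONENTS].copy()
    area_tbl = _scales.build_area_scales(scale_sample, weighted=True)
    for flag in AREA_COVARIATES:
        df[flag] = area_tbl[flag].to_numpy()[area_id]

    # Outcome from the multilevel model equation.
    fe = config.fixed_effects
    lp = np.full(n, fe["intercept"], dtype=float)
    for name, beta in fe.items():
        if name == "intercept":
            continue
        if name not in df.columns:
            raise ConfigurationError(
                f"fixed_effects names '{name}' which was not generated")
        lp += beta * df[name].to_numpy(float)
    e = rng.normal(0.0, np.sqrt(config.sigma2), size=n)
    y = lp + u0[area_id] + u1[area_id] * df["married_lt18"].to_numpy(float) + e

    if config.count_mode:
        y_count = np.maximum(np.rint(y), 0).astype(int)
        df["outcome_parity3plus"] = y_count.astype(float)
        base_children = y_count + 2
    else:
        df["outcome_parity3plus"] = y
        base_children = np.full(n, 2)

    # Living-children counts: only the (age, >=2 children) filter uses them.
    children = np.asarray(base_children).copy()
    if config.all_eligible:
        df["n_living_children"] = np.maximum(children, 2)
    else:
        lt2_old = (age >= 30) & (rng.random(n) < _P_LT2_GIVEN_30PLUS)
        young = age < 30
        children = np.where(lt2_old | young, 0, np.maximum(children, 2))
        children[lt2_old] = rng.integers(0, 2, size=int(lt2_old.sum()))
        children[young] = rng.choice([0, 1, 2, 3], size=int(young.sum()),
                                     p=[0.3, 0.4, 0.2, 0.1])
        df["n_living_children"] = children

    area_truth = area_tbl.copy()
    area_truth["u0"] = u0
    area_truth["u1"] = u1
    area_truth["area_wealth"] = area_mu
    area_truth["n_women"] = sizes

    model_sample = filter_model_sample(df)
    return SyntheticDataset(scale_sample=scale_sample,
                            model_sample=model_sample,
                            women=df, truth=config, area_truth=area_truth)


def filter_model_sample(records: pd.DataFrame) -> pd.DataFrame:
    """Analytic-sample filter: women aged 30+ with at least 2 living children.

    Row order is preserved; raises :class:`SchemaError` if the age or
    living-children columns are absent.
    """
    for col in ("age_years", "n_living_children"):
        if col not in records.columns:
            raise SchemaError(f"model-sample filter requires column '{col}'")
    mask = (records["age_years"] >= 30) & (records["n_living_children"] >= 2)
    return records.loc[mask].copy()


# ---------------------------------------------------------------------------
# Persistence

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write CSV tables, config JSON and a generation log; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scale_sample": outdir / "scale_sample.csv",
        "model_sample": outdir / "model_sample.csv",
        "area_truth": outdir / "area_truth.csv",
        "config": outdir / "generator_config.json",
        "log": outdir / "generation_log.json",
    }
    dataset.scale_sample.to_csv(paths["scale_sample"], index=False)
    dataset.model_sample.to_csv(paths["model_sample"], index=False)
    dataset.area_truth.to_csv(paths["area_truth"])
    cfg = dataset.truth.to_dict()
    cfg["schema_version"] = SCHEMA_VERSION
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True))
    paths["log"].write_text(json.dumps({
        "schema_version": SCHEMA_VERSION,
        "seed": dataset.truth.seed,
        "config_hash": dataset.truth.config_hash(),
        "n_women": int(len(dataset.women)),
        "n_model_sample": int(len(dataset.model_sample)),
        "n_areas": int(dataset.truth.n_areas),
    }, indent=2))
    return {k: str(v) for k, v in paths.items()}
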