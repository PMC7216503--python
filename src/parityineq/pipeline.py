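"""End-to-end orchestration: generate/load -> filter -> scales -> fits ->
decomposition -> tables.

A :class:`PipelineConfig` names either a generator configuration (synthetic
run) or a pair of input CSVs (scale sample + woman-level sample), never
both.  Every run writes its tables, a JSON summary, and a structured log
carrying the seed and a configuration hash, so a rerun with the same seed
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import area_scales as scales_mod
from . import decomposition as dec
from . import multilevel as ml
from . import reporting
from . import synthetic as syn
from .concentration import ci_uncertainty, weighted_fractional_rank

EXIT_CONFIG = 2
EXIT_SCHEMA = 3
EXIT_CONVERGENCE = 4
EXIT_CLOSURE = 5

_MODEL_SAMPLE_REQUIRED = ["area_id", "weight", "wealth_score",
                          "outcome_parity3plus", "age_years",
                          "n_living_children"]


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """One run of the full analysis chain."""

    generator: syn.GeneratorConfig | None = None
    scale_sample_path: str | None = None
    model_sample_path: str | None = None
    weighted_scales: bool = True
    bootstrap_reps: int = 0          # 0 disables the CI bootstrap
    seed: int = 0
    out_dir: str = "results"
    random_slope: str | None = "married_lt18"

    def validate(self) -> None:
        has_paths = self.scale_sample_path is not None or \
            self.model_sample_path is not None
        if self.generator is not None and has_paths:
            raise PipelineConfigError(
                "configure either a generator or input paths, not both")
        if self.generator is None and not (
                self.scale_sample_path and self.model_sample_path):
            raise PipelineConfigError(
                "a run needs a generator config or both input CSV paths")

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None,
                  out_dir: str | None = None) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        gen = raw.pop("generator", None)
        if gen is not None:
            if "women_per_area" in gen and isinstance(gen["women_per_area"], list):
                gen["women_per_area"] = tuple(gen["women_per_area"])
            gen = syn.GeneratorConfig(**gen)
        cfg = cls(generator=gen, **raw)
        if seed is not None:
            cfg.seed = seed
            if cfg.generator is not None:
                cfg.generator.seed = seed
        if out_dir is not None:
            cfg.out_dir = out_dir
        return cfg

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.generator is not None:
        ds = syn.generate_population(config.generator)
        return ds.scale_sample, ds.women
    scale_sample = pd.read_csv(config.scale_sample_path)
    women = pd.read_csv(config.model_sample_path)
    missing = [c for c in _MODEL_SAMPLE_REQUIRED if c not in women.columns]
    if missing:
        raise syn.SchemaError(f"model-sample CSV missing columns: {missing}")
    return scale_sample, women


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write the report bundle.

    Returns a dict with the fitted models, the decomposition table, the
    descriptive tables and the paths written.  Raises (never silently
    reports) on schema, convergence or closure failure.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scale_sample, women = _load_inputs(config)

    # Area scales from the full 15-49 sample, merged by area onto the
    # model sample; a synthetic run regenerates identical flags.
    area_tbl = scales_mod.build_area_scales(scale_sample,
                                            weighted=config.weighted_scales)
    women = women.drop(columns=[c for c in scales_mod.SCALE_COLUMNS
                                + scales_mod.FLAG_COLUMNS
                                if c in women.columns])
    women = women.merge(area_tbl, left_on="area_id", right_index=True,
                        how="left")
    model_sample = syn.filter_model_sample(women).reset_index(drop=True)

    specs = ml.nested_model_specs(random_slope=config.random_slope
                                  or "married_lt18")
    if config.random_slope is None:
        specs = specs[:3]
    fits = [ml.fit_model(spec, model_sample) for spec in specs]
    final = fits[-1]

    weights = model_sample["weight"].to_numpy(float)
    ranks = weighted_fractional_rank(
        model_sample["wealth_score"].to_numpy(float), weights)
    table = dec.decompose(final, model_sample, ranks, weights)

    descriptives = reporting.run_descriptives(model_sample)
    comparison = reporting.model_comparison_table(fits)

    outcome = model_sample["outcome_parity3plus"].to_numpy(float)
    ci_summary = {"ci_observed": table.ci_observed, "mu": table.mu}
    if config.bootstrap_reps:
        se, lo, hi = ci_uncertainty(
            outcome, model_sample["wealth_score"].to_numpy(float), weights,
            n_boot=config.bootstrap_reps, seed=config.seed)
        ci_summary.update({"ci_se": se, "ci_lower": lo, "ci_upper": hi})

    paths = {
        "area_scales": out / "area_scales.csv",
        "model_comparison": out / "model_comparison.csv",
        "decomposition": out / "decomposition.csv",
        "top_areas": out / "top_areas.csv",
        "top_area_slopes": out / "top_area_slopes.csv",
        "descriptives_distribution": out / "descriptives_distribution.csv",
        "descriptives_outcome": out / "descriptives_outcome.csv",
        "blups": out / "area_random_effects.csv",
        "summary": out / "summary.json",
        "log": out / "run_log.json",
    }
    area_tbl.to_csv(paths["area_scales"])
    comparison.to_csv(paths["model_comparison"])
    table.to_frame().to_csv(paths["decomposition"], index=False)
    _rows_frame(dec.rank_rows(table, dec.TIER_RANDOM_INTERCEPT, 5)).to_csv(
        paths["top_areas"], index=False)
    if final.spec.random_slope is not None:
        _rows_frame(dec.rank_rows(table, dec.TIER_RANDOM_SLOPE, 5)).to_csv(
            paths["top_area_slopes"], index=False)
    descriptives["distribution"].to_csv(
        paths["descriptives_distribution"], index=False)
    descriptives["outcome_by_level"].to_csv(
        paths["descriptives_outcome"], index=False)
    reporting.blup_table(final).to_csv(paths["blups"])

    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_model_sample": int(len(model_sample)),
        "n_areas": int(model_sample["area_id"].nunique()),
        "concentration": ci_summary,
        "decomposition": table.summary(),
        "models": {f.spec.name: {
            "tau00": f.tau00, "tau11": f.tau11, "sigma2": f.sigma2,
            "loglik": f.loglik, "icc_pct": ml.icc(f) * 100.0,
            "boundary": f.boundary} for f in fits},
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["log"].write_text(json.dumps({
        "seed": config.seed, "config_hash": config.config_hash(),
        "outputs": {k: str(v) for k, v in paths.items()}}, indent=2))

    return {"fits": fits, "decomposition": table,
            "descriptives": descriptives, "model_sample": model_sample,
            "area_scales": area_tbl, "summary": summary,
            "paths": {k: str(v) for k, v in paths.items()}}


def _rows_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [{"name": r.name, "tier": r.tier, "coef": r.beta, "average": r.xbar,
          "elasticity": r.elasticity, "CI": r.c_k,
          "contribution": r.contribution, "pct": r.pct} for r in rows])
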