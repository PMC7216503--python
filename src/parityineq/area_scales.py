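"""Area-level contextual scales and lowest-quartile exposure flags.

Three per-area scales summarize the context all ever-married women aged
15-49 live in:

* **gendered context** — mean of eight proportions (five practices: never
  experienced FGC, not married before 18, no spousal violence, no other
  violence, secondary+ education; three attitudes: FGC not religiously
  required, spousal violence never justified, appropriate marriage age 18+);
* **environmental development** — proportion of women whose household has a
  modern toilet facility;
* **health-system performance** — mean of three proportions (current
  contraceptive use, met need for contraception, postnatal care after a
  delivery in the last two years).

Each scale is dichotomized across areas at its lowest quartile
(flag = 1 for areas at or below the 25th percentile), giving the area-level
exposures used in the multilevel model.  Proportions are sampling-weight
weighted by default; quartiles are taken across *areas*, unweighted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GENDERED_COMPONENTS = [
    "never_fgc",
    "married_18plus",
    "no_spousal_violence",
    "no_other_violence",
    "secondary_plus_education",
    "fgc_not_religious",
    "violence_never_justified",
    "marriage_age_18_attitude",
]
ENV_COMPONENTS = ["modern_toilet"]
HEALTH_COMPONENTS = [
    "currently_using_contraception",
    "met_need",
    "postnatal_care_last2y",
]
ALL_COMPONENTS = GENDERED_COMPONENTS + ENV_COMPONENTS + HEALTH_COMPONENTS

SCALE_COLUMNS = ["gendered_scale", "env_scale", "health_scale"]
FLAG_COLUMNS = ["gendered_lowq", "env_lowq", "health_lowq"]


class UndefinedScaleError(ValueError):
    """An area has no records, so its scale is undefined."""


def _area_proportions(records: pd.DataFrame, components: list[str],
                      weighted: bool) -> pd.DataFrame:
    missing = [c for c in components if c not in records.columns]
    if missing:
        raise KeyError(f"scale-sample table is missing indicators: {missing}")
    if records.empty:
        raise UndefinedScaleError("no records supplied")
    df = records.copy()
    w = df["weight"].to_numpy(float) if weighted else np.ones(len(df))
    df["_w"] = w
    for c in components:
        df[f"_w_{c}"] = w * df[c].to_numpy(float)
    grouped = df.groupby("area_id", sort=True)
    wsum = grouped["_w"].sum()
    out = pd.DataFrame(index=wsum.index)
    for c in components:
        out[c] = grouped[f"_w_{c}"].sum() / wsum
    return out


def _scale_from(records: pd.DataFrame, components: list[str],
                weighted: bool) -> pd.Series:
    props = _area_proportions(records, components, weighted)
    return props.mean(axis=1)


def compute_gendered_scale(records: pd.DataFrame,
                           weighted: bool = True) -> pd.Series:
    """Per-area gendered-context scale: mean of the eight proportions."""
    return _scale_from(records, GENDERED_COMPONENTS, weighted)


def compute_env_scale(records: pd.DataFrame,
                      weighted: bool = True) -> pd.Series:
    """Per-area environmental-development scale (modern-toilet proportion)."""
    return _scale_from(records, ENV_COMPONENTS, weighted)


def compute_health_scale(records: pd.DataFrame,
                         weighted: bool = True) -> pd.Series:
    """Per-area health-system scale: mean of the three proportions."""
    return _scale_from(records, HEALTH_COMPONENTS, weighted)


def lowest_quartile_flags(scales: pd.Series) -> pd.Series:
    """1 for areas at or below the 25th percentile of the area scale values.

    The cut point is the linear-interpolation 25th percentile of the
    (unweighted) area-level values; boundary ties are included in the lowest
    quartile.  Requires at least 4 areas.
    """
    values = np.asarray(scales, dtype=float)
    if values.size < 4:
        raise ValueError("lowest-quartile flags require at least 4 areas")
    q1 = np.percentile(values, 25, method="linear")
    return pd.Series((values <= q1).astype(int), index=scales.index)


def build_area_scales(records: pd.DataFrame,
                      weighted: bool = True) -> pd.DataFrame:
    """All three scales plus lowest-quartile flags, indexed by area_id.

    ``records`` is the scale sample: one row per ever-married woman aged
    15-49 with ``area_id``, ``weight`` and the twelve binary indicators.
    """
    out = pd.DataFrame({
        "gendered_scale": compute_gendered_scale(records, weighted),
        "env_scale": compute_env_scale(records, weighted),
        "health_scale": compute_health_scale(records, weighted),
    })
    out["gendered_lowq"] = lowest_quartile_flags(out["gendered_scale"])
    out["env_lowq"] = lowest_quartile_flags(out["env_scale"])
    out["health_lowq"] = lowest_quartile_flags(out["health_scale"])
    out.index.name = "area_id"
    return out
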