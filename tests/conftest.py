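import warnings

import numpy as np
import pandas as pd
import pytest

from parityineq import synthetic as syn
from parityineq import multilevel as ml

# MixedLM emits benign runtime warnings near variance boundaries.
warnings.filterwarnings("ignore", category=RuntimeWarning,
                        module="statsmodels")


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic population: 20 areas, ~100 women each."""
    cfg = syn.GeneratorConfig(seed=11, n_areas=20, women_per_area=(80, 120))
    return syn.generate_population(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-scale population (47 areas, ~12k model women)."""
    return syn.generate_population(syn.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_fits(default_dataset):
    """The four nested model fits on the default population."""
    return [ml.fit_model(s, default_dataset.model_sample)
            for s in ml.nested_model_specs()]


@pytest.fixture()
def toy_roster():
    """Six women with stated ages and parities; three pass the filter."""
    return pd.DataFrame({
        "woman_id": range(6),
        "age_years": [29, 30, 45, 33, 31, 50],
        "n_living_children": [3, 2, 1, 4, 2, 0],
        "weight": 1.0,
    })


def brute_force_ci(h, r, w):
    """O(n^2) double-sum concentration index, independent of the package.

    cov_w(h, r) = sum_ij w_i w_j (h_i - h_j)(r_i - r_j) / (2 W^2);
    CI = 2 cov / mu.
    """
    h = np.asarray(h, float)
    r = np.asarray(r, float)
    w = np.asarray(w, float)
    W = w.sum()
    mu = np.sum(w * h) / W
    cov = 0.0
    for i in range(len(h)):
        cov += np.sum(w[i] * w * (h[i] - h) * (r[i] - r))
    cov /= 2.0 * W**2
    return 2.0 * cov / mu
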