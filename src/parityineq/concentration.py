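"""Weighted fractional ranks and the concentration index.

The concentration index (CI) measures socioeconomic inequality in a health
variable ``h`` ranked by a living-standards score (here, a household wealth
score).  For micro data it is computed from the weighted covariance between
``h`` and the fractional wealth rank ``r``::

    CI = 2 * cov_w(h, r) / mu

where ``mu`` is the weighted mean of ``h``.  CI lies in [-1, 1] for
non-negative ``h``; negative values indicate that the outcome is
disproportionately concentrated among the poor.  The *generalized*
concentration index drops the division by the mean and is used for the
residual term of a regression-based decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FractionalRanks",
    "CIResult",
    "weighted_fractional_rank",
    "weighted_mean",
    "weighted_cov",
    "concentration_index",
    "generalized_concentration",
    "ci_uncertainty",
]


@dataclass(frozen=True)
class FractionalRanks:
    """Weighted fractional ranks of a score vector, in original record order.

    ``ranks[i]`` is the midpoint of record *i*'s weight interval in the
    cumulative weight distribution of the score, scaled to (0, 1).  Records
    with tied scores share the rank computed at the midpoint of the tie
    group's pooled weight, so the weighted mean of the ranks is exactly 0.5.
    """

    ranks: np.ndarray
    weights: np.ndarray
    total_weight: float
    tie_groups: dict = field(default_factory=dict, repr=False)

    def reversed(self) -> "FractionalRanks":
        """Ranks under the reversed (rich-to-poor) ordering: r -> 1 - r."""
        return FractionalRanks(1.0 - self.ranks, self.weights,
                               self.total_weight, self.tie_groups)


@dataclass(frozen=True)
class CIResult:
    """A concentration index with the pieces it was computed from."""

    ci_value: float
    mu: float
    cov: float
    n_effective: float
    se: float | None = None
    ci95: tuple[float, float] | None = None


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def weighted_fractional_rank(scores, weights=None) -> FractionalRanks:
    """Weighted fractional ranks of ``scores``, ascending (poorest first).

    After sorting by score, record *i* receives
    ``r_i = (cumweight of strictly poorer records + w_i / 2) / W``.
    Tied scores all receive the rank at the midpoint of the tie group's
    pooled cumulative weight.

    Parameters
    ----------
    scores : array-like
        Wealth (or other stratifier) scores, one per record.
    weights : array-like, optional
        Positive sampling weights; equal weights if omitted.

    Returns
    -------
    FractionalRanks
        Ranks aligned with the input order.
    """
    s = _as_float_array(scores, "scores")
    if weights is None:
        w = np.ones_like(s)
    else:
        w = _as_float_array(weights, "weights")
    if w.shape != s.shape:
        raise ValueError("scores and weights must have the same length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")

    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    w_sorted = w[order]
    total = float(w_sorted.sum())

    # Pool tied scores: each unique score gets the midpoint of its tie
    # group's cumulative weight, which reduces to the per-record midpoint
    # when scores are distinct.
    uniq, inv = np.unique(s_sorted, return_inverse=True)
    grp_w = np.bincount(inv, weights=w_sorted)
    grp_cum = np.cumsum(grp_w)
    ranks_sorted = ((grp_cum - grp_w / 2.0) / total)[inv]

    tie_groups: dict[float, np.ndarray] = {}
    if uniq.size < s_sorted.size:
        counts = np.bincount(inv)
        for g in np.nonzero(counts > 1)[0]:
            tie_groups[float(uniq[g])] = order[inv == g]

    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    return FractionalRanks(ranks, w, total, tie_groups)


def weighted_mean(x, weights) -> float:
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w * x) / np.sum(w))


def weighted_cov(x, y, weights) -> float:
    """Population-style weighted covariance, normalized by total weight."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    wsum = np.sum(w)
    xm = np.sum(w * x) / wsum
    ym = np.sum(w * y) / wsum
    return float(np.sum(w * (x - xm) * (y - ym)) / wsum)


def _ranks_array(ranks) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(ranks, FractionalRanks):
        return ranks.ranks, ranks.weights
    return np.asarray(ranks, dtype=float), None


def concentration_index(h, ranks, weights=None) -> CIResult:
    """Concentration index of ``h`` against wealth ranks.

    Parameters
    ----------
    h : array-like
        The health/outcome variable (or a determinant of it).
    ranks : FractionalRanks or array-like
        Fractional ranks from :func:`weighted_fractional_rank`.
    weights : array-like, optional
        Defaults to the weights stored in ``ranks``.

    Raises
    ------
    ZeroDivisionError
        If the weighted mean of ``h`` is zero, the ratio form is undefined;
        use :func:`generalized_concentration` instead.
    """
    r, rank_w = _ranks_array(ranks)
    h = _as_float_array(h, "h")
    w = np.asarray(weights, dtype=float) if weights is not None else rank_w
    if w is None:
        w = np.ones_like(h)
    if not (h.shape == r.shape == w.shape):
        raise ValueError("h, ranks and weights must be aligned")

    mu = weighted_mean(h, w)
    cov = weighted_cov(h, r, w)
    n_eff = float(np.sum(w) ** 2 / np.sum(w**2))
    if mu == 0:
        raise ZeroDivisionError(
            "concentration index undefined for zero-mean variable; "
            "use generalized_concentration")
    return CIResult(ci_value=2.0 * cov / mu, mu=mu, cov=cov, n_effective=n_eff)


def generalized_concentration(values, ranks, weights=None) -> float:
    """Generalized concentration index ``2 * cov_w(values, r)`` (no 1/mu).

    Used for the residual term ``GC_e / mu`` of the decomposition, where the
    residuals have (near-)zero mean and the ratio form is undefined.
    """
    r, rank_w = _ranks_array(ranks)
    v = _as_float_array(values, "values")
    w = np.asarray(weights, dtype=float) if weights is not None else rank_w
    if w is None:
        w = np.ones_like(v)
    return 2.0 * weighted_cov(v, r, w)


def ci_uncertainty(h, scores, weights=None, n_boot: int = 1000,
                   seed: int | None = None) -> tuple[float, float, float]:
    """Bootstrap standard error and percentile 95% interval for the CI.

    Records are resampled with replacement (a case bootstrap: a resampled
    record keeps its sampling weight) and ranks are recomputed inside each
    resample.  Resamples with a zero-mean outcome are skipped and counted.

    Returns ``(se, lower, upper)``; deterministic for a fixed ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100 for a stable interval")
    h = _as_float_array(h, "h")
    s = _as_float_array(scores, "scores")
    w = (_as_float_array(weights, "weights") if weights is not None
         else np.ones_like(h))
    n = h.size
    rng = np.random.default_rng(seed)
    stats = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        hb, sb, wb = h[idx], s[idx], w[idx]
        mu = weighted_mean(hb, wb)
        if mu == 0:
            skipped += 1
            continue
        rb = weighted_fractional_rank(sb, wb)
        stats.append(2.0 * weighted_cov(hb, rb.ranks, wb) / mu)
    arr = np.asarray(stats)
    se = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    lower, upper = (float(np.percentile(arr, 2.5)),
                    float(np.percentile(arr, 97.5)))
    return se, lower, upper
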