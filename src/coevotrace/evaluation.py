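"""Prediction selection, precision curves, bootstrap random bands, and
selected-vs-control comparisons.

The benchmark convention: for each metric, select the top ``L/5`` column
pairs (``L`` = protein length; largest-first for covariation scores,
smallest-first for rate- and parsimony-based predictors), measure precision
against the contact map (successes / predictions at a distance threshold),
and compare with the 95% bootstrap confidence band of the precision of
randomly selected pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PredictionSet",
    "PrecisionCurve",
    "MedianComparison",
    "l_over_5",
    "select_top_pairs",
    "precision",
    "best_covariation_meta",
    "bootstrap_random_expectation",
    "median_comparison",
    "bh_fdr",
    "pair_rate_stats",
    "rate_entropy_correlation",
]

#: Ranking direction per metric family; covariation scores rank largest
#: first, rate/parsimony predictors rank smallest first.
METRIC_DIRECTIONS: dict[str, str] = {
    "MI": "largest", "MI_over_HXY": "largest", "MIp": "largest",
    "MI_adj": "largest", "chi2": "largest", "PSICOV": "largest", "DI": "largest",
    "mean_rate": "smallest", "rate_diff": "smallest",
    "mp_ind": "smallest", "mp_dep": "smallest", "single_double_ratio": "smallest",
}


@dataclass(frozen=True)
class PredictionSet:
    """An ordered selection of column pairs made by one metric."""

    pairs: tuple[tuple[int, int], ...]
    metric: str
    direction: str

    @property
    def k(self) -> int:
        return len(self.pairs)


@dataclass
class PrecisionCurve:
    """Precision and the random-expectation band over a grid of selection
    sizes ``k``."""

    k_grid: np.ndarray
    precision: np.ndarray
    rand_lo: np.ndarray
    rand_hi: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        for arr in ("k_grid", "precision", "rand_lo", "rand_hi"):
            setattr(self, arr, np.asarray(getattr(self, arr)))
        if not (len(self.k_grid) == len(self.precision) == len(self.rand_lo) == len(self.rand_hi)):
            raise ValueError("curve arrays must share one k-grid")
        if np.any(self.rand_lo > self.rand_hi + 1e-12):
            raise ValueError("band lower bound exceeds upper bound")


@dataclass(frozen=True)
class MedianComparison:
    """Medians of a selected and a control sample with a Mann-Whitney test."""

    median_selected: float
    median_control: float
    p_value: float
    degenerate: bool = False


def l_over_5(L: int) -> int:
    """Benchmark selection size: floor(L/5), at least 1."""
    return max(1, L // 5)


def select_top_pairs(
    scores: Mapping[tuple[int, int], float],
    metric: str,
    k: int | None = None,
    L: int | None = None,
    direction: str | None = None,
) -> PredictionSet:
    """Select the top-``k`` pairs by a metric.

    Either ``k`` or ``L`` (for the floor(L/5) rule) must be given.  Ties are
    broken by ascending ``(i, j)``; pairs with missing/undefined scores are
    skipped; if fewer than ``k`` scored pairs exist the selection is capped.
    """
    if direction is None:
        if metric not in METRIC_DIRECTIONS:
            raise KeyError(f"unknown metric {metric!r}: pass an explicit direction")
        direction = METRIC_DIRECTIONS[metric]
    if direction not in ("largest", "smallest"):
        raise ValueError(f"direction must be 'largest' or 'smallest', got {direction!r}")
    if k is None:
        if L is None:
            raise ValueError("either k or L must be supplied")
        k = l_over_5(L)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")

    usable = [
        (pair, value)
        for pair, value in scores.items()
        if value is not None and not (isinstance(value, float) and math.isnan(value))
    ]
    sign = -1.0 if direction == "largest" else 1.0
    usable.sort(key=lambda pv: (sign * _rank_value(pv[1]), pv[0]))
    chosen = tuple(pair for pair, _ in usable[:k])
    return PredictionSet(pairs=chosen, metric=metric, direction=direction)


def _rank_value(v: float) -> float:
    # +inf sentinels (e.g. single:double ratio with no doubles) rank last
    # when selecting smallest and first when selecting largest, naturally.
    return float(v)


def precision(
    predictions: PredictionSet | Sequence[tuple[int, int]],
    contacts: Mapping[tuple[int, int], bool],
) -> float:
    """Fraction of predicted pairs that are true contacts."""
    pairs = predictions.pairs if isinstance(predictions, PredictionSet) else tuple(predictions)
    if not pairs:
        raise ValueError("precision is undefined for an empty prediction set")
    successes = 0
    for pair in pairs:
        if pair not in contacts:
            raise KeyError(f"pair {pair} has no contact label")
        successes += bool(contacts[pair])
    return successes / len(pairs)


def best_covariation_meta(curves: Sequence[PrecisionCurve]) -> PrecisionCurve:
    """Pointwise-best meta curve: the highest precision among all covariation
    measures at each selection size."""
    if not curves:
        raise ValueError("at least one curve is required")
    grid = curves[0].k_grid
    for c in curves[1:]:
        if not np.array_equal(c.k_grid, grid):
            raise ValueError("curves must share one k-grid")
    prec = np.max([c.precision for c in curves], axis=0)
    lo = curves[0].rand_lo
    hi = curves[0].rand_hi
    return PrecisionCurve(grid, prec, lo, hi, metric="best")


def bootstrap_random_expectation(
    statistic_fn: Callable[[Sequence[tuple[int, int]]], float],
    pair_universe: Sequence[tuple[int, int]],
    k: int,
    n_reps: int = 1000,
    level: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a statistic under random
    pair selection.

    Draws ``k`` pairs with replacement from the universe ``n_reps`` times,
    evaluates the statistic on each draw, and returns the central
    ``level``-percent interval.  Deterministic given the seed.
    """
    if k > len(pair_universe):
        raise ValueError(f"k={k} exceeds universe size {len(pair_universe)}")
    rng = np.random.default_rng(seed)
    universe = list(pair_universe)
    values = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.integers(0, len(universe), size=k)
        values[r] = statistic_fn([universe[i] for i in idx])
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(values, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def median_comparison(
    selected_values: Sequence[float], control_values: Sequence[float]
) -> MedianComparison:
    """Medians of both samples with a two-sided Mann-Whitney U p-value.

    Fully tied degenerate samples give p = 1 with a flag rather than an
    error.  Across many families, apply :func:`bh_fdr` to the p-value
    vector.
    """
    sel = np.asarray(selected_values, dtype=float)
    ctl = np.asarray(control_values, dtype=float)
    if sel.size == 0 or ctl.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([sel, ctl])).size == 1:
        return MedianComparison(float(np.median(sel)), float(np.median(ctl)), 1.0, True)
    res = stats.mannwhitneyu(sel, ctl, alternative="two-sided")
    return MedianComparison(
        float(np.median(sel)), float(np.median(ctl)), float(res.pvalue), False
    )


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg FDR: (reject flags, adjusted p-values)."""
    reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject, p_adj


def pair_rate_stats(rate_i: float, rate_j: float) -> tuple[float, float]:
    """Mean and absolute difference of the two site rates of a pair."""
    if rate_i < 0 or rate_j < 0:
        raise ValueError("rates must be >= 0")
    return (rate_i + rate_j) / 2.0, abs(rate_i - rate_j)


def rate_entropy_correlation(
    rates: Sequence[float], entropies: Sequence[float]
) -> float:
    """Pearson correlation between per-site evolutionary rates and column
    entropies."""
    r = np.asarray(rates, dtype=float)
    h = np.asarray(entropies, dtype=float)
    if r.shape != h.shape or r.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(r) == 0 or np.std(h) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(r, h)[0])
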