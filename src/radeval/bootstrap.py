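"""Paired bootstrap significance test for comparing two systems.

The test statistic is the score difference δs = s(A) − s(B) on the shared
test set.  Bootstrap test sets are drawn by resampling records with
replacement; corpus-level statistics are recomputed on every replicate from
per-record sufficient statistics.  The null distribution is the replicate
distribution of δ recentred at its own mean (shape-preserving mean shift);
the two-sided p-value uses add-one smoothing so it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import ParallelCorpus, Report

__all__ = ["BootstrapOutcome", "percentile_ci", "bootstrap_compare"]


@dataclass(frozen=True)
class BootstrapOutcome:
    delta_observed: float
    b: int
    replicate_mean: float
    replicate_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    seed: int
    score_a: float
    score_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    replicate_deltas: Optional[np.ndarray] = None


def percentile_ci(values: Sequence[float], alpha: float = 0.05) -> tuple[float, float]:
    """Empirical alpha/2 and 1−alpha/2 quantiles with linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty value sequence")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lo, hi = np.quantile(arr, [alpha / 2, 1 - alpha / 2], method="linear")
    return float(lo), float(hi)


def _stats_matrix(metric, refs: Sequence[Report], cands: Sequence[Report]) -> np.ndarray:
    if hasattr(metric, "item_stats"):
        return metric.item_stats(refs, cands)
    raise TypeError(
        "metric must expose item_stats/score_from_stats (all built-in metrics do)"
    )


def bootstrap_compare(
    corpus: ParallelCorpus,
    candidates_a: Sequence[Report],
    candidates_b: Sequence[Report],
    metric,
    b: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    keep_replicates: bool = False,
) -> BootstrapOutcome:
    """Paired bootstrap comparison of two candidate sets under one corpus metric.

    Both candidate sets must be aligned with the corpus references.  Defaults
    follow common practice for this test: B = 1000 replicates and 95%
    percentile intervals (alpha = 0.05).
    """
    n = len(corpus)
    if len(candidates_a) != n or len(candidates_b) != n:
        raise ValueError("candidate sets are not aligned with the corpus")
    if b < 1:
        raise ValueError("the number of bootstrap replicates must be >= 1")
    refs = corpus.references
    stats_a = _stats_matrix(metric, refs, list(candidates_a))
    stats_b = _stats_matrix(metric, refs, list(candidates_b))
    score_a = metric.score_from_stats(stats_a.sum(axis=0))
    score_b = metric.score_from_stats(stats_b.sum(axis=0))
    delta_obs = score_a - score_b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(b, n))
    rep_a = np.empty(b)
    rep_b = np.empty(b)
    for t in range(b):
        rows = idx[t]
        rep_a[t] = metric.score_from_stats(stats_a[rows].sum(axis=0))
        rep_b[t] = metric.score_from_stats(stats_b[rows].sum(axis=0))
    deltas = rep_a - rep_b

    centered = np.abs(deltas - deltas.mean())
    p_value = (1 + int(np.sum(centered >= abs(delta_obs)))) / (b + 1)
    ci_low, ci_high = percentile_ci(deltas, alpha)
    return BootstrapOutcome(
        delta_observed=float(delta_obs),
        b=b,
        replicate_mean=float(deltas.mean()),
        replicate_sd=float(deltas.std(ddof=1)) if b > 1 else 0.0,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p_value),
        seed=seed,
        score_a=float(score_a),
        score_b=float(score_b),
        ci_a=percentile_ci(rep_a, alpha),
        ci_b=percentile_ci(rep_b, alpha),
        replicate_deltas=deltas if keep_replicates else None,
    )
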