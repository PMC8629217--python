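"""Permutation unconditioning, stratified evaluation, n-gram diversity.

Randomly reassigning a model's generated reports to other test inputs severs
any dependence on the input; if scores survive that, the model was not using
the input.  Stratified evaluation splits the corpus by diagnostic tag
(normal vs abnormal) and recomputes each metric's corpus-level statistics
within each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import ParallelCorpus, Report
from .metrics import NGramIndex, evaluate_all

__all__ = [
    "PermutationPlan",
    "permute_candidates",
    "stratified_evaluate",
    "ngram_diversity",
]


@dataclass(frozen=True)
class PermutationPlan:
    """Audit record of a candidate-reassignment: p maps position i to source p[i]."""

    permutation: tuple[int, ...]
    seed: int
    identity_allowed: bool

    def __post_init__(self) -> None:
        if sorted(self.permutation) != list(range(len(self.permutation))):
            raise ValueError("permutation is not a bijection on 0..m-1")


def permute_candidates(
    corpus: ParallelCorpus,
    seed: int = 0,
    identity_allowed: bool = True,
) -> tuple[ParallelCorpus, PermutationPlan]:
    """Reassign candidates by a uniform random permutation; references/ids/tags untouched."""
    cands = corpus.candidates  # raises if any candidate is missing
    m = len(corpus)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    if not identity_allowed and m > 1:
        while np.array_equal(perm, np.arange(m)):
            perm = rng.permutation(m)
    plan = PermutationPlan(tuple(int(i) for i in perm), seed, identity_allowed)
    permuted = corpus.with_candidates([cands[i] for i in plan.permutation])
    return permuted, plan


def stratified_evaluate(
    corpus: ParallelCorpus,
    metric_spec: Sequence,
    idf_scope: str = "global",
    lexicon=None,
) -> pd.DataFrame:
    """Evaluate the metric spec within each tag stratum independently.

    Corpus-level statistics (brevity penalty, pooled counts) are recomputed
    per stratum.  The tf-idf table for CIDEr is built on the full reference
    side by default (``idf_scope="global"``); ``"stratum"`` rebuilds it
    within each stratum.
    """
    for rec in corpus:
        if rec.tag is None:
            raise ValueError(f"record {rec.id!r} has no stratum tag")
    if idf_scope not in ("global", "stratum"):
        raise ValueError(f"unknown idf scope {idf_scope!r}")
    index = None
    if idf_scope == "global":
        index = NGramIndex.build(corpus.references, 4)
    rows = []
    strata = sorted({rec.tag for rec in corpus})
    for stratum in strata:
        sub = ParallelCorpus(tuple(rec for rec in corpus if rec.tag == stratum))
        results = evaluate_all(sub, metric_spec, index=index, lexicon=lexicon)
        for res in results:
            rows.append(
                {
                    "stratum": stratum,
                    "metric": res.name,
                    "score": res.corpus_score,
                    "n_records": len(sub),
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "metric", "score", "n_records"])


def ngram_diversity(
    reports: Sequence[Report], n_values: Sequence[int] = (1, 2, 3, 4)
) -> dict[int, int]:
    """Distinct n-gram counts pooled over a report set."""
    out = {}
    for n in n_values:
        if n < 1:
            raise ValueError("n must be >= 1")
        grams = set()
        for r in reports:
            toks = tuple(r)
            grams.update(toks[i : i + n] for i in range(len(toks) - n + 1))
        out[n] = len(grams)
    return out
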