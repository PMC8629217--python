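"""Corpus-level caption-evaluation metrics: BLEU, ROUGE-L, METEOR, CIDEr(-D).

Two BLEU dialects are provided.  The ``paper`` dialect is the summed form
BP·Σ_k precision_k, with every precision normalised by the total number of
candidate *tokens* n_C, as some papers write BLEU out; the ``coco`` dialect
(default) is the conventional geometric-mean BLEU with per-k denominators,
matching the COCO caption-evaluation convention most published
radiology-report numbers use.

Every metric exposes per-record sufficient statistics (``item_stats`` /
``score_from_stats``) so that corpus scores can be recomputed exactly on
bootstrap resamples without re-tokenising.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import ParallelCorpus, Report

__all__ = [
    "NGramIndex",
    "MetricResult",
    "ngram_counts",
    "brevity_penalty",
    "Bleu",
    "RougeL",
    "Meteor",
    "Cider",
    "bleu",
    "rouge_l",
    "meteor",
    "cider",
    "evaluate_all",
    "make_metric",
]


def ngram_counts(report: Report | Sequence[str], k: int) -> Counter:
    """Multiset of contiguous k-grams of a report (sliding window)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tokens = tuple(report)
    return Counter(tokens[i : i + k] for i in range(len(tokens) - k + 1))


def brevity_penalty(n_c: int, n_r: int) -> float:
    """BLEU brevity penalty min(1, exp(1 - n_R/n_C)); 0 when the candidate side is empty."""
    if n_c == 0:
        return 0.0
    return min(1.0, math.exp(1.0 - n_r / n_c))


@dataclass
class NGramIndex:
    """Per-k corpus occurrence counts, document frequencies and idf weights.

    idf(w) = ln(N / df(w)); unseen k-grams get their document frequency floored
    at 1, so idf(w) = ln(N).  A k-gram occurring in every indexed report has
    idf 0 and contributes nothing to tf-idf similarity.
    """

    n_reports: int
    k_max: int
    counts: dict[int, Counter]
    doc_freq: dict[int, Counter]
    length_hist: Counter
    total_tokens: int

    @classmethod
    def build(cls, reports: Sequence[Report], k_max: int = 4) -> "NGramIndex":
        counts: dict[int, Counter] = {k: Counter() for k in range(1, k_max + 1)}
        doc_freq: dict[int, Counter] = {k: Counter() for k in range(1, k_max + 1)}
        length_hist: Counter = Counter()
        total = 0
        for r in reports:
            length_hist[len(r)] += 1
            total += len(r)
            for k in range(1, k_max + 1):
                c = ngram_counts(r, k)
                counts[k].update(c)
                doc_freq[k].update(c.keys())
        return cls(len(reports), k_max, counts, doc_freq, length_hist, total)

    def idf(self, gram: tuple[str, ...]) -> float:
        df = self.doc_freq[len(gram)].get(gram, 0)
        return math.log(self.n_reports / max(df, 1))


@dataclass
class MetricResult:
    """A named corpus score, with per-record scores for pairwise-averaged metrics."""

    name: str
    corpus_score: float
    params: dict = field(default_factory=dict)
    per_item_scores: Optional[np.ndarray] = None


class _MeanMetric:
    """Base for per-pair metrics whose corpus score is the arithmetic mean.

    Sufficient statistics per record are (pair score, 1), so a resampled
    corpus score is exactly the mean over the resampled pair scores.
    """

    name: str = "mean-metric"
    params: dict = {}

    def pair_score(self, cand: Report, ref: Report) -> float:  # pragma: no cover
        raise NotImplementedError

    def item_stats(self, refs: Sequence[Report], cands: Sequence[Report]) -> np.ndarray:
        stats = np.empty((len(refs), 2), dtype=float)
        for i, (r, c) in enumerate(zip(refs, cands)):
            stats[i, 0] = self.pair_score(c, r)
            stats[i, 1] = 1.0
        return stats

    def score_from_stats(self, totals: np.ndarray) -> float:
        return float(totals[0] / totals[1])

    def corpus_score(self, refs: Sequence[Report], cands: Sequence[Report]) -> float:
        stats = self.item_stats(refs, cands)
        return self.score_from_stats(stats.sum(axis=0))

    def result(self, corpus: ParallelCorpus) -> MetricResult:
        refs, cands = corpus.references, corpus.candidates
        stats = self.item_stats(refs, cands)
        return MetricResult(
            self.name,
            self.score_from_stats(stats.sum(axis=0)),
            dict(self.params),
            per_item_scores=stats[:, 0].copy(),
        )


class Bleu:
    """Corpus BLEU-K with pooled clipped k-gram counts.

    Statistics per record: [n_c, n_r, match_1..K, candidate k-gram totals 1..K].
    """

    def __init__(self, k: int = 4, dialect: str = "coco"):
        if k < 1:
            raise ValueError("K must be >= 1")
        if dialect not in ("paper", "coco"):
            raise ValueError(f"unknown BLEU dialect {dialect!r}")
        self.k = k
        self.dialect = dialect
        self.name = f"bleu-{k}"
        self.params = {"dialect": dialect, "K": k}

    def item_stats(self, refs: Sequence[Report], cands: Sequence[Report]) -> np.ndarray:
        k = self.k
        stats = np.zeros((len(refs), 2 + 2 * k), dtype=float)
        for i, (r, c) in enumerate(zip(refs, cands)):
            stats[i, 0] = len(c)
            stats[i, 1] = len(r)
            for kk in range(1, k + 1):
                cc = ngram_counts(c, kk)
                rc = ngram_counts(r, kk)
                match = sum(min(n, rc.get(g, 0)) for g, n in cc.items())
                stats[i, 1 + kk] = match
                stats[i, 1 + k + kk] = max(0, len(c) - kk + 1)
        return stats

    def score_from_stats(self, totals: np.ndarray) -> float:
        n_c = totals[0]
        n_r = totals[1]
        if n_c == 0:
            return 0.0
        bp = brevity_penalty(n_c, n_r)
        matches = totals[2 : 2 + self.k]
        if self.dialect == "paper":
            return float(bp * matches.sum() / n_c)
        denoms = totals[2 + self.k : 2 + 2 * self.k]
        if np.any(denoms == 0) or np.any(matches == 0):
            return 0.0
        log_precisions = np.log(matches / denoms)
        return float(bp * math.exp(log_precisions.mean()))

    def corpus_score(self, refs: Sequence[Report], cands: Sequence[Report]) -> float:
        return self.score_from_stats(self.item_stats(refs, cands).sum(axis=0))

    def result(self, corpus: ParallelCorpus) -> MetricResult:
        score = self.corpus_score(corpus.references, corpus.candidates)
        return MetricResult(self.name, score, dict(self.params))


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Length of the longest common subsequence (classic dynamic program)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, start=1):
            if x == y:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


class RougeL(_MeanMetric):
    """ROUGE-L F-score per pair (LCS-based), averaged over the corpus."""

    def __init__(self, beta: float = 1.2):
        if beta <= 0:
            raise ValueError("beta must be > 0")
        self.beta = beta
        self.name = "rouge-l"
        self.params = {"beta": beta}

    def pair_score(self, cand: Report, ref: Report) -> float:
        lcs = _lcs_length(tuple(cand), tuple(ref))
        if lcs == 0:
            return 0.0
        p = lcs / len(cand)
        r = lcs / len(ref)
        b2 = self.beta**2
        return (1 + b2) * p * r / (b2 * p + r)


def _meteor_matches_chunks(cand: Sequence[str], ref: Sequence[str]) -> tuple[int, int]:
    """Exact-surface unigram matches and chunk count via longest-run greedy alignment.

    Repeatedly aligns the longest contiguous run of unused identical tokens;
    each run is one chunk.  The total number of matched tokens equals the
    clipped unigram match count Σ_w min(occ(w,c), occ(w,r)).
    """
    used_c = [False] * len(cand)
    used_r = [False] * len(ref)
    matches = 0
    chunks = 0
    while True:
        best_len = 0
        best = (0, 0)
        for i in range(len(cand)):
            if used_c[i]:
                continue
            for j in range(len(ref)):
                if used_r[j] or cand[i] != ref[j]:
                    continue
                length = 0
                while (
                    i + length < len(cand)
                    and j + length < len(ref)
                    and not used_c[i + length]
                    and not used_r[j + length]
                    and cand[i + length] == ref[j + length]
                ):
                    length += 1
                if length > best_len:
                    best_len = length
                    best = (i, j)
        if best_len == 0:
            break
        i, j = best
        for t in range(best_len):
            used_c[i + t] = True
            used_r[j + t] = True
        matches += best_len
        chunks += 1
    return matches, chunks


class Meteor(_MeanMetric):
    """METEOR with exact surface matching and a cubed chunk penalty.

    Per pair: (1 - 0.5·CP³)·(10·P·R)/(9·P + R) with CP = chunks/matches,
    P = matches/|c|, R = matches/|r|; zero matches score 0.
    """

    def __init__(self) -> None:
        self.name = "meteor"
        self.params = {}

    def pair_score(self, cand: Report, ref: Report) -> float:
        c, r = tuple(cand), tuple(ref)
        if not c or not r:
            return 0.0
        matches, chunks = _meteor_matches_chunks(c, r)
        if matches == 0:
            return 0.0
        p = matches / len(c)
        rec = matches / len(r)
        fmean = 10 * p * rec / (9 * p + rec)
        cp = chunks / matches
        return (1 - 0.5 * cp**3) * fmean


def _length_penalty(lc: int, lr: int, sigma: float, mode: str) -> float:
    if mode == "squared":
        return math.exp(-((lc - lr) ** 2) / (2 * sigma**2))
    if mode == "literal":
        # Non-standard variant: exponent linear in the signed length difference.
        return math.exp(-(lc - lr) / (2 * sigma**2))
    raise ValueError(f"unknown length penalty mode {mode!r}")


class Cider(_MeanMetric):
    """CIDEr / CIDEr-D consensus metric over tf-idf weighted k-gram vectors.

    tf is the k-gram count normalised by the report's total k-gram count;
    idf comes from an :class:`NGramIndex` built over the reference side (or a
    declared training corpus).  The ``d`` variant clips candidate counts at
    the reference counts (min(g(c), g(r))·g(r)), applies a Gaussian penalty
    on the report-length difference, and scales by 10.
    """

    def __init__(
        self,
        k: int = 4,
        variant: str = "d",
        sigma: float = 6.0,
        index: Optional[NGramIndex] = None,
        length_penalty: str = "squared",
    ):
        if k < 1:
            raise ValueError("K must be >= 1")
        if variant not in ("plain", "d"):
            raise ValueError(f"unknown CIDEr variant {variant!r}")
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        self.k = k
        self.variant = variant
        self.sigma = sigma
        self.index = index
        self.length_penalty = length_penalty
        self.name = "cider-d" if variant == "d" else "cider"
        self.params = {"K": k, "variant": variant, "sigma": sigma}

    def _require_index(self, refs: Sequence[Report]) -> NGramIndex:
        if self.index is not None:
            return self.index
        return NGramIndex.build(refs, self.k)

    def vectors(self, report: Report, index: NGramIndex) -> list[tuple[dict, float]]:
        """Per k: tf-idf weight dict and its Euclidean norm."""
        out = []
        for kk in range(1, self.k + 1):
            counts = ngram_counts(report, kk)
            total = sum(counts.values())
            vec: dict = {}
            if total:
                for g, n in counts.items():
                    vec[g] = (n / total) * index.idf(g)
            norm = math.sqrt(sum(w * w for w in vec.values()))
            out.append((vec, norm))
        return out

    def pair_score_vectors(
        self,
        cvecs: list[tuple[dict, float]],
        rvecs: list[tuple[dict, float]],
        lc: int,
        lr: int,
    ) -> float:
        total = 0.0
        for (cv, cn), (rv, rn) in zip(cvecs, rvecs):
            if cn == 0.0 or rn == 0.0:
                continue
            if self.variant == "plain":
                dot = sum(w * rv[g] for g, w in cv.items() if g in rv)
                total += dot / (cn * rn)
            else:
                dot = sum(min(w, rv[g]) * rv[g] for g, w in cv.items() if g in rv)
                pen = _length_penalty(lc, lr, self.sigma, self.length_penalty)
                total += pen * dot / (cn * rn)
        score = total / self.k
        return 10.0 * score if self.variant == "d" else score

    def pair_score(self, cand: Report, ref: Report) -> float:
        if self.index is None:
            raise ValueError(
                "per-pair CIDEr needs an NGramIndex built over a reference corpus"
            )
        return self.pair_score_vectors(
            self.vectors(cand, self.index),
            self.vectors(ref, self.index),
            len(cand),
            len(ref),
        )

    def item_stats(self, refs: Sequence[Report], cands: Sequence[Report]) -> np.ndarray:
        index = self._require_index(refs)
        stats = np.empty((len(refs), 2), dtype=float)
        for i, (r, c) in enumerate(zip(refs, cands)):
            score = self.pair_score_vectors(
                self.vectors(c, index), self.vectors(r, index), len(c), len(r)
            )
            stats[i, 0] = score
            stats[i, 1] = 1.0
        return stats


def bleu(corpus: ParallelCorpus, k: int = 4, dialect: str = "coco") -> MetricResult:
    return Bleu(k, dialect).result(corpus)


def rouge_l(corpus: ParallelCorpus, beta: float = 1.2) -> MetricResult:
    return RougeL(beta).result(corpus)


def meteor(corpus: ParallelCorpus) -> MetricResult:
    return Meteor().result(corpus)


def cider(
    corpus: ParallelCorpus,
    k: int = 4,
    variant: str = "d",
    sigma: float = 6.0,
    index: Optional[NGramIndex] = None,
) -> MetricResult:
    return Cider(k, variant, sigma, index).result(corpus)


def make_metric(spec, index: Optional[NGramIndex] = None, lexicon=None):
    """Instantiate a metric from a name or an options mapping.

    Names: ``bleu-1`` .. ``bleu-4`` (coco dialect), ``rouge-l``, ``meteor``,
    ``cider``, ``cider-d``, ``label-accuracy``.  A mapping form
    ``{"name": "bleu", "K": 4, "dialect": "paper"}`` exposes the options.
    """
    if isinstance(spec, str):
        spec = {"name": spec}
    name = spec["name"].lower()
    if name.startswith("bleu"):
        k = spec.get("K")
        if k is None:
            k = int(name.split("-")[1]) if "-" in name else 4
        return Bleu(k=k, dialect=spec.get("dialect", "coco"))
    if name in ("rouge", "rouge-l"):
        return RougeL(beta=spec.get("beta", 1.2))
    if name == "meteor":
        return Meteor()
    if name in ("cider", "cider-d"):
        variant = spec.get("variant", "d" if name == "cider-d" else "plain")
        return Cider(
            k=spec.get("K", 4),
            variant=variant,
            sigma=spec.get("sigma", 6.0),
            index=index,
        )
    if name in ("accuracy", "label-accuracy"):
        from .labels import LabelAccuracy, default_lexicon

        return LabelAccuracy(lexicon if lexicon is not None else default_lexicon())
    raise ValueError(f"unknown metric {spec['name']!r}")


def evaluate_all(
    corpus: ParallelCorpus,
    metric_spec: Sequence,
    index: Optional[NGramIndex] = None,
    lexicon=None,
) -> list[MetricResult]:
    """Run a list of configured metrics with a shared reference-side n-gram index."""
    if not metric_spec:
        return []
    if index is None and any(
        (m if isinstance(m, str) else m["name"]).lower().startswith("cider")
        for m in metric_spec
    ):
        index = NGramIndex.build(corpus.references, 4)
    results = []
    for spec in metric_spec:
        metric = make_metric(spec, index=index, lexicon=lexicon)
        results.append(metric.result(corpus))
    return results
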