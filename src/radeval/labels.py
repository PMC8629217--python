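"""Rule-based diagnostic label extraction and label-accuracy scoring.

A small, configurable stand-in for an external rule-based chest-finding
labeler: each category is marked positive when one of its mention phrases
occurs without a negation cue in the few tokens immediately preceding the
match, and negative otherwise (no-mention counts as negative).  Values are
binary; the real external tool's "uncertain"/"blank" outputs are collapsed
to negative and are unsupported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus import Report

__all__ = [
    "DEFAULT_CATEGORIES",
    "LabelVector",
    "Lexicon",
    "default_lexicon",
    "load_lexicon",
    "extract_labels",
    "label_accuracy",
    "LabelAccuracy",
    "load_label_table",
    "save_label_table",
]

# 14 finding categories following the CheXpert convention. no_finding is an
# ordinary category here (normality is encoded as the all-negative state).
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "enlarged_cardiomediastinum",
    "cardiomegaly",
    "lung_opacity",
    "lung_lesion",
    "edema",
    "consolidation",
    "pneumonia",
    "atelectasis",
    "pneumothorax",
    "pleural_effusion",
    "pleural_other",
    "fracture",
    "support_devices",
    "no_finding",
)


@dataclass(frozen=True)
class LabelVector:
    """Binary positive/negative findings over a fixed, ordered category list."""

    categories: tuple[str, ...]
    values: tuple[bool, ...]  # True = positive

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.values):
            raise ValueError("category and value lists differ in length")

    def __getitem__(self, category: str) -> bool:
        return self.values[self.categories.index(category)]

    @property
    def any_positive(self) -> bool:
        return any(self.values)

    def as_dict(self) -> dict[str, str]:
        return {
            c: ("positive" if v else "negative")
            for c, v in zip(self.categories, self.values)
        }


@dataclass(frozen=True)
class Lexicon:
    """Per-category mention phrases plus negation cues and a preceding-token window."""

    categories: tuple[str, ...]
    phrases: dict[str, tuple[tuple[str, ...], ...]]
    cues: dict[str, tuple[str, ...]]
    window: int = 3

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("negation window must be >= 1")
        for cat in self.categories:
            if not self.phrases.get(cat):
                raise ValueError(f"category {cat!r} has no mention phrases")


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon from YAML (categories -> phrases; shared or per-category cues)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _lexicon_from_mapping(raw)


def _lexicon_from_mapping(raw: dict) -> Lexicon:
    window = int(raw.get("window", 3))
    global_cues = tuple(raw.get("cues", ()))
    categories = tuple(raw["categories"].keys())
    phrases = {}
    cues = {}
    for cat, entry in raw["categories"].items():
        phrases[cat] = tuple(tuple(p) for p in entry["phrases"])
        cues[cat] = tuple(entry.get("cues", global_cues))
    return Lexicon(categories, phrases, cues, window)


def default_lexicon() -> Lexicon:
    raw = yaml.safe_load(
        resources.files("radeval.data").joinpath("lexicon.yaml").read_text("utf-8")
    )
    return _lexicon_from_mapping(raw)


def _phrase_positions(tokens: tuple[str, ...], phrase: tuple[str, ...]) -> list[int]:
    n = len(phrase)
    return [
        i
        for i in range(len(tokens) - n + 1)
        if tokens[i : i + n] == tuple(phrase)
    ]


def extract_labels(report: Report, lexicon: Lexicon) -> LabelVector:
    """Positive iff some mention of the category is not negated in its preceding window."""
    tokens = tuple(report)
    values = []
    for cat in lexicon.categories:
        cues = set(lexicon.cues.get(cat, ()))
        positive = False
        for phrase in lexicon.phrases[cat]:
            for start in _phrase_positions(tokens, phrase):
                window = tokens[max(0, start - lexicon.window) : start]
                if not any(t in cues for t in window):
                    positive = True
                    break
            if positive:
                break
        values.append(positive)
    return LabelVector(lexicon.categories, tuple(values))


def label_accuracy(
    candidates: Sequence[LabelVector],
    references: Sequence[LabelVector],
    average: str = "micro",
) -> float:
    """Fraction of agreeing (report, category) cells; ``macro`` averages per category."""
    if len(candidates) != len(references):
        raise ValueError("candidate and reference label lists differ in length")
    if not candidates:
        raise ValueError("empty label lists")
    cats = candidates[0].categories
    for v in list(candidates) + list(references):
        if v.categories != cats:
            raise ValueError("mismatched category lists")
    agree = np.array(
        [
            [cv == rv for cv, rv in zip(c.values, r.values)]
            for c, r in zip(candidates, references)
        ],
        dtype=float,
    )
    if average == "micro":
        return float(agree.mean())
    if average == "macro":
        return float(agree.mean(axis=0).mean())
    raise ValueError(f"unknown average {average!r}")


class LabelAccuracy:
    """Corpus metric: micro-averaged label agreement between candidate and reference reports.

    Statistics per record: [agreeing cells, total cells], so bootstrap
    resamples recompute the micro-average exactly.
    """

    def __init__(self, lexicon: Lexicon, average: str = "micro"):
        self.lexicon = lexicon
        self.average = average
        self.name = "label-accuracy"
        self.params = {"average": average}
        self._cache: dict[tuple[str, ...], LabelVector] = {}

    def _labels(self, report: Report) -> LabelVector:
        key = tuple(report)
        out = self._cache.get(key)
        if out is None:
            out = extract_labels(report, self.lexicon)
            self._cache[key] = out
        return out

    def item_stats(self, refs: Sequence[Report], cands: Sequence[Report]) -> np.ndarray:
        n_cat = len(self.lexicon.categories)
        stats = np.empty((len(refs), 2), dtype=float)
        for i, (r, c) in enumerate(zip(refs, cands)):
            rv = self._labels(r)
            cv = self._labels(c)
            stats[i, 0] = sum(a == b for a, b in zip(rv.values, cv.values))
            stats[i, 1] = n_cat
        return stats

    def score_from_stats(self, totals: np.ndarray) -> float:
        return float(totals[0] / totals[1])

    def corpus_score(self, refs: Sequence[Report], cands: Sequence[Report]) -> float:
        return self.score_from_stats(self.item_stats(refs, cands).sum(axis=0))

    def result(self, corpus):
        from .metrics import MetricResult

        stats = self.item_stats(corpus.references, corpus.candidates)
        return MetricResult(
            self.name,
            self.score_from_stats(stats.sum(axis=0)),
            dict(self.params),
            per_item_scores=stats[:, 0] / stats[:, 1],
        )


_TRUE = {"positive", "1", "true"}
_FALSE = {"negative", "0", "false"}


def load_label_table(
    path: str | Path, categories: Sequence[str] | None = None
) -> list[LabelVector]:
    """Read per-report labels from CSV (id column + one column per category)."""
    frame = pd.read_csv(path, dtype=str)
    cols = [c for c in frame.columns if c != "id"]
    if categories is not None:
        unknown = set(cols) - set(categories)
        if unknown:
            raise ValueError(f"unknown category columns: {sorted(unknown)}")
        missing = set(categories) - set(cols)
        if missing:
            raise ValueError(f"missing category columns: {sorted(missing)}")
        cols = list(categories)
    cats = tuple(cols)
    vectors = []
    for i, row in frame.iterrows():
        values = []
        for c in cols:
            cell = row[c]
            if pd.isna(cell):
                raise ValueError(f"missing label cell at row {i}, column {c!r}")
            cell = str(cell).strip().lower()
            if cell in _TRUE:
                values.append(True)
            elif cell in _FALSE:
                values.append(False)
            else:
                raise ValueError(f"invalid label value {cell!r} at row {i}, column {c!r}")
        vectors.append(LabelVector(cats, tuple(values)))
    return vectors


def save_label_table(
    vectors: Sequence[LabelVector], path: str | Path, ids: Sequence[str] | None = None
) -> None:
    if not vectors:
        raise ValueError("no label vectors to write")
    cats = vectors[0].categories
    rows = []
    for i, v in enumerate(vectors):
        row = {"id": ids[i] if ids is not None else f"r{i + 1}"}
        row.update(v.as_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=["id", *cats]).to_csv(path, index=False)
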