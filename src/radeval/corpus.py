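"""Report/corpus containers and text normalisation.

Radiology reports are compared at the token level: a report is an ordered
sequence of lowercase alphabetic word tokens.  Cleaning drops every maximal
run of non-alphabetic characters (so ``"5 cm,"`` yields only ``cm``), keeps
stop words, and applies no stemming.  De-identification placeholders
(``xxxx`` and friends — any run of x's) are removed by default.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

__all__ = [
    "Report",
    "Record",
    "ParallelCorpus",
    "CorpusSummary",
    "preprocess_text",
    "load_parallel_corpus",
    "save_parallel_corpus",
    "corpus_summary",
]

_NON_ALPHA = re.compile(r"[^A-Za-z]+")
_PLACEHOLDER = re.compile(r"^x+$")


@dataclass(frozen=True)
class Report:
    """An ordered sequence of lowercase alphabetic word tokens."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        for t in self.tokens:
            if not t or not t.isalpha() or t != t.lower():
                raise ValueError(
                    f"report token {t!r} is not a nonempty lowercase alphabetic word"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def preprocess_text(raw: str, drop_placeholders: bool = True) -> Report:
    """Clean free text into a :class:`Report`.

    Splits on maximal runs of non-alphabetic characters, lowercases, and
    optionally drops de-identification placeholders (tokens that are a pure
    run of x's, any casing/length).  Empty input yields an empty report.
    """
    tokens = [t.lower() for t in _NON_ALPHA.split(raw) if t]
    if drop_placeholders:
        tokens = [t for t in tokens if not _PLACEHOLDER.match(t)]
    return Report(tuple(tokens))


@dataclass(frozen=True)
class Record:
    """One aligned test-set record: reference report, optional candidate, optional stratum tag."""

    id: str
    reference: Report
    candidate: Optional[Report] = None
    tag: Optional[str] = None


@dataclass(frozen=True)
class ParallelCorpus:
    """Ordered aligned records of reference and (optionally) candidate reports."""

    records: tuple[Record, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a corpus must contain at least one record")
        ids = [rec.id for rec in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    @property
    def references(self) -> list[Report]:
        return [rec.reference for rec in self.records]

    @property
    def has_candidates(self) -> bool:
        return all(rec.candidate is not None for rec in self.records)

    @property
    def candidates(self) -> list[Report]:
        cands = []
        for rec in self.records:
            if rec.candidate is None:
                raise ValueError(f"record {rec.id!r} has no candidate report")
            cands.append(rec.candidate)
        return cands

    def with_candidates(self, candidates: Sequence[Report]) -> "ParallelCorpus":
        if len(candidates) != len(self.records):
            raise ValueError("candidate list length does not match corpus size")
        return ParallelCorpus(
            tuple(
                Record(rec.id, rec.reference, cand, rec.tag)
                for rec, cand in zip(self.records, candidates)
            )
        )

    def subset(self, indices: Sequence[int]) -> list[Record]:
        """Records at the given positions (duplicates allowed, e.g. bootstrap resamples)."""
        return [self.records[i] for i in indices]


@dataclass(frozen=True)
class CorpusSummary:
    n_reports: int
    total_tokens: int
    mean_report_length: float
    vocabulary_size: int


def corpus_summary(corpus: ParallelCorpus, side: str = "reference") -> CorpusSummary:
    """Token counts of one side of the corpus; errors if the side is missing anywhere."""
    if side == "reference":
        reports = corpus.references
    elif side == "candidate":
        reports = corpus.candidates
    else:
        raise ValueError(f"unknown side {side!r}")
    total = sum(len(r) for r in reports)
    vocab = set()
    for r in reports:
        vocab.update(r.tokens)
    return CorpusSummary(
        n_reports=len(reports),
        total_tokens=total,
        mean_report_length=total / len(reports),
        vocabulary_size=len(vocab),
    )


def _record_from_obj(obj: dict, lineno: int, drop_placeholders: bool) -> Record:
    if "reference" not in obj:
        raise ValueError(f"record on line {lineno} is missing the 'reference' field")
    rid = str(obj.get("id", f"r{lineno}"))
    reference = preprocess_text(str(obj["reference"]), drop_placeholders)
    candidate = None
    if obj.get("candidate") is not None:
        candidate = preprocess_text(str(obj["candidate"]), drop_placeholders)
    tag = obj.get("tag")
    return Record(rid, reference, candidate, None if tag is None else str(tag))


def load_parallel_corpus(
    path: str | Path,
    format: str = "jsonl",
    candidate_path: str | Path | None = None,
    drop_placeholders: bool = True,
) -> ParallelCorpus:
    """Read a parallel corpus and preprocess every report.

    Formats: ``jsonl`` (one object per line, keys id/reference/candidate/tag),
    ``text_pair`` (reference file plus optional parallel candidate file, one
    report per line), ``csv`` (columns id, reference, optional candidate/tag).
    """
    path = Path(path)
    records: list[Record] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                obj = json.loads(line)
                records.append(_record_from_obj(obj, lineno, drop_placeholders))
    elif format == "text_pair":
        refs = path.read_text(encoding="utf-8").splitlines()
        cands = None
        if candidate_path is not None:
            cands = Path(candidate_path).read_text(encoding="utf-8").splitlines()
            if len(cands) != len(refs):
                raise ValueError("reference and candidate files differ in line count")
        for i, line in enumerate(refs, start=1):
            cand = preprocess_text(cands[i - 1], drop_placeholders) if cands else None
            records.append(Record(f"r{i}", preprocess_text(line, drop_placeholders), cand))
    elif format == "csv":
        import pandas as pd

        frame = pd.read_csv(path, dtype=str).fillna("")
        if "reference" not in frame.columns:
            raise ValueError("csv corpus is missing the 'reference' column")
        for i, row in enumerate(frame.to_dict("records"), start=1):
            obj = {k: (v if v != "" else None) for k, v in row.items()}
            if obj.get("reference") is None:
                raise ValueError(f"record on line {i} is missing the 'reference' field")
            records.append(_record_from_obj(obj, i, drop_placeholders))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return ParallelCorpus(tuple(records))


def save_parallel_corpus(corpus: ParallelCorpus, path: str | Path) -> None:
    """Write a corpus as JSON Lines (reports re-joined with single spaces)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus:
            obj: dict = {"id": rec.id, "reference": rec.reference.text}
            if rec.candidate is not None:
                obj["candidate"] = rec.candidate.text
            if rec.tag is not None:
                obj["tag"] = rec.tag
            fh.write(json.dumps(obj) + "\n")
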