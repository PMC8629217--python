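"""Synthetic chest-X-ray report corpus and a tunable simulated generator.

Emulates the statistical structure of standardised chest-X-ray reporting:
one sentence per anatomical topic (heart size, lungs, pulmonary
vasculature, bones) drawn from small shared sentence banks, about 70% fully
normal reports, negation phrasing in normal sentences, and a known true
finding vector per report.  A simulated report generator renders candidates
from either the record's own findings (conditioning strength rho) or from
corpus-marginal findings, with optional word-substitution noise, so the
dependence of a "model" on its input can be dialled from zero to perfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .corpus import ParallelCorpus, Record, Report, preprocess_text
from .labels import DEFAULT_CATEGORIES, LabelVector

__all__ = [
    "TemplateBank",
    "GeneratorConfig",
    "SyntheticRecord",
    "default_templates",
    "generate_references",
    "simulate_model",
    "records_to_corpus",
]


@dataclass(frozen=True)
class TemplateBank:
    """Per-topic normal/abnormal sentence banks (already tokenised)."""

    topics: tuple[str, ...]
    topic_category: dict[str, str]
    normal: dict[str, tuple[Report, ...]]
    abnormal: dict[str, tuple[Report, ...]]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        for t in self.topics:
            if not self.normal[t] or not self.abnormal[t]:
                raise ValueError(f"topic {t!r} needs >= 1 normal and abnormal template")


def default_templates() -> TemplateBank:
    raw = yaml.safe_load(
        resources.files("radeval.data").joinpath("templates.yaml").read_text("utf-8")
    )
    topics, cat, normal, abnormal = [], {}, {}, {}
    for entry in raw["topics"]:
        name = entry["name"]
        topics.append(name)
        cat[name] = entry["category"]
        normal[name] = tuple(preprocess_text(s) for s in entry["normal"])
        abnormal[name] = tuple(preprocess_text(s) for s in entry["abnormal"])
    return TemplateBank(
        tuple(topics), cat, normal, abnormal, tuple(raw["template_weights"])
    )


@dataclass
class GeneratorConfig:
    """Study conditions for reference generation.

    ``normal_fraction`` defaults to 0.70 (the share of fully normal
    chest-X-ray reports); sentence banks target a mean report length of
    roughly 30 tokens.  ``abnormal_category_probs`` are per-finding
    probabilities conditional on the report being abnormal (at least one
    positive finding is guaranteed).
    """

    n_reports: int = 100
    normal_fraction: float = 0.70
    abnormal_category_probs: dict[str, float] = field(
        default_factory=lambda: {
            "cardiomegaly": 0.50,
            "pleural_effusion": 0.45,
            "edema": 0.35,
            "fracture": 0.25,
        }
    )
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    templates: Optional[TemplateBank] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not 0 <= self.normal_fraction <= 1:
            raise ValueError("normal_fraction must be in [0, 1]")
        for cat, p in self.abnormal_category_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {cat!r} out of [0, 1]")
            if cat not in self.categories:
                raise ValueError(f"unknown category {cat!r}")


@dataclass(frozen=True)
class SyntheticRecord:
    id: str
    reference: Report
    labels: LabelVector
    tag: str  # "normal" iff all labels negative


def _render(
    labels: LabelVector, bank: TemplateBank, rng: np.random.Generator
) -> Report:
    """One sentence per topic, abnormal variant when the topic's finding is positive."""
    weights = np.asarray(bank.weights, dtype=float)
    tokens: list[str] = []
    for topic in bank.topics:
        positive = labels[bank.topic_category[topic]]
        pool = bank.abnormal[topic] if positive else bank.normal[topic]
        w = weights[: len(pool)]
        choice = int(rng.choice(len(pool), p=w / w.sum()))
        tokens.extend(pool[choice].tokens)
    return Report(tuple(tokens))


def _sample_labels(
    config: GeneratorConfig, rng: np.random.Generator
) -> LabelVector:
    values = {c: False for c in config.categories}
    if rng.random() >= config.normal_fraction:
        cats = list(config.abnormal_category_probs)
        probs = np.array([config.abnormal_category_probs[c] for c in cats])
        draw = rng.random(len(cats)) < probs
        if not draw.any():
            forced = rng.choice(len(cats), p=probs / probs.sum())
            draw[forced] = True
        for c, d in zip(cats, draw):
            values[c] = bool(d)
    return LabelVector(config.categories, tuple(values[c] for c in config.categories))


def generate_references(config: GeneratorConfig) -> list[SyntheticRecord]:
    """Deterministically (under the seed) generate reference records with true labels."""
    bank = config.templates or default_templates()
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_reports):
        labels = _sample_labels(config, rng)
        reference = _render(labels, bank, rng)
        tag = "abnormal" if labels.any_positive else "normal"
        records.append(SyntheticRecord(f"r{i + 1:05d}", reference, labels, tag))
    return records


def _marginal_rates(
    records: Sequence[SyntheticRecord],
) -> tuple[tuple[str, ...], np.ndarray]:
    cats = records[0].labels.categories
    mat = np.array([[v for v in rec.labels.values] for rec in records], dtype=float)
    return cats, mat.mean(axis=0)


def simulate_model(
    records: Sequence[SyntheticRecord],
    rho: float,
    noise: float = 0.0,
    seed: int = 0,
    templates: Optional[TemplateBank] = None,
) -> list[Report]:
    """Render candidate reports with conditioning strength rho and word noise.

    With probability rho a candidate is rendered from the record's own true
    findings, otherwise from findings drawn at the corpus marginal rates;
    tokens are then substituted with in-vocabulary tokens at rate ``noise``.
    rho = 0 is a fully unconditioned generator, rho = 1 a perfect one.
    """
    if not 0 <= rho <= 1 or not 0 <= noise <= 1:
        raise ValueError("rho and noise must be in [0, 1]")
    if not records:
        return []
    bank = templates or default_templates()
    rng = np.random.default_rng(seed)
    cats, rates = _marginal_rates(records)
    vocab = sorted({t for rec in records for t in rec.reference.tokens})
    out = []
    for rec in records:
        if rng.random() < rho:
            labels = rec.labels
        else:
            draw = rng.random(len(cats)) < rates
            labels = LabelVector(cats, tuple(bool(d) for d in draw))
        tokens = list(_render(labels, bank, rng).tokens)
        if noise > 0:
            for t in range(len(tokens)):
                if rng.random() < noise:
                    tokens[t] = vocab[int(rng.integers(len(vocab)))]
        out.append(Report(tuple(tokens)))
    return out


def records_to_corpus(
    records: Sequence[SyntheticRecord],
    candidates: Optional[Sequence[Report]] = None,
) -> ParallelCorpus:
    """Assemble synthetic records (and optional candidates) into a parallel corpus."""
    recs = []
    for i, rec in enumerate(records):
        cand = candidates[i] if candidates is not None else None
        recs.append(Record(rec.id, rec.reference, cand, rec.tag))
    return ParallelCorpus(tuple(recs))
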