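"""Per-pair classification under the three regimes.

The binary and zero-shot regimes decompose the 7-way decision into 7
independent yes/no prompts; when several answer positively, the conflict is
resolved in favour of the relation type with the smallest training sample
count (rarer types are less likely to be predicted spuriously), with ties
broken by the fixed schema declaration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .backend import Backend, BackendError, CompletionRequest, parse_answer
from .context import RelationInstance, enumerate_pairs
from .prompts import (
    ExampleBank,
    build_binary_prompt,
    build_multiclass_prompt,
    build_zeroshot_prompt,
)
from .schema import ALL_LABELS, NONE_LABEL, RELATION_LABELS

__all__ = [
    "TrainingCounts",
    "classify_multiclass",
    "classify_binary_all",
    "classify_zeroshot_all",
    "resolve_conflict",
    "classify_instance",
    "run_extraction",
    "PredictionRecord",
]

logger = logging.getLogger(__name__)

REGIMES = ("multiclass", "binary", "zeroshot")

#: Deterministic tie-break for conflict resolution: the order in which the
#: relation types are defined by the annotation guideline.
TIE_BREAK_ORDER: tuple[str, ...] = (
    "BEGINS-AT",
    "ENDS-AT",
    "BEFORE",
    "BEFORE-OVERLAP",
    "SIMULTANEOUS",
    "OVERLAP",
    "CONTAINS",
)


@dataclass(frozen=True)
class TrainingCounts:
    """Per-relation sample counts used by rarity-based conflict resolution."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(RELATION_LABELS) - set(self.counts)
        if missing:
            raise ValueError(f"counts missing relation types: {sorted(missing)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    def __getitem__(self, label: str) -> int:
        return self.counts[label]

    @classmethod
    def from_bank(cls, bank: ExampleBank) -> "TrainingCounts":
        """Counts from the curated example bank (the default source)."""
        return cls(counts=bank.counts())

    @classmethod
    def from_table1(cls) -> "TrainingCounts":
        """Documented alternative: the published per-type relation totals."""
        from .synth import table1_fixture

        totals = table1_fixture().sum(axis=0)
        return cls(counts={label: int(totals[label]) for label in RELATION_LABELS})


def _request(prompt_text: str, instance: RelationInstance, regime: str,
             relation: str | None = None) -> CompletionRequest:
    meta = {
        "doc_id": instance.doc_id,
        "source_id": instance.source.id,
        "target_id": instance.target.id,
        "regime": regime,
    }
    if relation is not None:
        meta["relation"] = relation
    return CompletionRequest(prompt=prompt_text, metadata=meta)


def classify_multiclass(
    instance: RelationInstance, bank: ExampleBank, backend: Backend
) -> str:
    """One 8-way prompt; returns a label from the full vocabulary."""
    spec = build_multiclass_prompt(bank, instance)
    raw = backend.complete(_request(spec.render(), instance, "multiclass"))
    return parse_answer(raw, ALL_LABELS).label


def _binary_sweep(
    instance: RelationInstance,
    backend: Backend,
    prompt_for: dict[str, str],
    regime: str,
) -> set[str]:
    positives: set[str] = set()
    for relation in RELATION_LABELS:
        try:
            raw = backend.complete(
                _request(prompt_for[relation], instance, regime, relation=relation)
            )
        except BackendError as exc:
            logger.warning(
                "backend failed for %s on %s; counting as negative: %s",
                relation, instance.key, exc,
            )
            continue
        answer = parse_answer(raw, (relation, NONE_LABEL))
        if answer.label == relation:
            positives.add(relation)
    return positives


def classify_binary_all(
    instance: RelationInstance, bank: ExampleBank, backend: Backend
) -> set[str]:
    """7 independent few-shot yes/no prompts; the positively answered subset."""
    prompts = {
        rel: build_binary_prompt(bank, rel, instance).render()
        for rel in RELATION_LABELS
    }
    return _binary_sweep(instance, backend, prompts, "binary")


def classify_zeroshot_all(instance: RelationInstance, backend: Backend) -> set[str]:
    """7 independent definition-only prompts; the positively answered subset."""
    prompts = {
        rel: build_zeroshot_prompt(rel, instance).render() for rel in RELATION_LABELS
    }
    return _binary_sweep(instance, backend, prompts, "zeroshot")


def resolve_conflict(positives: Iterable[str], counts: TrainingCounts) -> str:
    """Pick one label from a set of positive binary answers.

    Empty set → NONE; otherwise the label with the smallest training count,
    ties broken by the fixed guideline declaration order. Permutation-invariant.
    """
    pos = set(positives)
    unknown = pos - set(RELATION_LABELS)
    if unknown:
        raise ValueError(f"unknown labels in positives: {sorted(unknown)}")
    if not pos:
        return NONE_LABEL
    return min(pos, key=lambda l: (counts[l], TIE_BREAK_ORDER.index(l)))


def classify_instance(
    instance: RelationInstance,
    regime: str,
    backend: Backend,
    bank: ExampleBank | None = None,
    counts: TrainingCounts | None = None,
) -> str:
    """Classify one candidate pair under the chosen regime."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if regime == "multiclass":
        if bank is None:
            raise ValueError("multiclass regime requires an example bank")
        return classify_multiclass(instance, bank, backend)
    if regime == "binary":
        if bank is None:
            raise ValueError("binary regime requires an example bank")
        positives = classify_binary_all(instance, bank, backend)
    else:
        positives = classify_zeroshot_all(instance, backend)
    if counts is None:
        counts = TrainingCounts.from_bank(bank) if bank else TrainingCounts.from_table1()
    return resolve_conflict(positives, counts)


@dataclass(frozen=True)
class PredictionRecord:
    doc_id: str
    source_id: str
    target_id: str
    predicted: str
    gold: str | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.doc_id, self.source_id, self.target_id)


def run_extraction(
    docs: Iterable,
    regime: str,
    backend: Backend,
    bank: ExampleBank | None = None,
    counts: TrainingCounts | None = None,
    window: int = 1000,
) -> list[PredictionRecord]:
    """Classify every candidate pair of every document."""
    records: list[PredictionRecord] = []
    for doc in docs:
        for inst in enumerate_pairs(doc, window=window, gold_corpus=True):
            predicted = classify_instance(
                inst, regime, backend, bank=bank, counts=counts
            )
            records.append(
                PredictionRecord(
                    doc_id=inst.doc_id,
                    source_id=inst.source.id,
                    target_id=inst.target.id,
                    predicted=predicted,
                    gold=inst.gold,
                )
            )
    return records
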