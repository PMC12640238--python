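"""Scoring of predicted relations and pairwise inter-annotator agreement.

Matching is exact on (source entity, target entity, label) — entities are
shared givens in this pipeline, so no partial-span credit exists. Per-label
rows cover the seven relation types; NONE appears only in the confusion
tally. Zero-support labels score F1 = 0 and carry an ``undefined`` flag so
macro averages stay reproducible.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .corpus_io import AnnotatedDocument
from .schema import ALL_LABELS, NONE_LABEL, RELATION_LABELS

__all__ = ["LabelMetrics", "MetricReport", "score", "score_records", "iaa"]


@dataclass(frozen=True)
class LabelMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    undefined: bool = False


@dataclass
class MetricReport:
    per_label: dict[str, LabelMetrics]
    macro_f1: float
    micro_f1: float
    weighted_f1: float
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_label": {
                label: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "support": m.support,
                    "undefined": m.undefined,
                }
                for label, m in self.per_label.items()
            },
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "weighted_f1": self.weighted_f1,
            "confusion": [
                {"gold": g, "predicted": p, "count": n}
                for (g, p), n in sorted(self.confusion.items())
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_table(self) -> str:
        """Plain-text table: one row per relation type plus aggregates."""
        header = f"{'Relation':<16}{'P':>8}{'R':>8}{'F1':>8}{'Support':>9}"
        lines = [header, "-" * len(header)]
        for label in RELATION_LABELS:
            m = self.per_label[label]
            flag = " *" if m.undefined else ""
            lines.append(
                f"{label:<16}{m.precision:>8.3f}{m.recall:>8.3f}"
                f"{m.f1:>8.3f}{m.support:>9d}{flag}"
            )
        lines.append("-" * len(header))
        lines.append(f"{'macro-F1':<16}{self.macro_f1:>32.3f}")
        lines.append(f"{'weighted-F1':<16}{self.weighted_f1:>32.3f}")
        lines.append(f"{'micro-F1':<16}{self.micro_f1:>32.3f}")
        lines.append("(* zero support and zero predictions: F1 undefined, reported as 0)")
        return "\n".join(lines)


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def score(
    predictions: Mapping[tuple, str], gold: Mapping[tuple, str]
) -> MetricReport:
    """Score predicted labels against gold over an identical instance set.

    Both mappings go from an instance key (doc, source, target) to a label;
    instances without a relation carry NONE. Mismatched key sets are an
    error — predictions must cover exactly the evaluated pairs.
    """
    if set(predictions) != set(gold):
        raise ValueError(
            f"prediction and gold instance sets differ "
            f"({len(set(predictions) ^ set(gold))} mismatched keys)"
        )
    for mapping, name in ((predictions, "prediction"), (gold, "gold")):
        bad = set(mapping.values()) - set(ALL_LABELS)
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")

    confusion: Counter[tuple[str, str]] = Counter()
    for key, gold_label in gold.items():
        confusion[(gold_label, predictions[key])] += 1

    per_label: dict[str, LabelMetrics] = {}
    for label in RELATION_LABELS:
        tp = confusion[(label, label)]
        fp = sum(n for (g, p), n in confusion.items() if p == label and g != label)
        fn = sum(n for (g, p), n in confusion.items() if g == label and p != label)
        support = tp + fn
        undefined = support == 0 and tp + fp == 0
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / support if support else 0.0
        per_label[label] = LabelMetrics(
            precision=precision, recall=recall, f1=_f1(precision, recall),
            support=support, undefined=undefined,
        )

    total = sum(confusion.values())
    correct = sum(n for (g, p), n in confusion.items() if g == p)
    micro_f1 = correct / total if total else 0.0  # multi-class micro == accuracy
    macro_f1 = sum(m.f1 for m in per_label.values()) / len(RELATION_LABELS)
    total_support = sum(m.support for m in per_label.values())
    weighted_f1 = (
        sum(m.f1 * m.support for m in per_label.values()) / total_support
        if total_support
        else 0.0
    )
    return MetricReport(
        per_label=per_label,
        macro_f1=macro_f1,
        micro_f1=micro_f1,
        weighted_f1=weighted_f1,
        confusion=dict(confusion),
    )


def score_records(records: Iterable) -> MetricReport:
    """Score `PredictionRecord` objects that carry their own gold labels."""
    predictions, gold = {}, {}
    for rec in records:
        if rec.gold is None:
            raise ValueError(f"record {rec.key} has no gold label")
        predictions[rec.key] = rec.predicted
        gold[rec.key] = rec.gold
    return score(predictions, gold)


def _relation_triples(
    docs: Iterable[AnnotatedDocument],
) -> set[tuple[str, tuple, tuple, str]]:
    """Annotator-independent identity of each relation.

    Entities are identified by (type, start, end) so that two annotators'
    differing entity ids still align.
    """
    triples = set()
    for doc in docs:
        by_id = {e.id: e for e in doc.entities}
        for rel in doc.relations:
            src, tgt = by_id[rel.source], by_id[rel.target]
            triples.add(
                (
                    doc.doc_id,
                    (src.etype, src.start, src.end),
                    (tgt.etype, tgt.start, tgt.end),
                    rel.rtype,
                )
            )
    return triples


def iaa(
    annotations_a: Iterable[AnnotatedDocument],
    annotations_b: Iterable[AnnotatedDocument],
) -> float:
    """Average-F1 agreement between two annotation sets of the same documents.

    One set is treated as reference; F1 is computed per relation type and
    averaged over the types present in either set. F1 swaps precision and
    recall under exchange of the two sets, so the value is symmetric.
    """
    docs_a, docs_b = list(annotations_a), list(annotations_b)
    ids_a = {d.doc_id for d in docs_a}
    ids_b = {d.doc_id for d in docs_b}
    if ids_a != ids_b:
        raise ValueError(
            f"annotation sets cover different documents: {sorted(ids_a ^ ids_b)}"
        )
    triples_a = _relation_triples(docs_a)
    triples_b = _relation_triples(docs_b)
    labels = {t[3] for t in triples_a | triples_b}
    if not labels:
        return 1.0  # vacuous agreement: neither annotator marked anything
    f1s = []
    for label in sorted(labels):
        ref = {t for t in triples_a if t[3] == label}
        cand = {t for t in triples_b if t[3] == label}
        tp = len(ref & cand)
        precision = tp / len(cand) if cand else 0.0
        recall = tp / len(ref) if ref else 0.0
        f1s.append(_f1(precision, recall))
    return sum(f1s) / len(f1s)
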