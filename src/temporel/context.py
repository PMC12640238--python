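"""Candidate-pair enumeration and entity-marked context extraction.

A candidate is any (temporal entity, phenotype) pair of a document. Its
snippet is the union of two token windows — up to ``window`` tokens on each
side of the phenotype and of the temporal entity — with both entities
wrapped in XML-style markers. Tokens are whitespace-delimited words of the
newline-normalized text; a custom tokenizer returning (start, end) character
offsets may be supplied instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable

from .corpus_io import AnnotatedDocument, Entity
from .schema import NONE_LABEL, PHENOTYPE_TYPE

__all__ = ["RelationInstance", "enumerate_pairs", "extract_context", "strip_markers"]

PHENOTYPE_OPEN = "<phenotype>"
PHENOTYPE_CLOSE = "</phenotype>"
TIME_CLOSE = "</time>"
#: Separator between disjoint window segments.
ELLIPSIS = " […] "

Tokenizer = Callable[[str], list[tuple[int, int]]]

_WORD = re.compile(r"\S+")
_MARKER = re.compile(r"</?phenotype>|<time type=\"[A-Za-z]+\">|</time>")


def time_open(etype: str) -> str:
    return f'<time type="{etype}">'


def whitespace_tokenize(text: str) -> list[tuple[int, int]]:
    """Character offsets of whitespace-delimited tokens."""
    return [m.span() for m in _WORD.finditer(text)]


@dataclass(frozen=True)
class RelationInstance:
    """One classification candidate: a temporal entity / phenotype pair."""

    doc_id: str
    source: Entity
    target: Entity
    snippet: str
    gold: str | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.doc_id, self.source.id, self.target.id)


def strip_markers(snippet: str) -> str:
    return _MARKER.sub("", snippet)


def _token_range(
    tokens: list[tuple[int, int]], entity: Entity
) -> tuple[int, int]:
    """Indices of the first and last token overlapping the entity span."""
    first = last = None
    for i, (ts, te) in enumerate(tokens):
        if te > entity.start and ts < entity.end:
            if first is None:
                first = i
            last = i
    if first is None:
        raise ValueError(f"entity {entity.id} covers no token")
    return first, last


def extract_context(
    doc: AnnotatedDocument,
    source: Entity,
    target: Entity,
    window: int = 1000,
    tokenizer: Tokenizer | None = None,
) -> str:
    """Build the marked snippet for one candidate pair.

    The two per-entity windows are merged into one contiguous segment when
    they overlap or touch, and joined with an ellipsis separator otherwise.
    A window boundary never cuts through either entity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    for ent in (source, target):
        if ent not in doc.entities:
            raise ValueError(f"entity {ent.id} not part of document {doc.doc_id}")
    tokenize = tokenizer or whitespace_tokenize
    tokens = tokenize(doc.text)

    ranges: list[tuple[int, int]] = []
    for ent in (source, target):
        first, last = _token_range(tokens, ent)
        lo = max(0, first - window)
        hi = min(len(tokens) - 1, last + window)
        # char range [a, b): from start of token lo to end of token hi, but
        # never truncating inside an entity that happens to extend beyond
        a = min(tokens[lo][0], ent.start)
        b = max(tokens[hi][1], ent.end)
        ranges.append((a, b))
    ranges.sort()

    segments: list[tuple[int, int]] = []
    for a, b in ranges:
        if segments and a <= segments[-1][1]:
            segments[-1] = (segments[-1][0], max(segments[-1][1], b))
        else:
            segments.append((a, b))

    marks = sorted(
        [
            (target.start, target.end, PHENOTYPE_OPEN, PHENOTYPE_CLOSE),
            (source.start, source.end, time_open(source.etype), TIME_CLOSE),
        ]
    )
    rendered: list[str] = []
    for a, b in segments:
        out, pos = [], a
        for ms, me, mo, mc in marks:
            if ms >= a and me <= b:
                out.append(doc.text[pos:ms])
                out.append(mo + doc.text[ms:me] + mc)
                pos = me
        out.append(doc.text[pos:b])
        rendered.append("".join(out))
    return ELLIPSIS.join(rendered)


def enumerate_pairs(
    doc: AnnotatedDocument,
    window: int = 1000,
    gold_corpus: bool = True,
    tokenizer: Tokenizer | None = None,
) -> list[RelationInstance]:
    """All (temporal entity, phenotype) candidates of a document.

    When ``gold_corpus`` is true, each instance carries its gold label:
    the stored relation type for annotated pairs, NONE for the rest.
    """
    gold_map: dict[tuple[str, str], str] = {
        (rel.source, rel.target): rel.rtype for rel in doc.relations
    }
    instances: list[RelationInstance] = []
    temporals = [e for e in doc.entities if e.etype != PHENOTYPE_TYPE]
    phenotypes = [e for e in doc.entities if e.etype == PHENOTYPE_TYPE]
    for src in temporals:
        for tgt in phenotypes:
            snippet = extract_context(doc, src, tgt, window=window, tokenizer=tokenizer)
            gold = gold_map.get((src.id, tgt.id), NONE_LABEL) if gold_corpus else None
            instances.append(
                RelationInstance(
                    doc_id=doc.doc_id, source=src, target=tgt,
                    snippet=snippet, gold=gold,
                )
            )
    return instances
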