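"""Reading and writing annotated reports in the BRAT standoff dialect.

A document is a ``.txt`` payload plus a ``.ann`` payload of T-lines (entity
spans) and R-lines (binary relations). Offsets are 0-based half-open
character offsets into the newline-normalized text, per the BRAT convention.

Relations are directed temporal-entity → phenotype; standoff files with the
arguments reversed are auto-normalized with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .schema import ENTITY_TYPES, PHENOTYPE_TYPE, RELATION_LABELS

__all__ = [
    "Entity",
    "Relation",
    "AnnotatedDocument",
    "BratParseError",
    "read_brat",
    "write_brat",
]


class BratParseError(ValueError):
    """Raised when a standoff payload cannot be interpreted."""


def normalize_newlines(text: str) -> str:
    return text.replace("\r\n", "\n").replace("\r", "\n")


@dataclass(frozen=True)
class Entity:
    """One annotated span: a phenotype mention or a time expression."""

    id: str
    etype: str
    start: int
    end: int
    surface: str

    def validate(self, text: str) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"entity {self.id}: unknown type {self.etype!r}")
        if not (0 <= self.start < self.end <= len(text)):
            raise ValueError(
                f"entity {self.id}: offsets [{self.start}, {self.end}) outside "
                f"text of length {len(text)}"
            )
        if text[self.start : self.end] != self.surface:
            raise ValueError(
                f"entity {self.id}: surface {self.surface!r} does not match "
                f"text slice {text[self.start:self.end]!r}"
            )


@dataclass(frozen=True)
class Relation:
    """Directed temporal-entity → phenotype link."""

    id: str
    rtype: str
    source: str  # entity id of the temporal entity
    target: str  # entity id of the phenotype


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)

    def entity_by_id(self, eid: str) -> Entity:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        raise KeyError(f"no entity {eid!r} in document {self.doc_id!r}")

    def validate(self) -> None:
        ids = [e.id for e in self.entities]
        if len(ids) != len(set(ids)):
            raise ValueError(f"document {self.doc_id}: duplicate entity ids")
        by_id = {e.id: e for e in self.entities}
        for ent in self.entities:
            ent.validate(self.text)
        seen: set[tuple[str, str, str]] = set()
        for rel in self.relations:
            if rel.rtype not in RELATION_LABELS:
                raise ValueError(
                    f"relation {rel.id}: unknown type {rel.rtype!r}"
                )
            for arg in (rel.source, rel.target):
                if arg not in by_id:
                    raise ValueError(
                        f"relation {rel.id}: dangling argument {arg!r}"
                    )
            if by_id[rel.source].etype == PHENOTYPE_TYPE:
                raise ValueError(
                    f"relation {rel.id}: source must be a temporal entity"
                )
            if by_id[rel.target].etype != PHENOTYPE_TYPE:
                raise ValueError(
                    f"relation {rel.id}: target must be a Phenotype"
                )
            key = (rel.source, rel.target, rel.rtype)
            if key in seen:
                raise ValueError(f"relation {rel.id}: duplicate of {key}")
            seen.add(key)


def _parse_t_line(lineno: int, line: str) -> Entity:
    try:
        tid, spec, surface = line.split("\t", 2)
    except ValueError:
        raise BratParseError(f"line {lineno}: malformed T-line {line!r}") from None
    if ";" in spec:
        raise BratParseError(
            f"line {lineno}: discontinuous spans are not supported ({spec!r})"
        )
    parts = spec.split(" ")
    if len(parts) != 3:
        raise BratParseError(f"line {lineno}: malformed T-line spec {spec!r}")
    etype, start_s, end_s = parts
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise BratParseError(f"line {lineno}: non-integer offsets in {spec!r}") from None
    return Entity(id=tid, etype=etype, start=start, end=end, surface=surface)


def _parse_r_line(lineno: int, line: str) -> Relation:
    try:
        rid, spec = line.split("\t", 1)
    except ValueError:
        raise BratParseError(f"line {lineno}: malformed R-line {line!r}") from None
    parts = spec.split()
    if len(parts) != 3:
        raise BratParseError(f"line {lineno}: malformed R-line spec {spec!r}")
    rtype, arg1, arg2 = parts
    args: dict[str, str] = {}
    for part in (arg1, arg2):
        if ":" not in part:
            raise BratParseError(f"line {lineno}: malformed argument {part!r}")
        role, eid = part.split(":", 1)
        args[role] = eid
    if set(args) != {"Arg1", "Arg2"}:
        raise BratParseError(
            f"line {lineno}: expected Arg1/Arg2 roles, got {sorted(args)}"
        )
    return Relation(id=rid, rtype=rtype, source=args["Arg1"], target=args["Arg2"])


def read_brat(
    txt_content: str,
    ann_content: str,
    doc_id: str = "doc",
    unknown_types: str = "skip",
) -> AnnotatedDocument:
    """Parse a ``.txt``/``.ann`` payload pair into an `AnnotatedDocument`.

    Parameters
    ----------
    unknown_types:
        ``"skip"`` (default) drops T-lines whose entity type is outside the
        schema vocabulary with a warning; ``"reject"`` raises instead.
        R-lines with an out-of-vocabulary relation type are handled the same
        way, so a relation is never dropped silently.
    """
    if unknown_types not in ("skip", "reject"):
        raise ValueError("unknown_types must be 'skip' or 'reject'")
    text = normalize_newlines(txt_content)
    entities: list[Entity] = []
    relations: list[Relation] = []
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("T"):
            ent = _parse_t_line(lineno, line)
            if ent.etype not in ENTITY_TYPES:
                if unknown_types == "reject":
                    raise BratParseError(
                        f"line {lineno}: unknown entity type {ent.etype!r}"
                    )
                warnings.warn(
                    f"line {lineno}: skipping entity {ent.id} of unknown type "
                    f"{ent.etype!r}",
                    stacklevel=2,
                )
                continue
            try:
                ent.validate(text)
            except ValueError as exc:
                raise BratParseError(f"line {lineno}: {exc}") from None
            entities.append(ent)
        elif line.startswith("R"):
            relations.append(_parse_r_line(lineno, line))
        # other standoff line types (#, A, E, ...) are outside this dialect
    by_id = {e.id: e for e in entities}
    resolved: list[Relation] = []
    for rel in relations:
        if rel.rtype not in RELATION_LABELS:
            if unknown_types == "reject":
                raise BratParseError(
                    f"relation {rel.id}: unknown relation type {rel.rtype!r}"
                )
            warnings.warn(
                f"skipping relation {rel.id} of unknown type {rel.rtype!r}",
                stacklevel=2,
            )
            continue
        for arg in (rel.source, rel.target):
            if arg not in by_id:
                raise BratParseError(
                    f"relation {rel.id}: dangling argument {arg!r}"
                )
        src, tgt = by_id[rel.source], by_id[rel.target]
        if src.etype == PHENOTYPE_TYPE and tgt.etype != PHENOTYPE_TYPE:
            # reversed arguments: normalize to temporal → phenotype
            warnings.warn(
                f"relation {rel.id}: arguments reversed, normalizing",
                stacklevel=2,
            )
            rel = replace(rel, source=rel.target, target=rel.source)
        resolved.append(rel)
    doc = AnnotatedDocument(doc_id=doc_id, text=text, entities=entities, relations=resolved)
    doc.validate()
    return doc


def write_brat(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize a document to its ``(.txt, .ann)`` payloads.

    Refuses to serialize a document violating its invariants, and rejects
    entity surfaces containing newlines (they would corrupt the standoff).
    """
    doc.validate()
    for ent in doc.entities:
        if "\n" in ent.surface:
            raise ValueError(
                f"entity {ent.id}: surface spans a newline, cannot serialize"
            )
    lines = [
        f"{ent.id}\t{ent.etype} {ent.start} {ent.end}\t{ent.surface}"
        for ent in doc.entities
    ]
    lines += [
        f"{rel.id}\t{rel.rtype} Arg1:{rel.source} Arg2:{rel.target}"
        for rel in doc.relations
    ]
    ann = "\n".join(lines)
    if ann:
        ann += "\n"
    return doc.text, ann
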