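"""Seeded generator of French-flavored annotated reports.

Every document is derived from a latent patient timeline on an abstract
integer day axis: phenotype episodes are intervals, time expressions are
points or spans, and each stored gold relation is *constructed* so that
`intervals.label_relation` applied to the latent spans reproduces its label
exactly. The same seed yields a byte-identical corpus.

Narrative realism is a non-goal: surface templates exist only to exercise
offsets, markers and the standoff round-trip.
"""

from __future__ import annotations

import datetime
import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .corpus_io import AnnotatedDocument, Entity, Relation, read_brat
from .intervals import Span, label_relation
from .schema import (
    PHENOTYPE_TYPE,
    RELATION_LABELS,
    SPAN_TIME_TYPES,
    TEMPORAL_ENTITY_TYPES,
)

__all__ = [
    "GenerationConfig",
    "LatentTimeline",
    "generate_corpus",
    "generate_corpus_with_timelines",
    "table1_fixture",
    "default_relation_mix",
    "write_corpus",
    "read_corpus",
]

#: Gold relation counts of the 25-report test set, per temporal entity type
#: (rows) and relation type (columns). Used as the default sampling target
#: and as the documented source of per-type training counts.
_TABLE1_ROWS: dict[str, tuple[int, ...]] = {
    # BEGINS-AT, ENDS-AT, CONTAINS, OVERLAP, BEFORE-OVERLAP, BEFORE, SIMULTANEOUS
    "DOB": (1, 0, 1, 0, 7, 0, 0),
    "DOR": (1, 0, 0, 0, 2, 0, 0),
    "DOV": (85, 0, 7, 2, 181, 11, 0),
    "DOPV": (50, 4, 1, 38, 59, 10, 0),
    "DOFV": (0, 0, 0, 0, 0, 0, 0),
    "DOTHER": (0, 0, 0, 0, 0, 0, 0),
    "Age": (9, 1, 1, 14, 9, 0, 0),
    "Duration": (22, 0, 9, 10, 58, 0, 11),
    "Frequency": (0, 0, 0, 0, 0, 0, 3),
    "Time": (34, 2, 3, 16, 41, 3, 0),
}

#: Labels that require an extended time span on the time-expression side.
_SPAN_REQUIRED = frozenset({"CONTAINS", "OVERLAP", "SIMULTANEOUS"})

_DAY_ZERO = datetime.date(2008, 1, 1)

_PHENOTYPES = (
    "fièvre prolongée",
    "protéinurie",
    "hématurie",
    "toux chronique",
    "retard de croissance",
    "asthénie",
    "polyurie",
    "insuffisance rénale chronique",
    "anémie",
    "douleurs abdominales",
    "vomissements",
    "hypertension artérielle",
)

_MONTHS = (
    "janvier", "février", "mars", "avril", "mai", "juin", "juillet",
    "août", "septembre", "octobre", "novembre", "décembre",
)

# Sentence frames per relation label; {T} and {P} are entity slots.
_FRAMES: dict[str, tuple[str, ...]] = {
    "BEGINS-AT": (
        "Apparition de {P} le {T}.",
        "Début de {P} à partir du {T}.",
        "On note {P} depuis le {T}.",
    ),
    "ENDS-AT": (
        "Résolution de {P} le {T}.",
        "Disparition de {P} au {T}.",
    ),
    "CONTAINS": (
        "Au cours de {T}, épisode transitoire de {P}.",
        "Pendant {T}, survenue résolutive de {P}.",
    ),
    "OVERLAP": (
        "Durant {T}, aggravation de {P}.",
        "Au moment de {T}, {P} documentée.",
    ),
    "BEFORE-OVERLAP": (
        "{P} ancienne, toujours présente au {T}.",
        "Persistance de {P} connue, constatée au {T}.",
    ),
    "BEFORE": (
        "Antécédent de {P}, résolu avant le {T}.",
        "Ancien épisode de {P}, guéri avant le {T}.",
    ),
    "SIMULTANEOUS": (
        "{P} strictement pendant {T}.",
        "{P} limitée exactement à {T}.",
    ),
}

_FILLER = (
    "L'examen clinique est par ailleurs sans particularité.",
    "Le reste du bilan biologique est normal.",
    "La croissance staturo-pondérale est régulière.",
    "Le traitement en cours est bien toléré.",
    "Les constantes sont dans les normes pour l'âge.",
)


def default_relation_mix() -> dict[str, float]:
    """Relation-type proportions matching the published count totals."""
    totals = table1_fixture().sum(axis=0)
    grand = float(totals.sum())
    return {label: float(totals[label]) / grand for label in RELATION_LABELS}


def table1_fixture() -> pd.DataFrame:
    """The printed 10×7 gold relation count matrix, as a DataFrame."""
    return pd.DataFrame.from_dict(
        _TABLE1_ROWS, orient="index", columns=list(RELATION_LABELS)
    ).loc[list(TEMPORAL_ENTITY_TYPES)]


@dataclass
class LatentTimeline:
    """Ground truth behind one generated report."""

    doc_id: str
    dob: int
    visits: list[int]
    phenotype_episodes: list[tuple[str, Span]] = field(default_factory=list)
    timeexp_anchors: list[tuple[str, Span, str]] = field(default_factory=list)
    #: (source entity id, target entity id) -> (phenotype span, timeexp span)
    gold_spans: dict[tuple[str, str], tuple[Span, Span]] = field(default_factory=dict)

    def to_json(self) -> str:
        def span(s: Span) -> list[int | None]:
            return [s.start, s.end]

        payload = {
            "doc_id": self.doc_id,
            "dob": self.dob,
            "visits": self.visits,
            "phenotype_episodes": [
                {"name": name, "span": span(s)} for name, s in self.phenotype_episodes
            ],
            "timeexp_anchors": [
                {"etype": et, "span": span(s), "surface": surf}
                for et, s, surf in self.timeexp_anchors
            ],
            "gold_spans": [
                {
                    "source": src,
                    "target": tgt,
                    "phenotype_span": span(p),
                    "timeexp_span": span(t),
                }
                for (src, tgt), (p, t) in self.gold_spans.items()
            ],
        }
        return json.dumps(payload, ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, payload: str) -> "LatentTimeline":
        d = json.loads(payload)
        tl = cls(doc_id=d["doc_id"], dob=d["dob"], visits=list(d["visits"]))
        tl.phenotype_episodes = [
            (e["name"], Span(*e["span"])) for e in d["phenotype_episodes"]
        ]
        tl.timeexp_anchors = [
            (e["etype"], Span(*e["span"]), e["surface"]) for e in d["timeexp_anchors"]
        ]
        tl.gold_spans = {
            (g["source"], g["target"]): (
                Span(*g["phenotype_span"]),
                Span(*g["timeexp_span"]),
            )
            for g in d["gold_spans"]
        }
        return tl


@dataclass(frozen=True)
class GenerationConfig:
    n_docs: int = 20
    seed: int = 0
    relation_mix: dict[str, float] | None = None
    mean_phenotypes_per_doc: float = 4.0
    span_time_types: tuple[str, ...] = SPAN_TIME_TYPES
    template_set: str = "fr_default"

    def mix(self) -> dict[str, float]:
        return dict(self.relation_mix) if self.relation_mix else default_relation_mix()

    def validate(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be >= 0")
        if self.template_set != "fr_default":
            raise ValueError(f"unknown template set {self.template_set!r}")
        mix = self.mix()
        if set(mix) - set(RELATION_LABELS):
            raise ValueError(f"unknown labels in relation_mix: {set(mix) - set(RELATION_LABELS)}")
        if any(p < 0 for p in mix.values()):
            raise ValueError("relation_mix proportions must be non-negative")
        if abs(sum(mix.values()) - 1.0) > 1e-6:
            raise ValueError("relation_mix proportions must sum to 1")
        for etype in self.span_time_types:
            if etype not in SPAN_TIME_TYPES:
                raise ValueError(f"{etype!r} is not a span-capable time type")
        if not self.span_time_types:
            for label in _SPAN_REQUIRED:
                if mix.get(label, 0.0) > 0:
                    raise ValueError(
                        f"relation_mix requests {label} but no span-capable "
                        "time entity types are enabled"
                    )


def _fmt_date(day: int) -> str:
    return (_DAY_ZERO + datetime.timedelta(days=day)).strftime("%d/%m/%Y")


class _DocBuilder:
    """Accumulates text while recording entity character offsets."""

    def __init__(self, doc_id: str) -> None:
        self.doc_id = doc_id
        self._parts: list[str] = []
        self._len = 0
        self.entities: list[Entity] = []
        self.relations: list[Relation] = []
        self._eid = 0
        self._rid = 0

    def text(self, s: str) -> None:
        self._parts.append(s)
        self._len += len(s)

    def entity(self, etype: str, surface: str) -> Entity:
        self._eid += 1
        ent = Entity(
            id=f"T{self._eid}", etype=etype,
            start=self._len, end=self._len + len(surface), surface=surface,
        )
        self.text(surface)
        self.entities.append(ent)
        return ent

    def relation(self, rtype: str, source: Entity, target: Entity) -> Relation:
        self._rid += 1
        rel = Relation(id=f"R{self._rid}", rtype=rtype, source=source.id, target=target.id)
        self.relations.append(rel)
        return rel

    def sentence(self, frame: str, slots: dict[str, tuple[str, str]]) -> dict[str, Entity]:
        """Emit a frame, materializing each ``{X}`` slot as an entity."""
        out: dict[str, Entity] = {}
        for part in re.split(r"(\{[TP]\})", frame):
            if part in ("{T}", "{P}"):
                key = part[1]
                etype, surface = slots[key]
                out[key] = self.entity(etype, surface)
            else:
                self.text(part)
        self.text("\n")
        return out

    def build(self) -> AnnotatedDocument:
        doc = AnnotatedDocument(
            doc_id=self.doc_id,
            text="".join(self._parts),
            entities=self.entities,
            relations=self.relations,
        )
        doc.validate()
        return doc


def _sample_entity_type(
    rng: random.Random, label: str, span_types: tuple[str, ...]
) -> str:
    """Entity type for a relation, weighted by the published count column."""
    column = table1_fixture()[label]
    if label in _SPAN_REQUIRED:
        allowed = [t for t in span_types]
    else:
        allowed = list(TEMPORAL_ENTITY_TYPES)
    if not allowed:
        raise ValueError(f"no time entity types available for label {label}")
    weights = [int(column[t]) for t in allowed]
    if sum(weights) == 0:
        weights = [1] * len(allowed)
    return rng.choices(allowed, weights=weights, k=1)[0]


def _make_time_anchor(
    rng: random.Random, etype: str, dob: int, visits: list[int]
) -> tuple[Span, str]:
    """Latent span and French surface for one time expression."""
    current = visits[-1]
    if etype == "DOB":
        return Span(dob, dob), _fmt_date(dob)
    if etype == "DOR":
        return Span(current, current), _fmt_date(current)
    if etype == "DOV":
        return Span(current, current), _fmt_date(current)
    if etype == "DOPV":
        day = rng.choice(visits[:-1]) if len(visits) > 1 else current
        return Span(day, day), _fmt_date(day)
    if etype == "DOFV":
        day = current + rng.randint(30, 200)
        return Span(day, day), _fmt_date(day)
    if etype == "DOTHER":
        day = rng.randint(dob + 30, current)
        return Span(day, day), _fmt_date(day)
    if etype == "Age":
        years = max(1, min((current - dob) // 365 - 1, rng.randint(1, 12)))
        start = dob + years * 365
        return Span(start, start + 364), f"l'âge de {years} ans"
    if etype == "Duration":
        months = rng.randint(2, 24)
        return Span(current - months * 30, current), f"{months} mois"
    if etype == "Frequency":
        return Span(current - 180, current), "deux fois par semaine"
    if etype == "Time":
        day = rng.randint(dob + 365, max(dob + 396, current - 60))
        month_start = day - day % 30
        d = _DAY_ZERO + datetime.timedelta(days=month_start)
        return Span(month_start, month_start + 29), f"{_MONTHS[d.month - 1]} {d.year}"
    raise ValueError(f"unknown time entity type {etype!r}")


def _make_phenotype_span(rng: random.Random, label: str, t: Span) -> Span:
    """Phenotype span realizing *label* against timeexp span *t*."""
    ts, te = t.start, t.end
    assert ts is not None and te is not None
    if label == "SIMULTANEOUS":
        return Span(ts, te)
    if label == "BEGINS-AT":
        if rng.random() < 0.3:
            return Span(ts, None)  # ongoing
        pe = ts + rng.randint(20, 400)
        if pe == te:
            pe += 7
        return Span(ts, pe)
    if label == "ENDS-AT":
        ps = te - rng.randint(20, 400)
        if ps == ts:
            ps -= 7
        return Span(ps, te)
    if label == "BEFORE":
        pe = ts - rng.randint(10, 300)
        return Span(pe - rng.randint(10, 300), pe)
    if label == "BEFORE-OVERLAP":
        ps = ts - rng.randint(60, 2000)
        if rng.random() < 0.6:
            return Span(ps, None)  # chronic, ongoing
        pe = rng.randint(ts, te + 200)
        if pe == te:
            pe += 11
        return Span(ps, pe)
    if label == "CONTAINS":
        width = te - ts
        if width < 2:
            raise ValueError("CONTAINS requires a time span of width >= 2")
        ps = ts + rng.randint(1, max(1, width // 2))
        pe = te - rng.randint(1, max(1, width // 3))
        return Span(ps, max(ps, pe))
    if label == "OVERLAP":
        ps = ts + rng.randint(1, te - ts)
        pe = te + rng.randint(10, 300)
        return Span(ps, pe)
    raise ValueError(f"unknown relation label {label!r}")


def _label_quota(mix: dict[str, float], total: int, rng: random.Random) -> list[str]:
    """Largest-remainder allocation of *total* labels to the mix, shuffled."""
    raw = {lab: mix.get(lab, 0.0) * total for lab in RELATION_LABELS}
    counts = {lab: int(raw[lab]) for lab in RELATION_LABELS}
    short = total - sum(counts.values())
    for lab in sorted(RELATION_LABELS, key=lambda l: raw[l] - counts[l], reverse=True)[:short]:
        counts[lab] += 1
    labels = [lab for lab in RELATION_LABELS for _ in range(counts[lab])]
    rng.shuffle(labels)
    return labels


def _generate_doc(
    doc_id: str, labels: list[str], rng: random.Random, config: GenerationConfig
) -> tuple[AnnotatedDocument, LatentTimeline]:
    dob = 0
    current = rng.randint(2500, 5500)
    past = sorted(rng.sample(range(400, current - 200), rng.randint(1, 3)))
    visits = past + [current]
    b = _DocBuilder(doc_id)
    tl = LatentTimeline(doc_id=doc_id, dob=dob, visits=visits)

    # header anchors: DOR, DOB, and the mandatory DOV-like anchor
    b.text("Compte rendu du ")
    dor = b.entity("DOR", _fmt_date(current))
    b.text(".\nPatient né le ")
    dob_ent = b.entity("DOB", _fmt_date(dob))
    b.text(".\nConsultation du ")
    dov = b.entity("DOV", _fmt_date(current))
    b.text(" en néphrologie pédiatrique.\n")
    tl.timeexp_anchors += [
        ("DOR", Span(current, current), dor.surface),
        ("DOB", Span(dob, dob), dob_ent.surface),
        ("DOV", Span(current, current), dov.surface),
    ]

    for label in labels:
        etype = _sample_entity_type(rng, label, config.span_time_types)
        t_span, t_surface = _make_time_anchor(rng, etype, dob, visits)
        p_span = _make_phenotype_span(rng, label, t_span)
        got = label_relation(p_span, t_span)
        if got != label:  # construction guarantee
            raise RuntimeError(
                f"generator bug: built {got} while targeting {label} "
                f"(P={p_span}, T={t_span})"
            )
        phen = rng.choice(_PHENOTYPES)
        frame = rng.choice(_FRAMES[label])
        ents = b.sentence(frame, {"T": (etype, t_surface), "P": (PHENOTYPE_TYPE, phen)})
        b.relation(label, ents["T"], ents["P"])
        tl.phenotype_episodes.append((phen, p_span))
        tl.timeexp_anchors.append((etype, t_span, t_surface))
        tl.gold_spans[(ents["T"].id, ents["P"].id)] = (p_span, t_span)
        if rng.random() < 0.4:
            b.text(rng.choice(_FILLER) + "\n")

    if rng.random() < 0.4:
        b.text("Prochaine consultation prévue le ")
        fut_span, fut_surface = _make_time_anchor(rng, "DOFV", dob, visits)
        b.entity("DOFV", fut_surface)
        b.text(".\n")
        tl.timeexp_anchors.append(("DOFV", fut_span, fut_surface))
    if rng.random() < 0.3:
        b.text("Examen clinique : ")
        extra = rng.choice(_PHENOTYPES)
        b.entity(PHENOTYPE_TYPE, extra)
        b.text(" notée ce jour, sans lien temporel précisé.\n")

    return b.build(), tl


def generate_corpus_with_timelines(
    config: GenerationConfig,
) -> tuple[list[AnnotatedDocument], list[LatentTimeline]]:
    config.validate()
    rng = random.Random(config.seed)
    per_doc = [
        max(1, int(rng.gauss(config.mean_phenotypes_per_doc, 1.2) + 0.5))
        for _ in range(config.n_docs)
    ]
    quota = _label_quota(config.mix(), sum(per_doc), rng)
    docs, timelines = [], []
    cursor = 0
    for i, n in enumerate(per_doc):
        labels = quota[cursor : cursor + n]
        cursor += n
        doc, tl = _generate_doc(f"doc{i:04d}", labels, rng, config)
        docs.append(doc)
        timelines.append(tl)
    return docs, timelines


def generate_corpus(config: GenerationConfig) -> list[AnnotatedDocument]:
    """Generate a seeded corpus of annotated reports."""
    return generate_corpus_with_timelines(config)[0]


def write_corpus(
    docs: list[AnnotatedDocument],
    out_dir: str | Path,
    timelines: list[LatentTimeline] | None = None,
) -> None:
    """Write BRAT pairs (plus optional timeline sidecars) to a directory."""
    from .corpus_io import write_brat

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, doc in enumerate(docs):
        txt, ann = write_brat(doc)
        (out / f"{doc.doc_id}.txt").write_text(txt, encoding="utf-8")
        (out / f"{doc.doc_id}.ann").write_text(ann, encoding="utf-8")
        if timelines is not None:
            (out / f"{doc.doc_id}.timeline.json").write_text(
                timelines[i].to_json(), encoding="utf-8"
            )


def read_corpus(corpus_dir: str | Path) -> list[AnnotatedDocument]:
    """Read every ``.txt``/``.ann`` pair of a directory, sorted by name."""
    corpus = Path(corpus_dir)
    docs = []
    for txt_path in sorted(corpus.glob("*.txt")):
        ann_path = txt_path.with_suffix(".ann")
        if not ann_path.exists():
            raise FileNotFoundError(f"missing annotation file for {txt_path.name}")
        docs.append(
            read_brat(
                txt_path.read_text(encoding="utf-8"),
                ann_path.read_text(encoding="utf-8"),
                doc_id=txt_path.stem,
            )
        )
    return docs
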