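"""Closed vocabularies shared by every stage of the pipeline.

The schema is deliberately small and frozen: label tokens appear verbatim
inside prompts and are parsed back out of model answers, so any drift here
would silently corrupt both directions.
"""

from __future__ import annotations

SCHEMA_VERSION = "1.0"

#: The seven temporal relation types, in canonical declaration order.
#: This order is load-bearing: it fixes example ordering in prompts, column
#: order in reports, and the deterministic tie-break in conflict resolution.
RELATION_LABELS: tuple[str, ...] = (
    "BEGINS-AT",
    "ENDS-AT",
    "CONTAINS",
    "OVERLAP",
    "BEFORE-OVERLAP",
    "BEFORE",
    "SIMULTANEOUS",
)

#: Predicted when no temporal relation holds. Never stored in gold corpora.
NONE_LABEL = "NONE"

#: Full answer vocabulary for the multi-class regime.
ALL_LABELS: tuple[str, ...] = RELATION_LABELS + (NONE_LABEL,)

#: Entity type of the clinical-sign mentions (relation targets).
PHENOTYPE_TYPE = "Phenotype"

#: The ten time-denoting entity types (relation sources).
TEMPORAL_ENTITY_TYPES: tuple[str, ...] = (
    "DOB",      # date of birth
    "DOR",      # date of report
    "DOV",      # date of visit
    "DOPV",     # date of past visit
    "DOFV",     # date of future visit
    "DOTHER",   # other date
    "Age",
    "Duration",
    "Frequency",
    "Time",
)

ENTITY_TYPES: tuple[str, ...] = (PHENOTYPE_TYPE,) + TEMPORAL_ENTITY_TYPES

#: Date-like types are modeled as time points on the day axis.
POINT_TIME_TYPES: tuple[str, ...] = ("DOB", "DOR", "DOV", "DOPV", "DOFV", "DOTHER")

#: These types may denote extended time spans.
SPAN_TIME_TYPES: tuple[str, ...] = ("Age", "Duration", "Frequency", "Time")

#: One-sentence French definition of each relation type, used verbatim in
#: binary and zero-shot prompt instructions. Label tokens stay in English
#: uppercase because model answers are parsed against them.
RELATION_DEFINITIONS: dict[str, str] = {
    "BEGINS-AT": (
        "le phénotype commence au point temporel désigné par l'expression de temps."
    ),
    "ENDS-AT": (
        "le phénotype se termine au point temporel désigné par l'expression de temps."
    ),
    "CONTAINS": (
        "l'expression de temps contient le début et la fin du phénotype."
    ),
    "OVERLAP": (
        "le phénotype et l'entité temporelle partagent une période commune, "
        "sans que l'on dispose d'autre information."
    ),
    "BEFORE-OVERLAP": (
        "le phénotype commence avant l'entité temporelle et continue de se "
        "manifester pendant la période désignée par l'expression de temps."
    ),
    "BEFORE": (
        "le phénotype se termine avant le point temporel désigné par "
        "l'expression de temps."
    ),
    "SIMULTANEOUS": (
        "le phénotype et l'entité temporelle couvrent exactement la même période."
    ),
}

assert set(RELATION_DEFINITIONS) == set(RELATION_LABELS)


def validate_relation_label(label: str) -> str:
    """Return *label* unchanged if it is one of the seven relation types."""
    if label not in RELATION_LABELS:
        raise ValueError(
            f"unknown relation type {label!r}; expected one of {RELATION_LABELS}"
        )
    return label


def validate_entity_type(etype: str) -> str:
    if etype not in ENTITY_TYPES:
        raise ValueError(
            f"unknown entity type {etype!r}; expected one of {ENTITY_TYPES}"
        )
    return etype
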