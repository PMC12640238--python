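"""Deterministic labeling of a (phenotype interval, time expression) pair.

Spans live on an abstract integer day axis and are closed intervals; a time
point is a span whose start equals its end. Either bound of a phenotype may
be unbounded (``None``) to model conditions whose onset predates the record
or which are still ongoing.

`label_relation` applies the seven relation definitions in a fixed
most-specific-first precedence; OVERLAP is the residual label for pairs that
intersect without matching anything more specific, and NONE is returned
exactly when the phenotype lies strictly after the time expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .schema import NONE_LABEL

__all__ = ["Span", "label_relation", "PRECEDENCE"]

#: Order in which definitions are tested, most specific first.
PRECEDENCE: tuple[str, ...] = (
    "SIMULTANEOUS",
    "BEGINS-AT",
    "ENDS-AT",
    "CONTAINS",
    "BEFORE-OVERLAP",
    "BEFORE",
    "OVERLAP",
)


@dataclass(frozen=True)
class Span:
    """Closed interval on the day axis; ``None`` marks an unbounded end."""

    start: int | None
    end: int | None

    def __post_init__(self) -> None:
        for bound in (self.start, self.end):
            if bound is not None and not isinstance(bound, int):
                raise ValueError(f"span bound must be int or None, got {bound!r}")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"invalid span: start {self.start} > end {self.end}")

    @property
    def lo(self) -> float:
        return -math.inf if self.start is None else float(self.start)

    @property
    def hi(self) -> float:
        return math.inf if self.end is None else float(self.end)

    @property
    def is_point(self) -> bool:
        return self.start is not None and self.start == self.end

    def intersects(self, other: "Span") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


def label_relation(phenotype: Span, timeexp: Span) -> str:
    """Return the single relation label holding between the two spans.

    Total over valid span pairs: every pair maps to exactly one of the seven
    relation types or NONE.
    """
    ps, pe = phenotype.lo, phenotype.hi
    ts, te = timeexp.lo, timeexp.hi

    if ps == ts and pe == te:
        return "SIMULTANEOUS"
    if ps == ts:
        return "BEGINS-AT"
    if pe == te:
        return "ENDS-AT"
    if ts <= ps and pe <= te:
        return "CONTAINS"
    if ps < ts <= pe:
        return "BEFORE-OVERLAP"
    if pe < ts:
        return "BEFORE"
    if ps <= te and ts <= pe:
        return "OVERLAP"
    # Disjoint with the phenotype strictly after the time expression.
    return NONE_LABEL
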