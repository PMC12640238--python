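"""Assembly of the three prompt regimes from a curated example bank.

All regimes share one instruction skeleton and one markup dialect; they
differ only in the task paragraph, the answer vocabulary and the example
blocks:

* ``multiclass`` — 2 examples for each of the 7 relation types (14 total),
  answers drawn from the full vocabulary plus NONE;
* ``binary`` — one relation type at a time, 3 positive + 3 NONE examples,
  answers restricted to {relation, NONE};
* ``zeroshot`` — the binary prompt stripped of its example blocks.

Templates live as editable text files under ``temporel/templates``.
Example selection is deterministic: the first k examples in bank order
(banks are curated by hand, not sampled).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .context import RelationInstance, strip_markers
from .schema import (
    NONE_LABEL,
    RELATION_DEFINITIONS,
    RELATION_LABELS,
    validate_relation_label,
)

__all__ = [
    "ExampleBank",
    "PromptSpec",
    "build_multiclass_prompt",
    "build_binary_prompt",
    "build_zeroshot_prompt",
    "template_hashes",
]

MULTICLASS_EXAMPLES_PER_TYPE = 2
BINARY_POSITIVE_EXAMPLES = 3
BINARY_NONE_EXAMPLES = 3


def _template(name: str) -> str:
    return (resources.files("temporel") / "templates" / name).read_text(encoding="utf-8")


def template_hashes() -> dict[str, str]:
    """sha256 of each prompt template, for run manifests."""
    out = {}
    for entry in sorted(
        (resources.files("temporel") / "templates").iterdir(), key=lambda p: p.name
    ):
        digest = hashlib.sha256(entry.read_bytes()).hexdigest()
        out[entry.name] = digest
    return out


@dataclass
class ExampleBank:
    """Curated labeled snippets, the raw material of few-shot prompts."""

    examples: dict[str, list[str]] = field(default_factory=dict)
    none_examples: list[str] = field(default_factory=list)
    provenance: str = ""

    def validate(self) -> None:
        for label, snippets in self.examples.items():
            validate_relation_label(label)
            for snippet in snippets:
                if "<phenotype>" not in snippet or "</phenotype>" not in snippet:
                    raise ValueError(
                        f"example for {label} lacks phenotype markers: {snippet!r}"
                    )

    def counts(self) -> dict[str, int]:
        """Per-relation example counts (the bank's training sample sizes)."""
        return {label: len(self.examples.get(label, [])) for label in RELATION_LABELS}

    def add(self, snippet: str, label: str) -> None:
        if label == NONE_LABEL:
            self.none_examples.append(snippet)
        else:
            self.examples.setdefault(validate_relation_label(label), []).append(snippet)

    @classmethod
    def from_instances(
        cls,
        instances: list[RelationInstance],
        per_label: int = 3,
        none_count: int = 3,
        provenance: str = "",
    ) -> "ExampleBank":
        """Curate a bank by taking the first k gold instances per label."""
        bank = cls(provenance=provenance)
        for inst in instances:
            if inst.gold is None:
                continue
            if inst.gold == NONE_LABEL:
                if len(bank.none_examples) < none_count:
                    bank.add(inst.snippet, NONE_LABEL)
            elif len(bank.examples.get(inst.gold, [])) < per_label:
                bank.add(inst.snippet, inst.gold)
        bank.validate()
        return bank

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if self.provenance:
                fh.write(json.dumps({"provenance": self.provenance}, ensure_ascii=False) + "\n")
            for label in RELATION_LABELS:
                for snippet in self.examples.get(label, []):
                    fh.write(json.dumps({"snippet": snippet, "label": label}, ensure_ascii=False) + "\n")
            for snippet in self.none_examples:
                fh.write(json.dumps({"snippet": snippet, "label": NONE_LABEL}, ensure_ascii=False) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "ExampleBank":
        bank = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                record = json.loads(line)
                if "provenance" in record and "snippet" not in record:
                    bank.provenance = record["provenance"]
                    continue
                bank.add(record["snippet"], record["label"])
        bank.validate()
        return bank


@dataclass(frozen=True)
class PromptSpec:
    """A fully determined prompt, renderable to the final string."""

    regime: str  # multiclass | binary | zeroshot
    instruction: str
    answers: tuple[str, ...]
    examples: tuple[tuple[str, str], ...]  # (snippet, label) blocks, in order
    query: str
    relation: str | None = None

    @property
    def n_examples(self) -> int:
        return len(self.examples)

    def render(self) -> str:
        block_tpl = _template("example_block.txt")
        blocks = "".join(
            block_tpl.format(snippet=snippet, label=label)
            for snippet, label in self.examples
        )
        return _template("skeleton.txt").format(
            task=self.instruction.rstrip("\n"),
            answers=", ".join(self.answers),
            examples=blocks,
            query=self.query,
        )


def _check_instance(instance: RelationInstance) -> None:
    if not strip_markers(instance.snippet).strip():
        raise ValueError("instance snippet is empty")


def build_multiclass_prompt(bank: ExampleBank, instance: RelationInstance) -> PromptSpec:
    """2 examples per relation type, 14 blocks, full answer vocabulary."""
    _check_instance(instance)
    blocks: list[tuple[str, str]] = []
    for label in RELATION_LABELS:
        available = bank.examples.get(label, [])
        if len(available) < MULTICLASS_EXAMPLES_PER_TYPE:
            raise ValueError(
                f"example bank holds {len(available)} examples for {label}, "
                f"need {MULTICLASS_EXAMPLES_PER_TYPE}"
            )
        blocks += [(s, label) for s in available[:MULTICLASS_EXAMPLES_PER_TYPE]]
    instruction = _template("task_multiclass.txt").format(labels=", ".join(RELATION_LABELS))
    return PromptSpec(
        regime="multiclass",
        instruction=instruction,
        answers=RELATION_LABELS + (NONE_LABEL,),
        examples=tuple(blocks),
        query=instance.snippet,
    )


def _binary_instruction(relation: str) -> str:
    validate_relation_label(relation)
    return _template("task_binary.txt").format(
        relation=relation, definition=RELATION_DEFINITIONS[relation]
    )


def build_binary_prompt(
    bank: ExampleBank, relation: str, instance: RelationInstance
) -> PromptSpec:
    """3 positive + 3 NONE examples for one relation type."""
    _check_instance(instance)
    validate_relation_label(relation)
    positives = bank.examples.get(relation, [])
    if len(positives) < BINARY_POSITIVE_EXAMPLES:
        raise ValueError(
            f"example bank holds {len(positives)} positives for {relation}, "
            f"need {BINARY_POSITIVE_EXAMPLES}"
        )
    if len(bank.none_examples) < BINARY_NONE_EXAMPLES:
        raise ValueError(
            f"example bank holds {len(bank.none_examples)} NONE examples, "
            f"need {BINARY_NONE_EXAMPLES}"
        )
    blocks = [(s, relation) for s in positives[:BINARY_POSITIVE_EXAMPLES]]
    blocks += [(s, NONE_LABEL) for s in bank.none_examples[:BINARY_NONE_EXAMPLES]]
    return PromptSpec(
        regime="binary",
        instruction=_binary_instruction(relation),
        answers=(relation, NONE_LABEL),
        examples=tuple(blocks),
        query=instance.snippet,
        relation=relation,
    )


def build_zeroshot_prompt(relation: str, instance: RelationInstance) -> PromptSpec:
    """The binary prompt without its example blocks: definition + query only."""
    _check_instance(instance)
    validate_relation_label(relation)
    return PromptSpec(
        regime="zeroshot",
        instruction=_binary_instruction(relation),
        answers=(relation, NONE_LABEL),
        examples=(),
        query=instance.snippet,
        relation=relation,
    )
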