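"""Model backends behind a minimal completion contract, plus answer parsing.

The production client speaks the chat-completions HTTP contract of a locally
served model; its only network peer is the configured base URL, so no
clinical text leaves the host it points at. Tests and offline runs use the
deterministic mock backends.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Iterable, Protocol

from .schema import NONE_LABEL, RELATION_LABELS

__all__ = [
    "CompletionRequest",
    "ParsedAnswer",
    "Backend",
    "ChatCompletionsClient",
    "OracleBackend",
    "NoisyOracleBackend",
    "ScriptedBackend",
    "CountingBackend",
    "BackendError",
    "parse_answer",
]

logger = logging.getLogger(__name__)


class BackendError(RuntimeError):
    """Completion could not be obtained (after retries, if any)."""


@dataclass(frozen=True)
class CompletionRequest:
    """One prompt plus decoding controls.

    ``metadata`` carries pipeline bookkeeping (instance key, regime, queried
    relation); mock backends may consult it, network clients ignore it and
    never transmit it.
    """

    prompt: str
    model: str = ""
    temperature: float = 0.0
    max_tokens: int = 64
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.prompt:
            raise ValueError("prompt must be non-empty")


@dataclass(frozen=True)
class ParsedAnswer:
    label: str
    raw: str
    parse_status: str  # clean | fuzzy | unparseable


class Backend(Protocol):
    def complete(self, request: CompletionRequest) -> str: ...


class ChatCompletionsClient:
    """Minimal client for a locally served chat-completions endpoint."""

    def __init__(
        self,
        base_url: str,
        model: str,
        temperature: float = 0.0,
        max_tokens: int = 64,
        timeout: float = 60.0,
        retries: int = 2,
    ) -> None:
        self.base_url = base_url.rstrip("/")
        self.model = model
        self.temperature = temperature
        self.max_tokens = max_tokens
        self.timeout = timeout
        self.retries = retries

    def complete(self, request: CompletionRequest) -> str:
        payload = json.dumps(
            {
                "model": request.model or self.model,
                "messages": [{"role": "user", "content": request.prompt}],
                "temperature": request.temperature,
                "max_tokens": request.max_tokens,
            }
        ).encode("utf-8")
        url = f"{self.base_url}/chat/completions"
        last_error: Exception | None = None
        for attempt in range(self.retries + 1):
            try:
                req = urllib.request.Request(
                    url, data=payload, headers={"Content-Type": "application/json"}
                )
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    body = json.loads(resp.read().decode("utf-8"))
                return body["choices"][0]["message"]["content"]
            except (urllib.error.URLError, TimeoutError, KeyError, json.JSONDecodeError) as exc:
                last_error = exc
                if attempt < self.retries:
                    time.sleep(min(2.0**attempt, 8.0))
        raise BackendError(f"completion failed after {self.retries + 1} attempts: {last_error}")


class OracleBackend:
    """Test double answering every prompt with the gold label.

    ``gold`` maps instance keys ``(doc_id, source_id, target_id)`` to gold
    labels; requests identify themselves through metadata. Binary/zero-shot
    requests are answered relative to their queried relation.
    """

    def __init__(self, gold: dict[tuple[str, str, str], str]) -> None:
        self.gold = dict(gold)

    def _gold_for(self, request: CompletionRequest) -> str:
        meta = request.metadata
        try:
            key = (meta["doc_id"], meta["source_id"], meta["target_id"])
        except KeyError as exc:
            raise BackendError(f"oracle request lacks metadata field {exc}") from None
        if key not in self.gold:
            raise BackendError(f"oracle has no gold label for instance {key}")
        return self.gold[key]

    def complete(self, request: CompletionRequest) -> str:
        gold = self._gold_for(request)
        relation = request.metadata.get("relation")
        if relation is not None:  # binary / zero-shot sub-call
            return relation if gold == relation else NONE_LABEL
        return gold

    @classmethod
    def from_documents(cls, docs: Iterable) -> "OracleBackend":
        from .context import enumerate_pairs

        gold: dict[tuple[str, str, str], str] = {}
        for doc in docs:
            for inst in enumerate_pairs(doc, gold_corpus=True):
                gold[inst.key] = inst.gold
        return cls(gold)


class NoisyOracleBackend(OracleBackend):
    """Oracle with a seeded per-instance label-flip rate.

    The flip decision is a deterministic function of (seed, instance key,
    queried relation), so identical runs produce identical outputs
    regardless of call order.
    """

    def __init__(
        self,
        gold: dict[tuple[str, str, str], str],
        flip_rate: float = 0.0,
        seed: int = 0,
    ) -> None:
        super().__init__(gold)
        if not 0.0 <= flip_rate <= 1.0:
            raise ValueError("flip_rate must be in [0, 1]")
        self.flip_rate = flip_rate
        self.seed = seed

    def complete(self, request: CompletionRequest) -> str:
        gold = self._gold_for(request)
        meta = request.metadata
        relation = meta.get("relation")
        token = f"{self.seed}|{meta['doc_id']}|{meta['source_id']}|{meta['target_id']}|{relation}"
        digest = hashlib.sha256(token.encode("utf-8")).digest()
        rng = random.Random(int.from_bytes(digest[:8], "big"))
        if relation is not None:
            answer = relation if gold == relation else NONE_LABEL
            if rng.random() < self.flip_rate:
                answer = NONE_LABEL if answer == relation else relation
            return answer
        answer = gold
        if rng.random() < self.flip_rate:
            answer = rng.choice([l for l in RELATION_LABELS + (NONE_LABEL,) if l != gold])
        return answer


class ScriptedBackend:
    """Answers from a fixed function of the request; for constructed tests."""

    def __init__(self, respond) -> None:
        self._respond = respond

    def complete(self, request: CompletionRequest) -> str:
        return self._respond(request)


class CountingBackend:
    """Wrapper counting completion calls (for call-accounting tests)."""

    def __init__(self, inner: Backend) -> None:
        self.inner = inner
        self.calls = 0

    def complete(self, request: CompletionRequest) -> str:
        self.calls += 1
        return self.inner.complete(request)


_YES_TOKENS = ("yes", "oui")
_NO_TOKENS = ("no", "non")


def parse_answer(raw: str, allowed: Iterable[str]) -> ParsedAnswer:
    """Map free-text model output onto the closed answer vocabulary.

    Total function: an exact (case-insensitive) match is ``clean``; otherwise
    the longest allowed label occurring as a substring wins (``fuzzy``, so
    BEFORE-OVERLAP is never mistaken for BEFORE); binary yes/no phrasings are
    mapped onto the single non-NONE candidate; anything else falls back to
    NONE with status ``unparseable``.
    """
    allowed_set = list(dict.fromkeys(allowed))
    if not allowed_set:
        raise ValueError("allowed label set must be non-empty")
    stripped = raw.strip()
    for label in allowed_set:
        if stripped.upper() == label.upper():
            return ParsedAnswer(label=label, raw=raw, parse_status="clean")
    lowered = raw.lower()
    hits = [label for label in allowed_set if label.lower() in lowered]
    if hits:
        best = max(hits, key=lambda l: (len(l), -allowed_set.index(l)))
        return ParsedAnswer(label=best, raw=raw, parse_status="fuzzy")
    positives = [l for l in allowed_set if l != NONE_LABEL]
    if len(positives) == 1 and NONE_LABEL in allowed_set:
        words = {w.strip(".,;:!?") for w in lowered.split()}
        if words & set(_YES_TOKENS):
            return ParsedAnswer(label=positives[0], raw=raw, parse_status="fuzzy")
        if words & set(_NO_TOKENS):
            return ParsedAnswer(label=NONE_LABEL, raw=raw, parse_status="fuzzy")
    logger.warning("unparseable model answer: %r", raw[:120])
    return ParsedAnswer(label=NONE_LABEL, raw=raw, parse_status="unparseable")
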