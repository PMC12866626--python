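"""Generative relevance feedback: prompts, providers, and caching.

Each prompt carries three components — the mention span, its containing
sentence, and a task instruction — and asks a text-generation backend for
one of three feedback types:

* ``definition``: a context-aware one-sentence definition of the mention;
* ``n_synonyms``: a list of n exact synonyms / alternative phrasings;
* ``standard_name``: the standard community-recognized name, conditioned
  on the target terminology (e.g. "NCBI Taxonomy").

Providers implement a single ``complete(prompt) -> text`` call. The
templates are plain-text package assets so deployments can edit the
wording without touching code; the template id travels with each Feedback
record. Results are cached on disk as JSON-lines keyed by the mention
text, sentence hash, task, and provider, so repeated runs are free and
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Protocol, runtime_checkable

from .errors import ProviderError, ValidationError

__all__ = [
    "Mention",
    "FeedbackTask",
    "Feedback",
    "CompletionProvider",
    "MockProvider",
    "FeedbackCache",
    "make_prompt",
    "generate_feedback",
    "parse_prompt_fields",
    "load_template",
]

TEMPLATE_VERSION = "v1"
DEFAULT_SYNONYM_GRID = (1, 3, 5, 10)


@dataclass(frozen=True)
class Mention:
    """A span to normalize, with its context and gold annotation."""

    mention_id: str
    text: str
    sentence: str
    document_id: str = ""
    gold_cuis: tuple[str, ...] = ()
    split: Literal["train", "dev", "test"] = "test"

    def __post_init__(self):
        if not self.text:
            raise ValidationError(f"mention {self.mention_id}: empty span text")
        if self.split not in ("train", "dev", "test"):
            raise ValidationError(f"mention {self.mention_id}: bad split {self.split!r}")
        object.__setattr__(self, "gold_cuis", tuple(self.gold_cuis))
        if self.sentence and self.text not in self.sentence:
            warnings.warn(
                f"mention {self.mention_id}: span {self.text!r} not found in its sentence"
            )


@dataclass(frozen=True)
class FeedbackTask:
    """Which feedback to generate. ``n`` applies to n_synonyms only;
    ``terminology`` names the normalization target for standard_name."""

    kind: Literal["definition", "n_synonyms", "standard_name"]
    n: int = 10
    terminology: str = ""

    def __post_init__(self):
        if self.kind not in ("definition", "n_synonyms", "standard_name"):
            raise ValidationError(f"unknown feedback kind {self.kind!r}")
        if self.kind == "n_synonyms" and self.n < 1:
            raise ValidationError("n_synonyms requires n >= 1")
        if self.kind == "standard_name" and not self.terminology:
            raise ValidationError("standard_name requires a terminology label")

    @property
    def expected_units(self) -> int:
        return self.n if self.kind == "n_synonyms" else 1

    @property
    def key(self) -> str:
        if self.kind == "n_synonyms":
            return f"n_synonyms:{self.n}"
        if self.kind == "standard_name":
            return f"standard_name:{self.terminology}"
        return "definition"


@dataclass(frozen=True)
class Feedback:
    """Generated expansion content for one mention and one task."""

    task: FeedbackTask
    texts: tuple[str, ...]
    provider_id: str
    mention_id: str
    template_id: str = TEMPLATE_VERSION

    def __post_init__(self):
        object.__setattr__(self, "texts", tuple(t.strip() for t in self.texts))
        if not self.texts or any(not t for t in self.texts):
            raise ValidationError(
                f"feedback for {self.mention_id}: texts must be non-empty and stripped"
            )


@runtime_checkable
class CompletionProvider(Protocol):
    provider_id: str

    def complete(self, prompt: str) -> str: ...


def load_template(name: str) -> str:
    return (resources.files("grflink.templates") / f"{name}.txt").read_text(encoding="utf-8")


def make_prompt(mention: Mention, task: FeedbackTask) -> str:
    """Render the task's template with the mention span and its sentence."""
    template = load_template(task.kind)
    return template.format(
        mention=mention.text,
        sentence=mention.sentence,
        n=task.n,
        terminology=task.terminology,
    )


_MENTION_RE = re.compile(r'^Mention: "(.*)"$', re.MULTILINE)
_SYNONYM_RE = re.compile(r"a list of (\d+) exact synonyms")


def parse_prompt_fields(prompt: str) -> dict:
    """Recover (mention, task kind, n) from a rendered prompt.

    Exists so scripted/mock providers can answer through the same
    ``complete(prompt)`` contract real backends use; kept next to the
    templates because it must track their markers.
    """
    m = _MENTION_RE.search(prompt)
    if m is None:
        raise ValidationError("prompt has no mention marker")
    fields: dict = {"mention": m.group(1)}
    if "context-aware definition" in prompt:
        fields["kind"] = "definition"
    elif "exact synonyms" in prompt:
        fields["kind"] = "n_synonyms"
        n_match = _SYNONYM_RE.search(prompt)
        fields["n"] = int(n_match.group(1)) if n_match else 1
    elif "standard community-recognized name" in prompt:
        fields["kind"] = "standard_name"
    else:
        fields["kind"] = "unknown"
    return fields


class MockProvider:
    """Deterministic provider backed by a fixture table.

    The table maps ``(mention_text, task kind)`` to the canned response;
    a ``(mention_text, "*")`` entry is a per-mention fallback.
    """

    def __init__(self, table: dict[tuple[str, str], str], provider_id: str = "mock"):
        self.table = dict(table)
        self.provider_id = provider_id
        self.calls = 0

    @classmethod
    def from_jsonl(cls, path: str | Path, provider_id: str = "mock") -> "MockProvider":
        table = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            table[(rec["mention"], rec["task"])] = rec["response"]
        return cls(table, provider_id=provider_id)

    def complete(self, prompt: str) -> str:
        self.calls += 1
        fields = parse_prompt_fields(prompt)
        key = (fields["mention"], fields["kind"])
        if key in self.table:
            return self.table[key]
        fallback = (fields["mention"], "*")
        if fallback in self.table:
            return self.table[fallback]
        raise ProviderError(f"mock provider has no scripted answer for {key}")


class FeedbackCache:
    """Content-addressed JSON-lines cache of feedback records."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._records: dict[str, list[str]] = {}
        if self.path is not None and self.path.exists():
            for line in self.path.read_text(encoding="utf-8").splitlines():
                if line.strip():
                    rec = json.loads(line)
                    self._records[rec["key"]] = rec["texts"]

    @staticmethod
    def cache_key(mention: Mention, task: FeedbackTask, provider_id: str) -> str:
        sentence_hash = hashlib.sha256(mention.sentence.encode("utf-8")).hexdigest()[:16]
        raw = f"{provider_id}|{task.key}|{mention.text}|{sentence_hash}|{TEMPLATE_VERSION}"
        return hashlib.sha256(raw.encode("utf-8")).hexdigest()

    def get(self, key: str) -> list[str] | None:
        return self._records.get(key)

    def put(self, key: str, texts: list[str]) -> None:
        self._records[key] = list(texts)
        if self.path is not None:
            with self.path.open("a", encoding="utf-8") as fh:
                fh.write(json.dumps({"key": key, "texts": list(texts)}, sort_keys=True) + "\n")

    def __len__(self) -> int:
        return len(self._records)


_BULLET_RE = re.compile(r"^\s*(?:[-*•]|\d+[.)])\s*")


def _parse_units(raw: str, task: FeedbackTask) -> list[str]:
    """Split a raw completion into the task's text units.

    Synonym lists accept newline- or comma-separated output with optional
    bullets/numbering. A wrong count is repaired by truncation (never by
    fabricating items), with a warning.
    """
    text = raw.strip()
    if not text:
        raise ProviderError("provider returned an empty completion")
    if task.kind != "n_synonyms":
        return [" ".join(text.split())]
    lines = [_BULLET_RE.sub("", ln).strip() for ln in text.splitlines()]
    units = [ln for ln in lines if ln]
    if len(units) <= 1 and "," in text:
        units = [u.strip() for u in text.split(",") if u.strip()]
    if len(units) > task.n:
        warnings.warn(f"provider returned {len(units)} synonyms, truncating to {task.n}")
        units = units[: task.n]
    elif len(units) < task.n:
        warnings.warn(f"provider returned {len(units)} synonyms, expected {task.n}; keeping all")
    return units


def generate_feedback(
    provider: CompletionProvider,
    mention: Mention,
    task: FeedbackTask,
    cache: FeedbackCache | None = None,
    max_retries: int = 2,
) -> Feedback:
    """Obtain feedback for one mention, consulting the cache first.

    Transport failures are retried ``max_retries`` times, then surfaced as
    :class:`ProviderError` carrying the mention id.
    """
    key = FeedbackCache.cache_key(mention, task, provider.provider_id)
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return Feedback(
                task=task, texts=tuple(hit), provider_id=provider.provider_id,
                mention_id=mention.mention_id,
            )
    prompt = make_prompt(mention, task)
    last_error: Exception | None = None
    for _ in range(max_retries + 1):
        try:
            raw = provider.complete(prompt)
            break
        except ProviderError as err:
            last_error = err
    else:
        raise ProviderError(
            f"provider {provider.provider_id} failed after {max_retries + 1} attempts: "
            f"{last_error}", mention_id=mention.mention_id,
        )
    units = _parse_units(raw, task)
    if cache is not None:
        cache.put(key, units)
    return Feedback(
        task=task, texts=tuple(units), provider_id=provider.provider_id,
        mention_id=mention.mention_id,
    )
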