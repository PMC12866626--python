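"""Synthetic knowledge bases, corpora, and scripted feedback providers.

Every pipeline stage is exercised against generated data with controlled
structure: a KB with a chosen homonym rate and alias counts, a corpus
whose mentions are corrupted alias variants with injected composite,
out-of-vocabulary, and train-overlap mentions, and a scripted provider
whose feedback quality is a dial. Generation is a pure function of
(spec, seed): the same spec always yields byte-identical fixtures.

The corruption operators — adjacent-character swaps, case flips, suffix
truncation, and acronym formation from word initials — emulate the
lexical mismatch between mentions and KB names that relevance feedback
targets; acronyms in particular land far from any alias under a
character n-gram encoder, exactly the failure mode feedback repairs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import ProviderError, ValidationError
from .feedback import Mention, parse_prompt_fields
from .kb import Concept, KnowledgeBase, save_kb
from .io import write_corpus

__all__ = [
    "FixtureSpec",
    "generate_kb",
    "generate_corpus",
    "scripted_provider",
    "ScriptedGrfProvider",
    "write_fixture_dir",
]

_SYLLABLES = (
    "ba be bi bo bu ca ce ci co cu da de di do du fa fe fi fo fu ga ge gi go gu "
    "la le li lo lu ma me mi mo mu na ne ni no nu pa pe pi po pu ra re ri ro ru "
    "sa se si so su ta te ti to tu va ve vi vo vu za ze zi zo zu"
).split()

_HEAD_WORDS = ("syndrome", "disease", "disorder", "deficiency", "dysplasia", "carcinoma")

_SENTENCES = (
    "The patient was diagnosed with {m} at an early age.",
    "Previous studies implicated {m} in disease progression.",
    "We observed clinical markers of {m} in all affected samples.",
    "Treatment targeting {m} reduced symptom severity in the cohort.",
)


class FixtureSpec(BaseModel):
    """Declarative description of one synthetic study condition."""

    n_concepts: int = Field(default=300, ge=1)
    aliases_min: int = Field(default=2, ge=1)
    aliases_max: int = Field(default=5, ge=1)
    homonym_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    n_mentions: int = Field(default=150, ge=0, description="mentions per split")
    composite_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    oov_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    seen_overlap_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    feedback_quality: float = Field(default=1.0, ge=0.0, le=1.0)
    seed: int = 0
    kb_name: str = "SYN Diseases"

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        if self.aliases_max < self.aliases_min:
            raise ValueError("aliases_max must be >= aliases_min")
        if self.homonym_rate > 0 and self.n_concepts < 2:
            raise ValueError("homonym_rate > 0 requires at least 2 concepts")
        if self.composite_rate + self.oov_rate + self.seen_overlap_rate > 1.0:
            raise ValueError("composite + oov + seen_overlap rates must sum to <= 1")
        return self


def _pseudo_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))


def _fresh_name(rng: np.random.Generator, taken: set[str]) -> str:
    for _ in range(1000):
        n_words = int(rng.integers(1, 3))
        words = [_pseudo_word(rng, int(rng.integers(2, 4))) for _ in range(n_words)]
        name = " ".join(words + [str(rng.choice(_HEAD_WORDS))])
        if name not in taken:
            taken.add(name)
            return name
    raise ValidationError("could not generate a fresh unique name")  # pragma: no cover


def generate_kb(spec: FixtureSpec) -> KnowledgeBase:
    """Generate a KB whose fraction of homonymous names matches
    ``spec.homonym_rate`` up to rounding.

    Names are globally unique pseudo-terms; homonyms are then injected by
    adding a chosen fraction of names as an alias of a second concept.
    """
    rng = np.random.default_rng([spec.seed, 101])
    taken: set[str] = set()
    alias_sets: list[list[str]] = []
    for _ in range(spec.n_concepts):
        n_aliases = int(rng.integers(spec.aliases_min, spec.aliases_max + 1))
        alias_sets.append([_fresh_name(rng, taken) for _ in range(n_aliases)])

    total_names = sum(len(a) for a in alias_sets)
    n_homonyms = int(round(spec.homonym_rate * total_names))
    flat = [(ci, alias) for ci, aliases in enumerate(alias_sets) for alias in aliases]
    if n_homonyms:
        picks = rng.choice(len(flat), size=n_homonyms, replace=False)
        for p in picks:
            owner, alias = flat[int(p)]
            other = int(rng.integers(spec.n_concepts - 1))
            if other >= owner:
                other += 1
            alias_sets[other].append(alias)

    concepts = [
        Concept(
            cui=f"SYN:{i:06d}",
            preferred_name=aliases[0],
            aliases=frozenset(aliases),
        )
        for i, aliases in enumerate(alias_sets)
    ]
    return KnowledgeBase(concepts=concepts, name=spec.kb_name)


def _corrupt(text: str, rng: np.random.Generator) -> str:
    """Apply one lexical corruption operator; always returns non-empty."""
    words = text.split()
    op = rng.choice(["swap", "case", "truncate", "acronym"], p=[0.3, 0.2, 0.2, 0.3])
    if op == "acronym" and len(words) >= 2:
        return "".join(w[0] for w in words).upper()
    if op == "truncate" and len(text) > 6:
        cut = int(rng.integers(1, 4))
        return text[:-cut]
    if op == "case":
        style = rng.choice(["upper", "title", "capitalize"])
        return getattr(text, str(style))()
    # adjacent character swap (default / fallback)
    if len(text) < 3:
        return text
    i = int(rng.integers(0, len(text) - 2)) + 1
    swapped = text[: i - 1] + text[i] + text[i - 1] + text[i + 1 :]
    return swapped if swapped.strip() else text


def _mention_of(concept: Concept, rng: np.random.Generator) -> str:
    alias = str(rng.choice(sorted(concept.aliases)))
    return _corrupt(alias, rng)


def _sentence_for(text: str, rng: np.random.Generator) -> str:
    return str(rng.choice(_SENTENCES)).format(m=text)


def generate_corpus(spec: FixtureSpec, kb: KnowledgeBase) -> list[Mention]:
    """Generate train/dev/test mentions against ``kb`` at the spec rates.

    Train and dev mentions are plain corrupted aliases. Test mentions are
    drawn per-category: composite (two gold concepts), OOV (gold cui not
    in the KB), seen-overlap (verbatim copy of a train mention), or clean
    zero-shot (re-corrupted until lexically distinct from train/dev).
    """
    if len(kb) == 0:
        raise ValidationError("cannot generate a corpus against an empty KB")
    rng = np.random.default_rng([spec.seed, 202])
    concepts = sorted(kb.concepts, key=lambda c: c.cui)
    corpus: list[Mention] = []

    def add(split: str, i: int, text: str, gold: tuple[str, ...]) -> None:
        corpus.append(
            Mention(
                mention_id=f"{split}-{i:05d}",
                text=text,
                sentence=_sentence_for(text, rng),
                document_id=f"doc-{split}-{i // 5:04d}",
                gold_cuis=gold,
                split=split,  # type: ignore[arg-type]
            )
        )

    for split in ("train", "dev"):
        for i in range(spec.n_mentions):
            concept = concepts[int(rng.integers(len(concepts)))]
            add(split, i, _mention_of(concept, rng), (concept.cui,))

    seen_norm = {" ".join(m.text.split()).casefold() for m in corpus}
    train_pool = [m for m in corpus if m.split == "train"]

    def norm(text: str) -> str:
        return " ".join(text.split()).casefold()

    for i in range(spec.n_mentions):
        u = rng.random()
        if u < spec.composite_rate and len(concepts) >= 2:
            a, b = rng.choice(len(concepts), size=2, replace=False)
            ca, cb = concepts[int(a)], concepts[int(b)]
            text = f"{_mention_of(ca, rng)} and {_mention_of(cb, rng)}"
            add("test", i, text, (ca.cui, cb.cui))
        elif u < spec.composite_rate + spec.oov_rate:
            text = _corrupt(_pseudo_word(rng, 3) + " " + str(rng.choice(_HEAD_WORDS)), rng)
            add("test", i, text, (f"OOV:{i:06d}",))
        elif u < spec.composite_rate + spec.oov_rate + spec.seen_overlap_rate and train_pool:
            src = train_pool[int(rng.integers(len(train_pool)))]
            add("test", i, src.text, src.gold_cuis)
            continue  # deliberately duplicates a train text
        else:
            # Clean zero-shot mention: re-corrupt until the text is distinct
            # from every train/dev mention and every earlier test mention, so
            # the zero-shot filter keeps it and its gold concept is the
            # unique concept its text was derived from.
            concept = concepts[int(rng.integers(len(concepts)))]
            text = _mention_of(concept, rng)
            for _ in range(30):
                if norm(text) not in seen_norm:
                    break
                text = _mention_of(concept, rng)
            else:  # pragma: no cover - exceedingly unlikely at default sizes
                text = text + " variant"
            add("test", i, text, (concept.cui,))
        seen_norm.add(norm(text))
    return corpus


def _unit_uniform(*parts: object) -> float:
    """Deterministic uniform draw in [0, 1) keyed by the given parts."""
    raw = "|".join(str(p) for p in parts).encode("utf-8")
    digest = hashlib.blake2b(raw, digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2**64


def _stable_int(*parts: object) -> int:
    raw = "|".join(str(p) for p in parts).encode("utf-8")
    return int.from_bytes(hashlib.blake2b(raw, digest_size=8).digest(), "big")


class ScriptedGrfProvider:
    """Feedback provider scripted against the fixture KB and corpus.

    With probability ``feedback_quality`` (decided deterministically per
    mention and task from the seed) the answer is grounded in the gold
    concept: the preferred name for standard_name, gold aliases for
    n_synonyms, a template sentence embedding gold alias tokens for
    definition. Otherwise a distractor concept supplies the content.
    """

    def __init__(self, spec: FixtureSpec, kb: KnowledgeBase, corpus: list[Mention] | None = None):
        self.spec = spec
        self.kb = kb
        self.provider_id = f"scripted-q{spec.feedback_quality}-s{spec.seed}"
        self._gold_by_text: dict[str, str] = {}
        for m in corpus or []:
            if len(m.gold_cuis) == 1 and m.gold_cuis[0] in kb:
                self._gold_by_text.setdefault(m.text, m.gold_cuis[0])
        self._concepts = sorted(kb.concepts, key=lambda c: c.cui)

    def _concept_for(self, mention_text: str, task_kind: str) -> Concept:
        gold_cui = self._gold_by_text.get(mention_text)
        quality_draw = _unit_uniform(self.spec.seed, mention_text, task_kind, "q")
        if gold_cui is not None and quality_draw < self.spec.feedback_quality:
            return self.kb.get(gold_cui)
        # distractor: a deterministic concept other than gold
        idx = _stable_int(self.spec.seed, mention_text, task_kind, "d") % len(self._concepts)
        concept = self._concepts[idx]
        if gold_cui is not None and concept.cui == gold_cui and len(self._concepts) > 1:
            concept = self._concepts[(idx + 1) % len(self._concepts)]
        return concept

    def complete(self, prompt: str) -> str:
        fields = parse_prompt_fields(prompt)
        kind = fields["kind"]
        if kind not in ("definition", "n_synonyms", "standard_name"):
            raise ProviderError(f"scripted provider cannot answer task {kind!r}")
        concept = self._concept_for(fields["mention"], kind)
        aliases = sorted(concept.aliases)
        if kind == "standard_name":
            return concept.preferred_name
        if kind == "n_synonyms":
            n = fields.get("n", 1)
            return "\n".join(aliases[i % len(aliases)] for i in range(n))
        other = aliases[-1]
        return (
            f"{fields['mention']} refers to {concept.preferred_name}, "
            f"a condition also documented under the name {other}."
        )


def scripted_provider(
    spec: FixtureSpec, kb: KnowledgeBase, corpus: list[Mention] | None = None
) -> ScriptedGrfProvider:
    """Factory form of :class:`ScriptedGrfProvider`."""
    return ScriptedGrfProvider(spec, kb, corpus)


def write_fixture_dir(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialize kb.tsv, corpus.jsonl, and provider_script.jsonl."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kb = generate_kb(spec)
    corpus = generate_corpus(spec, kb)
    provider = ScriptedGrfProvider(spec, kb, corpus)
    paths = {
        "kb": outdir / "kb.tsv",
        "corpus": outdir / "corpus.jsonl",
        "provider_script": outdir / "provider_script.jsonl",
        "spec": outdir / "fixture_spec.json",
    }
    save_kb(kb, paths["kb"])
    write_corpus(corpus, paths["corpus"])
    from .feedback import FeedbackTask, make_prompt

    with paths["provider_script"].open("w", encoding="utf-8") as fh:
        tasks = [
            FeedbackTask(kind="definition"),
            FeedbackTask(kind="n_synonyms", n=10),
            FeedbackTask(kind="standard_name", terminology=kb.name),
        ]
        for m in sorted((m for m in corpus if m.split == "test"), key=lambda m: m.mention_id):
            for task in tasks:
                response = provider.complete(make_prompt(m, task))
                fh.write(
                    json.dumps(
                        {"mention": m.text, "task": task.kind, "response": response},
                        sort_keys=True,
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    paths["spec"].write_text(json.dumps(spec.model_dump(), indent=2, sort_keys=True) + "\n")
    return paths
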