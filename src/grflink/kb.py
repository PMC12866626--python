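"""Knowledge bases, homonym detection, and alias disambiguation.

A knowledge base (KB) maps concept unique identifiers (CUIs, e.g.
``MESH:D012779``) to sets of surface forms (aliases), one of which is the
preferred concept name. Name-based entity linking retrieves over the alias
strings, so aliases shared by several concepts ("homonyms") cause index
collisions: the same string would have to point at two different CUIs.
This module detects those collisions and rewrites each colliding alias,
per owning concept, into an unambiguous variant
``"<alias> (<preferred name of owner>)"`` so the final surface-form ->
CUI relation is a function.

The canonical on-disk dialect is a UTF-8 TSV with header
``cui<TAB>name<TAB>is_preferred`` and one alias per row.
"""

from __future__ import annotations

import csv
import unicodedata
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import KBFormatError, ValidationError

__all__ = [
    "Concept",
    "KnowledgeBase",
    "AliasEntry",
    "normalize_surface",
    "load_kb",
    "save_kb",
    "find_homonyms",
    "disambiguate_homonyms",
]

_HEADER = ("cui", "name", "is_preferred")


def normalize_surface(text: str) -> str:
    """Normalization used for name-collision checks: Unicode NFC, collapse
    internal whitespace, strip, casefold. Stored surface forms keep their
    original casing; only comparisons go through this."""
    t = unicodedata.normalize("NFC", text)
    t = " ".join(t.split())
    return t.casefold()


@dataclass(frozen=True)
class Concept:
    """One KB concept: identifier, preferred name, and its alias set."""

    cui: str
    preferred_name: str
    aliases: frozenset[str]

    def __post_init__(self):
        if not self.cui:
            raise ValidationError("concept cui must be non-empty")
        if not self.aliases:
            raise ValidationError(f"{self.cui}: alias set must be non-empty")
        if self.preferred_name not in self.aliases:
            raise ValidationError(
                f"{self.cui}: preferred name {self.preferred_name!r} not in aliases"
            )


@dataclass
class KnowledgeBase:
    """A collection of concepts with unique CUIs."""

    concepts: list[Concept]
    name: str = "kb"
    _by_cui: dict[str, Concept] = field(init=False, repr=False)

    def __post_init__(self):
        self._by_cui = {}
        for c in self.concepts:
            if c.cui in self._by_cui:
                raise ValidationError(f"duplicate cui {c.cui!r} in knowledge base")
            self._by_cui[c.cui] = c

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, cui: str) -> bool:
        return cui in self._by_cui

    def get(self, cui: str) -> Concept:
        return self._by_cui[cui]

    @property
    def cuis(self) -> set[str]:
        return set(self._by_cui)


@dataclass(frozen=True)
class AliasEntry:
    """One searchable index entry. ``surface_form`` is the (possibly
    disambiguated) string actually embedded; ``original_form`` is the raw
    KB alias it came from."""

    surface_form: str
    cui: str
    original_form: str
    was_homonym: bool = False


def load_kb(path: str | Path, dialect: str = "canonical", name: str | None = None) -> KnowledgeBase:
    """Read a KB from the canonical TSV dialect.

    Parameters
    ----------
    path:
        TSV file with header ``cui\\tname\\tis_preferred``.
    dialect:
        Only ``"canonical"`` is supported; the argument exists so future
        dialects keep the same entry point.
    name:
        Label for the normalization target; defaults to the file stem.

    Raises
    ------
    KBFormatError
        Malformed row (wrong column count, bad flag), with line number.
    ValidationError
        A cui with zero or more than one preferred-name rows.
    """
    if dialect != "canonical":
        raise KBFormatError(f"unknown KB dialect {dialect!r}")
    path = Path(path)
    rows_by_cui: dict[str, list[tuple[str, bool]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if lineno == 1:
                if tuple(h.strip() for h in row) != _HEADER:
                    raise KBFormatError(
                        f"expected header {list(_HEADER)}, got {row}", line=lineno
                    )
                continue
            if len(row) != 3:
                raise KBFormatError(f"expected 3 columns, got {len(row)}", line=lineno)
            cui, alias, flag = row[0].strip(), row[1], row[2].strip()
            if not cui:
                raise KBFormatError("empty cui", line=lineno)
            if flag not in ("0", "1"):
                raise KBFormatError(f"is_preferred must be 0 or 1, got {flag!r}", line=lineno)
            if not normalize_surface(alias):
                warnings.warn(f"{path.name} line {lineno}: dropping empty alias for {cui}")
                continue
            rows_by_cui.setdefault(cui, []).append((alias, flag == "1"))

    concepts = []
    for cui, rows in rows_by_cui.items():
        preferred = [a for a, p in rows if p]
        if len(preferred) != 1:
            raise ValidationError(
                f"cui {cui!r} has {len(preferred)} preferred names, expected exactly 1"
            )
        concepts.append(
            Concept(cui=cui, preferred_name=preferred[0], aliases=frozenset(a for a, _ in rows))
        )
    return KnowledgeBase(concepts=concepts, name=name or path.stem)


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write a KB in the canonical TSV dialect (sorted, reproducible)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for concept in sorted(kb.concepts, key=lambda c: c.cui):
            for alias in sorted(concept.aliases):
                writer.writerow([concept.cui, alias, int(alias == concept.preferred_name)])


def find_homonyms(kb: KnowledgeBase) -> dict[str, set[str]]:
    """Map each normalized surface form shared by >= 2 concepts to the set
    of CUIs sharing it. Forms unique to one concept are absent."""
    owners: dict[str, set[str]] = {}
    for concept in kb.concepts:
        for alias in concept.aliases:
            owners.setdefault(normalize_surface(alias), set()).add(concept.cui)
    return {form: cuis for form, cuis in owners.items() if len(cuis) >= 2}


def disambiguate_homonyms(kb: KnowledgeBase) -> list[AliasEntry]:
    """Produce collision-free alias entries for the whole KB.

    Every alias whose normalized form is shared across concepts is replaced,
    per owning concept, by ``"<alias> (<owner preferred name>)"``. If that
    variant still collides with another surface form, the CUI is appended as
    a secondary disambiguator and a warning is emitted. Non-homonymous
    aliases pass through byte-identical. Entries are sorted by
    (cui, surface_form) so index builds are reproducible.
    """
    homonyms = find_homonyms(kb)
    entries: list[AliasEntry] = []
    for concept in sorted(kb.concepts, key=lambda c: c.cui):
        for alias in sorted(concept.aliases):
            if not normalize_surface(alias):
                warnings.warn(f"dropping alias normalizing to empty string for {concept.cui}")
                continue
            if normalize_surface(alias) in homonyms:
                surface = f"{alias} ({concept.preferred_name})"
                entries.append(AliasEntry(surface, concept.cui, alias, was_homonym=True))
            else:
                entries.append(AliasEntry(alias, concept.cui, alias, was_homonym=False))

    # Resolve residual collisions: a disambiguated variant can still match
    # another surface form (e.g. two homonym owners sharing a preferred
    # name). Rename only forms whose normalized string is still claimed by
    # more than one cui; same-cui case variants are harmless and kept.
    norm_owners: dict[str, set[str]] = {}
    for e in entries:
        norm_owners.setdefault(normalize_surface(e.surface_form), set()).add(e.cui)
    resolved: list[AliasEntry] = []
    taken: set[str] = set()
    for e in entries:
        if len(norm_owners[normalize_surface(e.surface_form)]) > 1:
            warnings.warn(
                f"secondary collision on {e.surface_form!r}; appending cui {e.cui}"
            )
            variant = f"{e.original_form} ({kb.get(e.cui).preferred_name}; {e.cui})"
            e = AliasEntry(variant, e.cui, e.original_form, was_homonym=True)
        if e.surface_form in taken:
            continue  # duplicate row collapsed onto one entry
        taken.add(e.surface_form)
        resolved.append(e)
    return resolved
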