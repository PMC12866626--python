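"""The searchable alias index: embeddings for every disambiguated alias,
exact cosine top-k search, and directory persistence.

Search is an exhaustive scan (a matrix-vector product plus a sort), which
is exact by construction and fast far beyond the index sizes this package
targets; accelerated approximate backends can be slotted in later as long
as they reproduce the exhaustive result in the exact-search configuration.
Ties are broken deterministically by (higher score, lower cui, lower
surface form) so rankings are stable across platforms.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embedding import Embedder, QueryVector
from .errors import ConfigurationError, ValidationError
from .kb import AliasEntry

__all__ = ["AliasIndex", "build_index", "cosine_top_k", "save_index", "load_index"]


@dataclass
class AliasIndex:
    """Alias entries plus one embedding per entry (row-aligned)."""

    entries: list[AliasEntry]
    vectors: np.ndarray  # (n_entries, embedding_dim)
    embedder_id: str
    normalized: bool = True

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.entries):
            raise ValidationError(
                f"vectors shape {self.vectors.shape} does not match {len(self.entries)} entries"
            )
        surfaces = [e.surface_form for e in self.entries]
        if len(set(surfaces)) != len(surfaces):
            raise ValidationError("duplicate surface_form in index entries")

    @property
    def embedding_dim(self) -> int:
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def cuis(self) -> set[str]:
        return {e.cui for e in self.entries}


def build_index(entries: list[AliasEntry], embedder: Embedder, batch_size: int = 1024) -> AliasIndex:
    """Embed every entry's surface form, in entry order.

    Batches are encoded separately; a dimension change across batches means
    the backend is misconfigured and raises :class:`ConfigurationError`.
    """
    if not entries:
        raise ValidationError("cannot build an index from zero entries")
    blocks = []
    for start in range(0, len(entries), batch_size):
        block = embedder.encode([e.surface_form for e in entries[start : start + batch_size]])
        block = np.asarray(block, dtype=np.float64)
        if block.ndim != 2 or block.shape[1] != embedder.dim:
            raise ConfigurationError(
                f"embedder {embedder.id} returned dim {block.shape[-1]}, expected {embedder.dim}"
            )
        blocks.append(block)
    vectors = np.vstack(blocks)
    return AliasIndex(
        entries=list(entries),
        vectors=vectors,
        embedder_id=embedder.id,
        normalized=getattr(embedder, "normalizes", False),
    )


def cosine_top_k(index: AliasIndex, q: QueryVector, k: int) -> list[tuple[AliasEntry, float]]:
    """Exact cosine top-k over all index entries.

    Returns ``min(k, len(index))`` (entry, score) pairs with non-increasing
    scores; invariant to positive rescaling of ``q``.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if q.dim != index.embedding_dim:
        raise ValidationError(
            f"query dim {q.dim} does not match index dim {index.embedding_dim}"
        )
    qv = q.values
    qnorm = np.linalg.norm(qv)
    if qnorm == 0.0:
        raise ValidationError("cannot search with a zero query vector")
    scores = index.vectors @ (qv / qnorm)
    if not index.normalized:
        row_norms = np.linalg.norm(index.vectors, axis=1)
        row_norms[row_norms == 0.0] = 1.0
        scores = scores / row_norms
    k_eff = min(k, len(index.entries))
    # Full sort with the deterministic tie-break; index sizes here make the
    # O(n log n) cost irrelevant and the result platform-stable.
    ranked = sorted(
        range(len(index.entries)),
        key=lambda i: (-scores[i], index.entries[i].cui, index.entries[i].surface_form),
    )
    return [(index.entries[i], float(scores[i])) for i in ranked[:k_eff]]


def save_index(index: AliasIndex, directory: str | Path) -> None:
    """Persist as a directory: entries TSV + ``.npy`` matrix + JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "entries.tsv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["surface_form", "cui", "original_form", "was_homonym"])
        for e in index.entries:
            writer.writerow([e.surface_form, e.cui, e.original_form, int(e.was_homonym)])
    np.save(directory / "vectors.npy", index.vectors)
    manifest = {
        "embedder_id": index.embedder_id,
        "embedding_dim": index.embedding_dim,
        "n_entries": len(index),
        "normalized": index.normalized,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_index(directory: str | Path) -> AliasIndex:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    entries = []
    with (directory / "entries.tsv").open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for surface, cui, original, homonym in reader:
            entries.append(AliasEntry(surface, cui, original, was_homonym=homonym == "1"))
    vectors = np.load(directory / "vectors.npy")
    index = AliasIndex(
        entries=entries,
        vectors=vectors,
        embedder_id=manifest["embedder_id"],
        normalized=manifest["normalized"],
    )
    if index.embedding_dim != manifest["embedding_dim"] or len(index) != manifest["n_entries"]:
        raise ValidationError("index directory is inconsistent with its manifest")
    return index
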