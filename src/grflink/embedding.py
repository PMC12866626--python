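"""Text-embedding contract and the deterministic hashing n-gram backend.

Dense candidate retrieval only needs two things from an embedding model:
a fixed output dimension and determinism (same string, same vector). The
contract below captures that; any sentence-encoder can be adapted to it.
The shipped backend embeds a string as a bag of hashed character 3-grams
projected through a seeded random sign matrix and L2-normalized — fully
deterministic, correlated with string similarity (shared trigrams yield
nearby vectors), and dependency-free, which makes lexical-mismatch
phenomena (typos, abbreviations) behave qualitatively like they do with
learned encoders: small edits move the vector a little, acronym formation
moves it a lot.
"""

from __future__ import annotations

import hashlib
import unicodedata
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import ValidationError

__all__ = ["Embedder", "HashingNgramEmbedder", "QueryVector", "embed_texts"]


@dataclass(frozen=True)
class QueryVector:
    """A dense retrieval query: the vector plus where it came from
    (``mention``, ``feedback``, or ``fused``)."""

    values: np.ndarray
    source: str = "mention"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValidationError("query vector must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValidationError("query vector has non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


@runtime_checkable
class Embedder(Protocol):
    """Minimal encoder contract: stable id, fixed dim, batch encode."""

    id: str
    dim: int
    normalizes: bool

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        """Return an (n_texts, dim) float64 array, one row per input."""
        ...


def _bucket(ngram: str, n_buckets: int) -> int:
    # blake2b is stable across processes, unlike Python's hash().
    digest = hashlib.blake2b(ngram.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") % n_buckets


class HashingNgramEmbedder:
    """Hashed character-trigram bag with a seeded random-sign projection.

    Parameters
    ----------
    dim:
        Output dimensionality (default 64).
    n_buckets:
        Size of the trigram hash space before projection.
    seed:
        Seed of the sign-matrix generator; fixing it makes the embedder a
        pure function of its inputs across runs and machines.
    ngram:
        Character n-gram order; text is padded with one space per side so
        word boundaries contribute n-grams too.
    """

    def __init__(self, dim: int = 64, n_buckets: int = 4096, seed: int = 7, ngram: int = 3):
        if dim < 1 or n_buckets < dim:
            raise ValidationError("need n_buckets >= dim >= 1")
        self.dim = dim
        self.n_buckets = n_buckets
        self.seed = seed
        self.ngram = ngram
        self.normalizes = True
        self.id = f"hash-{ngram}gram-d{dim}-b{n_buckets}-s{seed}"
        rng = np.random.default_rng(seed)
        self._projection = rng.choice([-1.0, 1.0], size=(n_buckets, dim)) / np.sqrt(dim)

    def _counts(self, text: str) -> np.ndarray:
        t = unicodedata.normalize("NFC", text).casefold()
        t = " " + " ".join(t.split()) + " "
        counts = np.zeros(self.n_buckets)
        n = self.ngram
        grams = [t[i : i + n] for i in range(max(1, len(t) - n + 1))]
        for g in grams:
            counts[_bucket(g, self.n_buckets)] += 1.0
        return counts

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        if len(texts) == 0:
            return np.zeros((0, self.dim))
        out = np.empty((len(texts), self.dim))
        for i, text in enumerate(texts):
            if not text:
                raise ValidationError("cannot embed an empty string")
            v = self._counts(text) @ self._projection
            norm = np.linalg.norm(v)
            if norm == 0.0:  # all trigrams cancelled; fall back to a stable unit vector
                v = np.zeros(self.dim)
                v[_bucket(text, self.dim)] = 1.0
                norm = 1.0
            out[i] = v / norm
        return out


def embed_texts(
    embedder: Embedder, texts: Sequence[str], source: str = "mention"
) -> list[QueryVector]:
    """Encode ``texts`` in order, wrapping each row as a :class:`QueryVector`."""
    if any(not t for t in texts):
        raise ValidationError("texts must be non-empty strings")
    matrix = embedder.encode(list(texts))
    if matrix.shape != (len(texts), embedder.dim):
        raise ValidationError(
            f"embedder {embedder.id} returned shape {matrix.shape}, "
            f"expected ({len(texts)}, {embedder.dim})"
        )
    return [QueryVector(values=row, source=source) for row in matrix]
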