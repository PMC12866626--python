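"""Integration strategies for generative relevance feedback (GRF).

Feedback text generated for a mention can enter the retrieval pipeline at
three points:

* **text** — concatenate mention and feedback into one string before
  embedding;
* **vector** — embed them separately and interpolate with the Rocchio rule
  ``Q_grf = alpha * Q0 + (1 - alpha) * Qf`` (multi-synonym feedback is
  averaged into a single feedback vector first);
* **rank** — retrieve separately for mention and feedback and merge the
  two concept rankings with weighted reciprocal rank fusion,
  ``score(c) = alpha / rank_r0(c) + (1 - alpha) / rank_rf(c)``, where a
  term is omitted when the concept is absent from that list.

The reciprocal uses the raw 1-based rank with no additive smoothing
constant (the classic RRF ``+60`` offset is deliberately not applied).
``alpha`` in [0, 1] weights the original mention against the feedback;
``alpha = 1`` reduces every strategy to the mention-only baseline.

The *All-in-One* variants combine several feedback types at once: vector
fusion averages the mention vector with all n feedback vectors (the
``alpha = 1/(n+1)`` case of Rocchio), rank fusion sums plain reciprocal
ranks over all lists with equal weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .embedding import QueryVector
from .errors import ValidationError
from .feedback import Feedback

__all__ = [
    "FusionConfig",
    "Ranking",
    "fuse_text",
    "fuse_vector",
    "aggregate_synonym_vectors",
    "fuse_ranks",
    "all_in_one_vector",
    "all_in_one_rank",
]


@dataclass(frozen=True)
class FusionConfig:
    """How feedback is merged into the query.

    ``synonym_aggregation`` matters only for the rank strategy: the default
    ``mean_then_fuse`` averages synonym embeddings into one feedback query
    so the feedback contributes a single candidate list;
    ``per_synonym_lists`` gives every synonym its own list instead.
    """

    strategy: Literal["text", "vector", "rank"] = "vector"
    alpha: float = 0.5
    synonym_aggregation: Literal["mean_then_fuse", "per_synonym_lists"] = "mean_then_fuse"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.strategy not in ("text", "vector", "rank"):
            raise ValidationError(f"unknown fusion strategy {self.strategy!r}")


@dataclass
class Ranking:
    """Concept-level candidate ranking: (cui, surface_form, score) triples
    with 1-based ranks, non-increasing scores, and each cui at most once."""

    items: list[tuple[str, str, float]]
    query_source: str = "mention"
    _rank_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        cuis = [c for c, _, _ in self.items]
        if len(set(cuis)) != len(cuis):
            raise ValidationError("a cui appears more than once in a ranking")
        scores = [s for _, _, s in self.items]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValidationError("ranking scores must be non-increasing")
        self._rank_of = {c: i + 1 for i, c in enumerate(cuis)}

    def __len__(self) -> int:
        return len(self.items)

    def rank_of(self, cui: str) -> int | None:
        """1-based rank of ``cui``, or None if absent."""
        return self._rank_of.get(cui)

    @property
    def cuis(self) -> list[str]:
        return [c for c, _, _ in self.items]

    def top(self) -> tuple[str, str, float]:
        if not self.items:
            raise ValidationError("ranking is empty")
        return self.items[0]


def fuse_text(mention_text: str, feedback: Feedback, separator: str = " ") -> str:
    """Concatenate the mention span with all feedback text units."""
    if not mention_text:
        raise ValidationError("mention text must be non-empty")
    units = [t for t in feedback.texts if t.strip()]
    if not units:
        warnings.warn("feedback has no text; query is the bare mention")
        return mention_text
    return separator.join([mention_text, *units])


def fuse_vector(q0: QueryVector, qf: QueryVector, alpha: float, normalize: bool = True) -> QueryVector:
    """Rocchio interpolation ``alpha * Q0 + (1 - alpha) * Qf``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    if q0.dim != qf.dim:
        raise ValidationError(f"dim mismatch: {q0.dim} vs {qf.dim}")
    fused = alpha * q0.values + (1.0 - alpha) * qf.values
    if normalize:
        norm = np.linalg.norm(fused)
        if norm > 0.0:
            fused = fused / norm
    return QueryVector(values=fused, source="fused")


def aggregate_synonym_vectors(vectors: Sequence[QueryVector], normalize: bool = True) -> QueryVector:
    """Coordinate-wise mean of synonym embeddings (single feedback vector)."""
    if not vectors:
        raise ValidationError("need at least one vector to aggregate")
    dims = {v.dim for v in vectors}
    if len(dims) != 1:
        raise ValidationError(f"vectors have mixed dims {sorted(dims)}")
    mean = np.sum([v.values for v in vectors], axis=0) / len(vectors)
    if normalize:
        norm = np.linalg.norm(mean)
        if norm > 0.0:
            mean = mean / norm
    return QueryVector(values=mean, source="feedback")


def _sort_fused(scored: dict[str, tuple[float, int, str]], source: str) -> Ranking:
    """Order fused candidates by (score desc, cui asc); the surface kept is
    the one from the candidate's best-ranked occurrence."""
    items = [
        (cui, surface, score)
        for cui, (score, _, surface) in sorted(
            scored.items(), key=lambda kv: (-kv[1][0], kv[0])
        )
    ]
    return Ranking(items=items, query_source=source)


def fuse_ranks(r0: Ranking, rf: Ranking, alpha: float) -> Ranking:
    """Weighted reciprocal rank fusion of the mention and feedback lists.

    A concept absent from one list simply contributes no term from it.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    weighted = [(r0, alpha), (rf, 1.0 - alpha)]
    scored: dict[str, tuple[float, int, str]] = {}
    for ranking, weight in weighted:
        for position, (cui, surface, _) in enumerate(ranking.items, start=1):
            score, best_rank, best_surface = scored.get(cui, (0.0, np.inf, surface))
            score += weight / position
            if position < best_rank:
                best_rank, best_surface = position, surface
            scored[cui] = (score, best_rank, best_surface)
    return _sort_fused(scored, source="fused")


def all_in_one_vector(
    q0: QueryVector, feedback_vectors: Sequence[QueryVector], normalize: bool = True
) -> QueryVector:
    """Mean of the mention vector and all feedback vectors,
    ``(Q0 + sum Qf_i) / (n + 1)`` — Rocchio at ``alpha = 1/(n+1)``."""
    if not feedback_vectors:
        warnings.warn("no feedback vectors; returning the mention query unchanged")
        return q0
    dims = {q0.dim} | {v.dim for v in feedback_vectors}
    if len(dims) != 1:
        raise ValidationError(f"vectors have mixed dims {sorted(dims)}")
    total = q0.values.copy()
    for v in feedback_vectors:
        total = total + v.values
    fused = total / (len(feedback_vectors) + 1)
    if normalize:
        norm = np.linalg.norm(fused)
        if norm > 0.0:
            fused = fused / norm
    return QueryVector(values=fused, source="fused")


def all_in_one_rank(rankings: Sequence[Ranking]) -> Ranking:
    """Equal-weight reciprocal rank fusion over the mention list and one
    list per feedback type: ``score(c) = sum over lists of 1/rank(c)``."""
    if len(rankings) < 2:
        raise ValidationError("all-in-one rank fusion needs at least two rankings")
    scored: dict[str, tuple[float, int, str]] = {}
    for ranking in rankings:
        for position, (cui, surface, _) in enumerate(ranking.items, start=1):
            score, best_rank, best_surface = scored.get(cui, (0.0, np.inf, surface))
            score += 1.0 / position
            if position < best_rank:
                best_rank, best_surface = position, surface
            scored[cui] = (score, best_rank, best_surface)
    return _sort_fused(scored, source="fused")
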