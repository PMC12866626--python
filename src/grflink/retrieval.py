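"""End-to-end candidate generation.

The retrieval query is built per strategy (baseline mention, text-fused
string, Rocchio-interpolated vector, or separate queries merged by
reciprocal rank fusion), searched against the alias index by cosine
similarity, and the surface-form hits are collapsed to concept level:
each concept keeps only its best-scoring surface form.

Surface-form search depth exceeds the requested concept cutoff
(``k_search = max(4k, 64)`` by default, or the whole index in exact-scan
mode) so that collapsing many aliases of one concept never starves the
cutoff.

:class:`GrfRetriever` packages the same pipeline as a scikit-learn style
estimator: ``fit`` on a knowledge base builds the disambiguated index,
``rank`` / ``predict`` retrieve for mentions.
"""

from __future__ import annotations

from dataclasses import dataclass

from sklearn.base import BaseEstimator

from .embedding import Embedder, HashingNgramEmbedder, QueryVector, embed_texts
from .errors import ValidationError
from .feedback import Feedback, Mention
from .fusion import (
    FusionConfig,
    Ranking,
    aggregate_synonym_vectors,
    all_in_one_rank,
    all_in_one_vector,
    fuse_ranks,
    fuse_text,
    fuse_vector,
)
from .index import AliasIndex, build_index, cosine_top_k
from .kb import AliasEntry, KnowledgeBase, disambiguate_homonyms

__all__ = ["RetrievalRequest", "collapse_to_concepts", "retrieve_candidates", "GrfRetriever"]


@dataclass(frozen=True)
class RetrievalRequest:
    """One retrieval job: a mention, optional feedback, fusion settings,
    and the concept-level cutoff k."""

    mention: Mention
    feedbacks: tuple[Feedback, ...] = ()
    fusion: FusionConfig | None = None
    k: int = 10

    def __post_init__(self):
        object.__setattr__(self, "feedbacks", tuple(self.feedbacks))
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if bool(self.feedbacks) != (self.fusion is not None):
            raise ValidationError(
                "fusion config must be present exactly when feedbacks are supplied"
            )


def collapse_to_concepts(
    hits: list[tuple[AliasEntry, float]], source: str = "mention"
) -> Ranking:
    """Keep, for each concept, only its highest-scoring surface form.

    ``hits`` must already be sorted by score (as returned by the index
    search); the first hit for a cui is therefore its best one.
    """
    items: list[tuple[str, str, float]] = []
    seen: set[str] = set()
    for entry, score in hits:
        if entry.cui in seen:
            continue
        seen.add(entry.cui)
        items.append((entry.cui, entry.surface_form, score))
    return Ranking(items=items, query_source=source)


def _search_depth(k: int, index_size: int, exact_scan: bool) -> int:
    return index_size if exact_scan else min(max(4 * k, 64), index_size)


def _query_and_collapse(
    index: AliasIndex, q: QueryVector, k: int, exact_scan: bool, source: str
) -> Ranking:
    depth = _search_depth(k, len(index), exact_scan)
    hits = cosine_top_k(index, q, depth)
    ranking = collapse_to_concepts(hits, source=source)
    return Ranking(items=ranking.items[:k], query_source=source)


def _feedback_vector(
    feedback: Feedback, embedder: Embedder, normalize: bool
) -> QueryVector:
    vectors = embed_texts(embedder, list(feedback.texts), source="feedback")
    if len(vectors) == 1:
        return vectors[0]
    return aggregate_synonym_vectors(vectors, normalize=normalize)


def retrieve_candidates(
    request: RetrievalRequest,
    index: AliasIndex,
    embedder: Embedder,
    exact_scan: bool = False,
    normalize: bool = True,
    text_separator: str = " ",
) -> Ranking:
    """Run one retrieval request and return the concept-level ranking.

    Strategy dispatch: no feedback embeds the bare mention; ``text``
    embeds the concatenated string; ``vector`` interpolates embeddings
    (averaging synonym embeddings first); ``rank`` issues one query per
    list and fuses rankings. Supplying more than one feedback switches to
    the corresponding All-in-One combination.
    """
    if embedder.dim != index.embedding_dim:
        raise ValidationError(
            f"embedder dim {embedder.dim} does not match index dim {index.embedding_dim}"
        )
    mention = request.mention
    k = request.k
    [q0] = embed_texts(embedder, [mention.text], source="mention")

    if not request.feedbacks:
        return _query_and_collapse(index, q0, k, exact_scan, source="mention")

    fusion = request.fusion
    assert fusion is not None
    if fusion.strategy == "text":
        fused_text = mention.text
        for fb in request.feedbacks:
            fused_text = fuse_text(fused_text, fb, separator=text_separator)
        [q] = embed_texts(embedder, [fused_text], source="fused")
        return _query_and_collapse(index, q, k, exact_scan, source="fused")

    if fusion.strategy == "vector":
        fb_vectors = [
            _feedback_vector(fb, embedder, normalize) for fb in request.feedbacks
        ]
        if len(fb_vectors) == 1:
            q = fuse_vector(q0, fb_vectors[0], fusion.alpha, normalize=normalize)
        else:  # All-in-One: average mention and all feedback vectors
            q = all_in_one_vector(q0, fb_vectors, normalize=normalize)
        return _query_and_collapse(index, q, k, exact_scan, source="fused")

    # rank strategy
    r0 = _query_and_collapse(index, q0, _rank_depth(k), exact_scan, source="mention")
    feedback_rankings: list[Ranking] = []
    for fb in request.feedbacks:
        if fusion.synonym_aggregation == "per_synonym_lists" and len(fb.texts) > 1:
            for vec in embed_texts(embedder, list(fb.texts), source="feedback"):
                feedback_rankings.append(
                    _query_and_collapse(index, vec, _rank_depth(k), exact_scan, "feedback")
                )
        else:
            qf = _feedback_vector(fb, embedder, normalize)
            feedback_rankings.append(
                _query_and_collapse(index, qf, _rank_depth(k), exact_scan, "feedback")
            )
    if len(feedback_rankings) == 1:
        fused = fuse_ranks(r0, feedback_rankings[0], fusion.alpha)
    else:  # All-in-One: equal-weight RRF over all lists
        fused = all_in_one_rank([r0, *feedback_rankings])
    return Ranking(items=fused.items[:k], query_source="fused")


def _rank_depth(k: int) -> int:
    """Depth of the per-query concept lists fed into rank fusion; well
    beyond the evaluation cutoffs so fusion sees enough candidates."""
    return max(4 * k, 64)


class GrfRetriever(BaseEstimator):
    """Knowledge-base candidate retriever with optional GRF fusion.

    Parameters
    ----------
    embedder:
        Embedding backend; defaults to the deterministic hashing trigram
        encoder at dim 64.
    strategy, alpha, synonym_aggregation:
        Fusion settings applied when feedback is supplied at query time.
    k:
        Concept-level cutoff of returned rankings.
    exact_scan:
        Score every index entry instead of the truncated search depth.

    Attributes
    ----------
    index_ : AliasIndex
        Embedded, homonym-disambiguated alias index (after ``fit``).
    entries_ : list[AliasEntry]
        The disambiguated entries backing the index.
    """

    def __init__(
        self,
        embedder: Embedder | None = None,
        strategy: str = "vector",
        alpha: float = 0.5,
        synonym_aggregation: str = "mean_then_fuse",
        k: int = 10,
        exact_scan: bool = False,
        normalize: bool = True,
    ):
        self.embedder = embedder
        self.strategy = strategy
        self.alpha = alpha
        self.synonym_aggregation = synonym_aggregation
        self.k = k
        self.exact_scan = exact_scan
        self.normalize = normalize

    def _effective_embedder(self) -> Embedder:
        return self.embedder if self.embedder is not None else HashingNgramEmbedder()

    def fit(self, X: KnowledgeBase, y=None) -> "GrfRetriever":
        """Disambiguate homonyms in the KB and build the alias index."""
        if not isinstance(X, KnowledgeBase):
            raise ValidationError("GrfRetriever.fit expects a KnowledgeBase")
        self.embedder_ = self._effective_embedder()
        self.entries_ = disambiguate_homonyms(X)
        self.index_ = build_index(self.entries_, self.embedder_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "index_"):
            raise ValidationError("GrfRetriever is not fitted; call fit(kb) first")

    def rank(
        self,
        mentions: list[Mention],
        feedbacks: dict[str, list[Feedback]] | None = None,
    ) -> dict[str, Ranking]:
        """Concept rankings per mention id. ``feedbacks`` maps mention_id
        to that mention's feedback list; mentions absent from it run the
        mention-only baseline."""
        self._check_fitted()
        fusion = FusionConfig(
            strategy=self.strategy,  # type: ignore[arg-type]
            alpha=self.alpha,
            synonym_aggregation=self.synonym_aggregation,  # type: ignore[arg-type]
        )
        out: dict[str, Ranking] = {}
        for mention in mentions:
            fbs = tuple((feedbacks or {}).get(mention.mention_id, ()))
            request = RetrievalRequest(
                mention=mention,
                feedbacks=fbs,
                fusion=fusion if fbs else None,
                k=self.k,
            )
            out[mention.mention_id] = retrieve_candidates(
                request,
                self.index_,
                self.embedder_,
                exact_scan=self.exact_scan,
                normalize=self.normalize,
            )
        return out

    def predict(
        self,
        mentions: list[Mention],
        feedbacks: dict[str, list[Feedback]] | None = None,
    ) -> list[str]:
        """Top-1 concept identifier per mention (empty string if the
        ranking came back empty)."""
        rankings = self.rank(mentions, feedbacks)
        return [
            rankings[m.mention_id].items[0][0] if len(rankings[m.mention_id]) else ""
            for m in mentions
        ]
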