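"""Refined zero-shot evaluation protocol and recall@k scoring.

Official test splits overstate linking performance because many test
mentions also occur verbatim in the training data. The refined protocol
therefore keeps only zero-shot test mentions, applying three filters in a
fixed order so the reported tallies are unambiguous:

1. **composite** — mentions annotated with more than one gold concept
   admit no unique linking decision and are removed;
2. **OOV** — mentions whose gold concept identifier is no longer present
   in the current KB release are removed;
3. **zero-shot** — test mentions whose normalized text also occurs among
   train/dev mentions are removed (dev counts as seen).

Scoring is recall@k: the fraction of retained test mentions whose gold
concept appears within the top-k candidates; recall@1 is accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ValidationError
from .feedback import Mention
from .fusion import Ranking
from .kb import KnowledgeBase, normalize_surface

__all__ = ["RefinementReport", "EvalReport", "refine_test_set", "recall_at_k"]

DEFAULT_CUTOFFS = (1, 2, 3, 5, 10)


@dataclass(frozen=True)
class RefinementReport:
    """Tallies of the test-set refinement, one per filter."""

    n_input: int
    n_composite_removed: int
    n_oov_removed: int
    n_seen_removed: int
    n_retained: int

    def __post_init__(self):
        removed = self.n_composite_removed + self.n_oov_removed + self.n_seen_removed
        if min(self.n_input, self.n_retained, removed) < 0:
            raise ValidationError("refinement counts must be non-negative")
        if self.n_retained != self.n_input - removed:
            raise ValidationError("refinement counts do not add up")


@dataclass(frozen=True)
class EvalReport:
    """recall@k per cutoff over the scored mentions."""

    recall_at: dict[int, float]
    n_mentions: int
    config_fingerprint: str = ""

    def __post_init__(self):
        cutoffs = sorted(self.recall_at)
        values = [self.recall_at[c] for c in cutoffs]
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise ValidationError("recall values must lie in [0, 1]")
        if any(a > b + 1e-12 for a, b in zip(values, values[1:])):
            raise ValidationError("recall@k must be non-decreasing in k")


def refine_test_set(
    corpus: list[Mention],
    kb: KnowledgeBase,
    case_sensitive: bool = False,
) -> tuple[list[Mention], RefinementReport]:
    """Apply composite -> OOV -> zero-shot filtering to the test split.

    Train/dev mentions define the "seen" vocabulary; the overlap check
    compares whitespace-collapsed text, case-insensitively by default.
    """
    def norm(text: str) -> str:
        collapsed = " ".join(text.split())
        return collapsed if case_sensitive else normalize_surface(collapsed)

    seen_texts = {norm(m.text) for m in corpus if m.split in ("train", "dev")}
    test = [m for m in corpus if m.split == "test"]
    for m in test:
        if not m.gold_cuis:
            raise ValidationError(f"test mention {m.mention_id} lacks a gold cui")

    n_input = len(test)
    after_composite = [m for m in test if len(m.gold_cuis) == 1]
    n_composite = n_input - len(after_composite)

    after_oov = [m for m in after_composite if m.gold_cuis[0].strip() in kb]
    n_oov = len(after_composite) - len(after_oov)

    retained = [m for m in after_oov if norm(m.text) not in seen_texts]
    n_seen = len(after_oov) - len(retained)

    report = RefinementReport(
        n_input=n_input,
        n_composite_removed=n_composite,
        n_oov_removed=n_oov,
        n_seen_removed=n_seen,
        n_retained=len(retained),
    )
    return retained, report


def recall_at_k(
    predictions: dict[str, Ranking],
    gold: dict[str, str],
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS,
    config_fingerprint: str = "",
) -> EvalReport:
    """Fraction of mentions whose gold cui occurs at rank <= k.

    Mentions without a prediction entry count as misses (with a warning);
    gold matching is exact string equality after trimming, including the
    identifier namespace prefix.
    """
    if not gold:
        raise ValidationError("empty gold set")
    if any(c < 1 for c in cutoffs):
        raise ValidationError("cutoffs must be positive")
    cutoffs = tuple(sorted(set(cutoffs)))
    hits_at = {c: 0 for c in cutoffs}
    for mention_id, gold_cui in gold.items():
        ranking = predictions.get(mention_id)
        if ranking is None:
            warnings.warn(f"no prediction for mention {mention_id}; counted as a miss")
            continue
        rank = ranking.rank_of(gold_cui.strip())
        if rank is None:
            continue
        for c in cutoffs:
            if rank <= c:
                hits_at[c] += 1
    n = len(gold)
    return EvalReport(
        recall_at={c: hits_at[c] / n for c in cutoffs},
        n_mentions=n,
        config_fingerprint=config_fingerprint,
    )
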