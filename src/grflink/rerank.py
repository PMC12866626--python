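"""Final linking decisions from candidate rankings.

Two strategies: *pick-top-1* takes the best retrieved concept directly;
*LLM re-ranking* shows the top-k candidates (surface form, plus preferred
name when a KB is supplied) to a generation provider and asks for the
index of the best match. A re-ranker can only choose among the candidates
it is shown, so its corpus accuracy is bounded above by recall@k of the
input rankings — the bounded-recall property high-recall candidate
generation exists to relax.

Unparseable or failed provider answers fall back to pick-top-1 and are
flagged on the decision.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .errors import ProviderError
from .feedback import CompletionProvider, Mention, load_template
from .fusion import Ranking
from .kb import KnowledgeBase

__all__ = ["LinkingDecision", "pick_top1", "rerank_with_provider", "make_rerank_prompt", "OracleRerankProvider"]

DEFAULT_CONTEXT_SIZES = (2, 3, 5, 10)


@dataclass(frozen=True)
class LinkingDecision:
    """The chosen concept for one mention; ``chosen_cui`` empty means
    abstain (empty candidate list)."""

    mention_id: str
    chosen_cui: str
    method: str  # pick_top1 | llm_rerank
    k_context: int = 1
    fallback: bool = False  # llm answer unusable; fell back to top-1


def pick_top1(ranking: Ranking, mention_id: str = "") -> LinkingDecision:
    """Select the rank-1 concept; abstain on an empty ranking."""
    if len(ranking) == 0:
        warnings.warn(f"empty ranking for mention {mention_id!r}; abstaining")
        return LinkingDecision(mention_id=mention_id, chosen_cui="", method="pick_top1")
    return LinkingDecision(
        mention_id=mention_id, chosen_cui=ranking.items[0][0], method="pick_top1"
    )


def make_rerank_prompt(
    mention: Mention, ranking: Ranking, k: int, kb: KnowledgeBase | None = None
) -> str:
    """Render the re-ranking prompt listing the top-k candidates."""
    lines = []
    for i, (cui, surface, _) in enumerate(ranking.items[:k], start=1):
        if kb is not None and cui in kb:
            lines.append(f"{i}. {cui}\t{surface}\t(preferred name: {kb.get(cui).preferred_name})")
        else:
            lines.append(f"{i}. {cui}\t{surface}")
    return load_template("rerank").format(
        mention_id=mention.mention_id,
        mention=mention.text,
        sentence=mention.sentence,
        candidates="\n".join(lines),
    )


_INT_RE = re.compile(r"\d+")


def rerank_with_provider(
    mention: Mention,
    ranking: Ranking,
    k: int,
    provider: CompletionProvider,
    kb: KnowledgeBase | None = None,
) -> LinkingDecision:
    """Ask the provider to pick one of the top-k candidates.

    ``k = 1`` degenerates to pick-top-1 (there is nothing to choose).
    """
    if len(ranking) == 0:
        return pick_top1(ranking, mention.mention_id)
    k_eff = min(k, len(ranking))
    if k_eff <= 1:
        top = pick_top1(ranking, mention.mention_id)
        return LinkingDecision(
            mention_id=mention.mention_id, chosen_cui=top.chosen_cui,
            method="llm_rerank", k_context=k_eff,
        )
    prompt = make_rerank_prompt(mention, ranking, k_eff, kb=kb)
    fallback = False
    choice = 1
    try:
        answer = provider.complete(prompt)
        match = _INT_RE.search(answer)
        if match is None or not 1 <= int(match.group()) <= k_eff:
            warnings.warn(
                f"unparseable re-rank answer {answer!r} for {mention.mention_id}; "
                "falling back to top-1"
            )
            fallback = True
        else:
            choice = int(match.group())
    except ProviderError as err:
        warnings.warn(f"re-rank provider failed ({err}); falling back to top-1")
        fallback = True
    return LinkingDecision(
        mention_id=mention.mention_id,
        chosen_cui=ranking.items[choice - 1][0],
        method="llm_rerank",
        k_context=k_eff,
        fallback=fallback,
    )


class OracleRerankProvider:
    """Scripted re-ranker that answers the gold candidate whenever it is
    listed. Its accuracy over a corpus equals recall@k of the input
    rankings exactly, which makes it the reference point for the
    bounded-recall law in tests and experiments."""

    provider_id = "oracle-rerank"

    _ID_RE = re.compile(r"^Mention id: (.*)$", re.MULTILINE)
    _CAND_RE = re.compile(r"^(\d+)\. (\S+)\t", re.MULTILINE)

    def __init__(self, gold: dict[str, str]):
        self.gold = dict(gold)

    def complete(self, prompt: str) -> str:
        id_match = self._ID_RE.search(prompt)
        if id_match is None:
            raise ProviderError("prompt has no mention id marker")
        gold_cui = self.gold.get(id_match.group(1).strip())
        for number, cui in self._CAND_RE.findall(prompt):
            if cui == gold_cui:
                return number
        return "none of the candidates match"  # unparseable -> top-1 fallback
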