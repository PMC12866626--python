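"""JSON-lines readers/writers for corpora, candidate rankings, and
linking decisions. All writers emit sorted keys and ``\\n`` line endings
so identical runs produce byte-identical artifacts."""

from __future__ import annotations

import json
from pathlib import Path

from .feedback import Mention
from .fusion import Ranking
from .rerank import LinkingDecision

__all__ = [
    "read_corpus",
    "write_corpus",
    "read_rankings",
    "write_rankings",
    "write_decisions",
]


def _dump(record: dict) -> str:
    return json.dumps(record, sort_keys=True, ensure_ascii=False)


def write_corpus(corpus: list[Mention], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for m in corpus:
            fh.write(
                _dump(
                    {
                        "mention_id": m.mention_id,
                        "text": m.text,
                        "sentence": m.sentence,
                        "document_id": m.document_id,
                        "gold_cuis": list(m.gold_cuis),
                        "split": m.split,
                    }
                )
                + "\n"
            )


def read_corpus(path: str | Path) -> list[Mention]:
    corpus = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        corpus.append(
            Mention(
                mention_id=rec["mention_id"],
                text=rec["text"],
                sentence=rec.get("sentence", ""),
                document_id=rec.get("document_id", ""),
                gold_cuis=tuple(rec.get("gold_cuis", ())),
                split=rec.get("split", "test"),
            )
        )
    return corpus


def write_rankings(rankings: dict[str, Ranking], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for mention_id in sorted(rankings):
            r = rankings[mention_id]
            fh.write(
                _dump(
                    {
                        "mention_id": mention_id,
                        "query_source": r.query_source,
                        "candidates": [
                            [cui, surface, round(score, 12)] for cui, surface, score in r.items
                        ],
                    }
                )
                + "\n"
            )


def read_rankings(path: str | Path) -> dict[str, Ranking]:
    rankings = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        rankings[rec["mention_id"]] = Ranking(
            items=[(c, s, float(v)) for c, s, v in rec["candidates"]],
            query_source=rec.get("query_source", "mention"),
        )
    return rankings


def write_decisions(decisions: list[LinkingDecision], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in sorted(decisions, key=lambda d: d.mention_id):
            fh.write(
                _dump(
                    {
                        "mention_id": d.mention_id,
                        "chosen_cui": d.chosen_cui,
                        "method": d.method,
                        "k_context": d.k_context,
                        "fallback": d.fallback,
                    }
                )
                + "\n"
            )
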