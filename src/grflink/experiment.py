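"""Run orchestration: one declarative config drives index build,
feedback generation, retrieval, refinement, scoring, and optional
linking, leaving a manifest sufficient to reproduce the run.

With the deterministic embedder and a scripted or mock provider, a run
is a pure function of its config: two executions write byte-identical
candidates, decisions, and reports.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field

from . import __version__
from .embedding import HashingNgramEmbedder
from .errors import ConfigurationError
from .evaluation import EvalReport, RefinementReport, recall_at_k, refine_test_set
from .feedback import (
    TEMPLATE_VERSION,
    CompletionProvider,
    Feedback,
    FeedbackCache,
    FeedbackTask,
    MockProvider,
    generate_feedback,
)
from .fixtures import FixtureSpec, scripted_provider
from .io import read_corpus, write_decisions, write_rankings
from .kb import load_kb
from .rerank import OracleRerankProvider, pick_top1, rerank_with_provider
from .retrieval import GrfRetriever

__all__ = ["RunConfig", "run_experiment", "run_alpha_sweep"]


class EmbedderConfig(BaseModel):
    backend: Literal["toy"] = "toy"
    dim: int = 64
    n_buckets: int = 4096
    seed: int = 7


class ProviderConfig(BaseModel):
    backend: Literal["scripted", "mock", "none"] = "scripted"
    script_path: str | None = None  # mock: JSONL fixture table
    feedback_quality: float = 1.0  # scripted
    seed: int = 0  # scripted


class TaskConfig(BaseModel):
    kind: Literal["definition", "n_synonyms", "standard_name"]
    n: int = 10
    terminology: str = ""


class FusionSection(BaseModel):
    strategy: Literal["text", "vector", "rank"] = "vector"
    alpha: float = Field(default=0.5, ge=0.0, le=1.0)
    synonym_aggregation: Literal["mean_then_fuse", "per_synonym_lists"] = "mean_then_fuse"


class LinkConfig(BaseModel):
    method: Literal["pick_top1", "llm_rerank", "oracle_rerank"] = "pick_top1"
    k: int = 5


class RunConfig(BaseModel):
    """Everything one experiment needs; see docs for field semantics."""

    kb_path: str
    corpus_path: str
    kb_name: str | None = None
    embedder: EmbedderConfig = EmbedderConfig()
    provider: ProviderConfig = ProviderConfig()
    tasks: list[TaskConfig] = []
    fusion: FusionSection = FusionSection()
    cutoffs: list[int] = [1, 2, 3, 5, 10]
    k: int = 64
    seed: int = 0
    output_dir: str = "runs/run"

    def fingerprint(self) -> str:
        # output_dir only says where artifacts land; it is not part of the
        # scientific configuration, so two runs of the same experiment into
        # different directories share a fingerprint.
        payload = self.model_dump(exclude={"output_dir"})
        blob = json.dumps(payload, sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_provider(config: RunConfig, kb, corpus) -> CompletionProvider | None:
    p = config.provider
    if p.backend == "none":
        return None
    if p.backend == "mock":
        if not p.script_path:
            raise ConfigurationError("mock provider requires script_path")
        return MockProvider.from_jsonl(p.script_path)
    spec = FixtureSpec(feedback_quality=p.feedback_quality, seed=p.seed, kb_name=kb.name)
    return scripted_provider(spec, kb, corpus)


def run_experiment(
    config: RunConfig,
    link: LinkConfig | None = None,
) -> tuple[EvalReport, RefinementReport]:
    """Execute the full pipeline described by ``config``.

    Writes candidates.jsonl, report.json, and manifest.json (plus
    decisions.jsonl when ``link`` is given) under ``config.output_dir``
    and returns the evaluation and refinement reports.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    kb = load_kb(config.kb_path, name=config.kb_name)
    corpus = read_corpus(config.corpus_path)
    retained, refinement = refine_test_set(corpus, kb)

    embedder = HashingNgramEmbedder(
        dim=config.embedder.dim,
        n_buckets=config.embedder.n_buckets,
        seed=config.embedder.seed,
    )
    retriever = GrfRetriever(
        embedder=embedder,
        strategy=config.fusion.strategy,
        alpha=config.fusion.alpha,
        synonym_aggregation=config.fusion.synonym_aggregation,
        k=config.k,
    ).fit(kb)

    feedbacks: dict[str, list[Feedback]] = {}
    if config.tasks:
        provider = _build_provider(config, kb, corpus)
        if provider is None:
            raise ConfigurationError("feedback tasks configured but provider is 'none'")
        cache = FeedbackCache(outdir / "feedback_cache.jsonl")
        tasks = [
            FeedbackTask(kind=t.kind, n=t.n, terminology=t.terminology or kb.name)
            for t in config.tasks
        ]
        for mention in retained:
            feedbacks[mention.mention_id] = [
                generate_feedback(provider, mention, task, cache=cache) for task in tasks
            ]

    rankings = retriever.rank(retained, feedbacks)
    write_rankings(rankings, outdir / "candidates.jsonl")

    gold = {m.mention_id: m.gold_cuis[0] for m in retained}
    report = recall_at_k(
        rankings, gold, cutoffs=tuple(config.cutoffs), config_fingerprint=config.fingerprint()
    )

    decisions = None
    if link is not None:
        by_id = {m.mention_id: m for m in retained}
        if link.method == "pick_top1":
            decisions = [pick_top1(rankings[mid], mid) for mid in sorted(rankings)]
        else:
            provider: CompletionProvider
            if link.method == "oracle_rerank":
                provider = OracleRerankProvider(gold)
            else:
                built = _build_provider(config, kb, corpus)
                if built is None:
                    raise ConfigurationError("llm_rerank requires a provider")
                provider = built
            decisions = [
                rerank_with_provider(by_id[mid], rankings[mid], link.k, provider, kb=kb)
                for mid in sorted(rankings)
            ]
        write_decisions(decisions, outdir / "decisions.jsonl")

    report_payload = {
        "refinement": {
            "n_input": refinement.n_input,
            "n_composite_removed": refinement.n_composite_removed,
            "n_oov_removed": refinement.n_oov_removed,
            "n_seen_removed": refinement.n_seen_removed,
            "n_retained": refinement.n_retained,
        },
        "recall_at": {str(k): report.recall_at[k] for k in sorted(report.recall_at)},
        "n_mentions": report.n_mentions,
        "config_fingerprint": report.config_fingerprint,
    }
    if decisions is not None:
        correct = sum(1 for d in decisions if d.chosen_cui == gold.get(d.mention_id))
        report_payload["linking_accuracy"] = correct / len(decisions) if decisions else 0.0
    (outdir / "report.json").write_text(
        json.dumps(report_payload, indent=2, sort_keys=True) + "\n"
    )

    manifest = {
        "package_version": __version__,
        "template_version": TEMPLATE_VERSION,
        "config": config.model_dump(),
        "config_fingerprint": config.fingerprint(),
        "link": link.model_dump() if link is not None else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report, refinement


def run_alpha_sweep(
    config: RunConfig, alphas: list[float], link: LinkConfig | None = None
) -> dict[float, EvalReport]:
    """Re-run the experiment across an alpha grid; each value writes its
    artifacts under ``<output_dir>/alpha_<value>`` with monotone naming."""
    base = Path(config.output_dir)
    reports: dict[float, EvalReport] = {}
    for alpha in alphas:
        sub = config.model_copy(deep=True)
        sub.fusion.alpha = alpha
        sub.output_dir = str(base / f"alpha_{alpha:0.2f}")
        reports[alpha], _ = run_experiment(sub, link=link)
    return reports
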