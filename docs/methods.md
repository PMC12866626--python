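# Methods

## Problem and model

Biomedical entity linking (BEL) maps a textual mention (e.g. "AO1") to a
concept unique identifier (CUI) in a curated knowledge base (e.g.
`MESH:C535396`). grflink implements the candidate-generation stage of
name-based BEL — retrieve a short, high-recall list of candidate concepts
per mention — together with generative relevance feedback (GRF), a
zero-shot query-expansion mechanism in which a text-generation model
produces mention-specific content that enriches the retrieval query.

### Alias index and homonym disambiguation

The index holds one entry per KB surface form. Aliases shared by two or
more concepts ("homonyms") would make the surface-form → CUI map
ill-defined, so each colliding alias is rewritten per owning concept as
`"<alias> (<owner's preferred name>)"`; residual collisions (e.g. two
owners with the same preferred name) append the CUI as a secondary
disambiguator. Collision detection is case-insensitive after Unicode NFC
normalization and whitespace collapsing; stored surface forms keep their
original bytes, and non-colliding aliases pass through unchanged. After
disambiguation, injectivity of the surface-form map and full concept
coverage are asserted property-style over generated KBs.

### Retrieval

Every index entry is embedded once; a mention is embedded with the same
encoder and the top-k entries by cosine similarity are retrieved
(vectors are L2-normalized at embedding time, so cosine is a dot
product). Retrieval operates over surface forms, evaluation over
concepts: hits are collapsed so each concept keeps only its
best-scoring surface form. Surface-form search depth exceeds the concept
cutoff (`max(4k, 64)`, or the whole index in `exact_scan` mode) so
collapsing never starves the cutoff. Search itself is an exhaustive
scan — exact by construction and fast at the index sizes targeted here;
ties are broken by (higher score, lower CUI, lower surface form) so
rankings are platform-stable.

### Feedback types

Each prompt carries the mention span, its containing sentence, and one
task instruction:

- **definition** — a context-aware one-sentence definition;
- **n_synonyms** — n exact synonyms / alternative phrasings
  (default grid n ∈ {1, 3, 5, 10});
- **standard_name** — the standard community-recognized name,
  conditioned on the target terminology label.

Prompt templates are editable text assets; the template version travels
with every feedback record. Providers implement a single
`complete(prompt) -> text` call; results are cached on disk keyed by
(mention text, sentence hash, task, provider, template version).

### Integration strategies

With mention query vector Q0 and feedback vector QF:

- **text**: embed the concatenation `mention ⧺ feedback` (separator is a
  single space by default);
- **vector** (Rocchio): `Q_grf = α·Q0 + (1−α)·QF`, α ∈ [0, 1]; for
  multi-synonym feedback the n synonym embeddings are averaged into one
  QF before interpolating;
- **rank** (weighted RRF): retrieve separately for mention and feedback
  and score each concept `α/rank_R0(c) + (1−α)/rank_RF(c)`, a term being
  omitted when c is absent from that list.

α = 1 reduces every strategy to the mention-only baseline; the default
α = 0.5 weights mention and feedback equally. *All-in-One* combines
several feedback types at once: vector fusion averages Q0 with all n
feedback vectors (the α = 1/(n+1) Rocchio case; for n = 1 it is bitwise
identical to α = 0.5), rank fusion sums plain reciprocal ranks over all
lists with equal weight.

Deliberate numerical choices, where the formulas alone underdetermine
behavior:

- RRF uses the reciprocal of the raw 1-based rank with **no additive
  smoothing constant** (the classic +60 offset is not applied).
- A candidate absent from one list contributes 0 from that list.
- Rank fusion operates on concept-collapsed lists (collapse happens in
  retrieval), each truncated at depth `max(4k, 64)` before fusing.
- Synonym feedback contributes a single candidate list by default
  (`mean_then_fuse`); `per_synonym_lists` issues one query per synonym.
- Fused vectors are re-normalized by default; cosine retrieval is
  scale-invariant, so this only standardizes stored vectors.
- Fused-ranking ties break by (score desc, CUI asc); the surface form
  kept for a fused candidate is the one from its best-ranked occurrence.

### Evaluation protocol

Official test splits overstate performance because many test mentions
repeat train mentions verbatim. The refined protocol filters the test
split in a fixed order — (1) composite mentions (more than one gold
CUI), (2) OOV mentions (gold CUI absent from the current KB release),
(3) mentions whose whitespace-collapsed, case-folded text occurs among
train/dev mentions (dev counts as seen) — and reports a tally per
filter. Scoring is recall@k over cutoffs {1, 2, 3, 5, 10}; recall@1 is
accuracy. Refinement is idempotent and the tallies are reproduced by an
independent brute-force recount in the tests.

### Linking and re-ranking

*Pick-top-1* takes the best retrieved concept. *LLM re-ranking* shows
the top-k candidates (k ∈ {2, 3, 5, 10} by default; surface form plus
preferred name when a KB is supplied) and asks the provider for the
index of the best match; unparseable or failed answers fall back to
pick-top-1, flagged. No abstention option is offered. Because a
re-ranker chooses among what it is shown, corpus accuracy is bounded by
recall@k of the input rankings (the bounded-recall law); the shipped
oracle re-rank provider attains that bound exactly and anchors the law
in tests.

## Embedding backend

The shipped encoder hashes character trigrams of the case-folded,
space-padded string into 4,096 buckets (BLAKE2b, stable across
processes), projects through a seeded ±1/√dim sign matrix to dim 64, and
L2-normalizes. It is deterministic, dependency-free, and correlated with
string overlap: small edits (swaps, truncations) move a vector slightly,
acronym formation moves it far — qualitatively the mismatch profile GRF
targets with learned encoders. Any sentence encoder can replace it
behind the `Embedder` protocol (`encode`, fixed `dim`, stable `id`);
dimensionality and normalization travel in the index manifest.

## Synthetic study conditions

The fixture generator is a pure function of (spec, seed). Defaults:
300 concepts with 2–5 aliases each (globally unique pseudo-terms),
homonym rate 0.05 (injected by adding a chosen fraction of names to a
second concept, so the realized fraction matches the spec up to
rounding), 150 mentions per split, composite 5%, OOV 5%,
train-overlap 15% — rates in the range real disease corpora exhibit.
Mentions are corrupted alias variants (adjacent-character swap 0.3,
case flip 0.2, suffix truncation 0.2, acronym from initials 0.3);
clean zero-shot test mentions are re-corrupted until lexically distinct
from all earlier mentions, so the zero-shot filter and the scripted
provider's gold mapping are unambiguous. The scripted provider emits
gold-grounded feedback with probability `feedback_quality` (drawn
deterministically per mention and task) and distractor-concept content
otherwise; quality 1 and 0 are exact by construction.

What the generator does **not** emulate: real lexical statistics
(abbreviation conventions, Greek letters, nested mentions), semantic —
rather than string — similarity structure between concepts, corpus
document structure, and LLM failure modes richer than the
quality/distractor dial. Passing tests therefore demonstrate the
correctness of the machinery (index, fusion arithmetic, protocol,
bounds) and the directional behavior of GRF under controlled feedback
quality, not absolute performance on real corpora.

## Problem sizes

Tests run on KBs of 40–80 concepts (plus one 5,000-concept rate check
and 1,000 small generated KBs for the injectivity sweep) and corpora of
40–120 mentions per split; the acceptance script uses 300 concepts and
200 mentions per split with feedback quality 1. These sizes keep every
retrieval exact (full scan) while leaving enough mentions for stable
corpus-level proportions.

## Known limitations

- Exhaustive search scales linearly in index size; multi-million-alias
  KBs need an ANN backend behind the same contract (it must match the
  exact scan on the documented exact-search configuration).
- The parenthetical disambiguator follows the printed convention only;
  alternative schemes (e.g. semantic-type tags) are not implemented.
- The zero-shot overlap check is exact lexical matching after
  normalization; near-duplicates (inflection, punctuation variants)
  count as unseen.
- Feedback quality is binary per draw in the scripted provider; graded
  degradation (partially correct names) is not modeled.
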