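import pytest

from grflink import (
    Concept,
    FixtureSpec,
    HashingNgramEmbedder,
    KnowledgeBase,
    generate_corpus,
    generate_kb,
)


@pytest.fixture(scope="session")
def embedder():
    return HashingNgramEmbedder(dim=64, seed=7)


@pytest.fixture
def conorenal_kb():
    """Hand-coded KB reproducing the canonical homonym example: one alias
    shared by two disease concepts, plus an unambiguous concept."""
    return KnowledgeBase(
        name="CTD Diseases",
        concepts=[
            Concept(
                cui="MESH:D012779",
                preferred_name="short rib-polydactyly syndrome",
                aliases=frozenset(
                    {"short rib-polydactyly syndrome", "conorenal syndrome"}
                ),
            ),
            Concept(
                cui="MESH:C535463",
                preferred_name="Mainzer-Saldino disease",
                aliases=frozenset({"Mainzer-Saldino disease", "conorenal syndrome"}),
            ),
            Concept(
                cui="MESH:C535396",
                preferred_name="atelosteogenesis, type 1",
                aliases=frozenset(
                    {
                        "atelosteogenesis, type 1",
                        "AO1",
                        "giant cell chondrodysplasia",
                        "spondylohumerofemoral hypoplasia",
                    }
                ),
            ),
        ],
    )


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(
        n_concepts=60,
        n_mentions=50,
        homonym_rate=0.05,
        composite_rate=0.05,
        oov_rate=0.05,
        seen_overlap_rate=0.15,
        feedback_quality=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_kb(small_spec):
    return generate_kb(small_spec)


@pytest.fixture(scope="session")
def small_corpus(small_spec, small_kb):
    return generate_corpus(small_spec, small_kb)
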