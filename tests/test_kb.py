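"""Knowledge-base loading, homonym detection, and alias disambiguation."""

import pytest

from grflink import (
    Concept,
    FixtureSpec,
    KnowledgeBase,
    KBFormatError,
    ValidationError,
    disambiguate_homonyms,
    find_homonyms,
    generate_kb,
    load_kb,
    save_kb,
)

KB_TSV = """cui\tname\tis_preferred
MESH:C535396\tatelosteogenesis, type 1\t1
MESH:C535396\tAO1\t0
MESH:C535396\tgiant cell chondrodysplasia\t0
MESH:C535396\tspondylohumerofemoral hypoplasia\t0
"""


class TestLoadKb:
    def test_groups_rows_by_cui(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text(KB_TSV)
        kb = load_kb(path)
        assert len(kb) == 1
        concept = kb.get("MESH:C535396")
        assert concept.preferred_name == "atelosteogenesis, type 1"
        assert len(concept.aliases) == 4
        assert "AO1" in concept.aliases

    def test_empty_file_gives_empty_kb(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text("cui\tname\tis_preferred\n")
        assert len(load_kb(path)) == 0

    def test_two_preferred_names_is_invalid(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text(
            "cui\tname\tis_preferred\nX:1\talpha\t1\nX:1\tbeta\t1\n"
        )
        with pytest.raises(ValidationError, match="preferred"):
            load_kb(path)

    def test_zero_preferred_names_is_invalid(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text("cui\tname\tis_preferred\nX:1\talpha\t0\n")
        with pytest.raises(ValidationError):
            load_kb(path)

    @pytest.mark.parametrize(
        "row, msg",
        [
            ("X:1\talpha", "3 columns"),
            ("X:1\talpha\t2", "is_preferred"),
            ("\talpha\t1", "empty cui"),
        ],
    )
    def test_malformed_row_reports_line_number(self, tmp_path, row, msg):
        path = tmp_path / "kb.tsv"
        path.write_text(f"cui\tname\tis_preferred\n{row}\n")
        with pytest.raises(KBFormatError, match="line 2"):
            load_kb(path)

    def test_round_trip(self, tmp_path, conorenal_kb):
        path = tmp_path / "kb.tsv"
        save_kb(conorenal_kb, path)
        reloaded = load_kb(path, name=conorenal_kb.name)
        assert reloaded.cuis == conorenal_kb.cuis
        for cui in conorenal_kb.cuis:
            assert reloaded.get(cui).aliases == conorenal_kb.get(cui).aliases
            assert reloaded.get(cui).preferred_name == conorenal_kb.get(cui).preferred_name


class TestFindHomonyms:
    def test_shared_alias_reported_with_both_owners(self, conorenal_kb):
        homonyms = find_homonyms(conorenal_kb)
        assert homonyms == {
            "conorenal syndrome": {"MESH:D012779", "MESH:C535463"}
        }

    def test_all_unique_aliases_gives_empty_mapping(self):
        kb = KnowledgeBase(
            concepts=[
                Concept(cui="A:1", preferred_name="alpha", aliases=frozenset({"alpha"})),
                Concept(cui="B:2", preferred_name="beta", aliases=frozenset({"beta"})),
            ]
        )
        assert find_homonyms(kb) == {}

    def test_case_insensitive_collision(self):
        # Enumerating alias pairs under the normalization rule: "ABC"/"abc"
        # normalize identically, so they form one homonym group.
        kb = KnowledgeBase(
            concepts=[
                Concept(cui="A:1", preferred_name="ABC", aliases=frozenset({"ABC"})),
                Concept(cui="B:2", preferred_name="abc", aliases=frozenset({"abc"})),
            ]
        )
        assert find_homonyms(kb) == {"abc": {"A:1", "B:2"}}


class TestDisambiguate:
    def test_reproduces_parenthetical_variants(self, conorenal_kb):
        entries = disambiguate_homonyms(conorenal_kb)
        surfaces = {e.surface_form for e in entries}
        assert "conorenal syndrome (short rib-polydactyly syndrome)" in surfaces
        assert "conorenal syndrome (Mainzer-Saldino disease)" in surfaces
        assert "conorenal syndrome" not in surfaces

    def test_no_homonyms_is_identity(self, conorenal_kb):
        kb = KnowledgeBase(
            concepts=[
                Concept(cui="A:1", preferred_name="alpha", aliases=frozenset({"alpha", "a"})),
            ]
        )
        entries = disambiguate_homonyms(kb)
        assert {e.surface_form for e in entries} == {"alpha", "a"}
        assert not any(e.was_homonym for e in entries)

    def test_homonym_that_is_a_preferred_name(self):
        # The shared form is itself one owner's preferred name, giving the
        # "<name> (<name>)" pattern; still well-formed and unique.
        kb = KnowledgeBase(
            concepts=[
                Concept(cui="A:1", preferred_name="gamma", aliases=frozenset({"gamma"})),
                Concept(cui="B:2", preferred_name="delta", aliases=frozenset({"delta", "gamma"})),
            ]
        )
        surfaces = {e.surface_form: e.cui for e in disambiguate_homonyms(kb)}
        assert surfaces["gamma (gamma)"] == "A:1"
        assert surfaces["gamma (delta)"] == "B:2"
        assert len(surfaces) == 3

    def test_secondary_collision_appends_cui(self):
        # Both owners of the homonym share a preferred name, so the
        # first-level variants collide and the cui disambiguates.
        kb = KnowledgeBase(
            concepts=[
                Concept(cui="A:1", preferred_name="same", aliases=frozenset({"same", "dup"})),
                Concept(cui="B:2", preferred_name="same", aliases=frozenset({"same", "dup"})),
            ]
        )
        with pytest.warns(UserWarning, match="secondary collision"):
            entries = disambiguate_homonyms(kb)
        surfaces = [e.surface_form for e in entries]
        assert len(surfaces) == len(set(surfaces))
        assert any("A:1" in s for s in surfaces) and any("B:2" in s for s in surfaces)

    @pytest.mark.parametrize("seed", range(25))
    def test_injectivity_and_coverage_on_generated_kbs(self, seed):
        """On generated KBs with up to 30% homonyms the disambiguated map
        is a function, covers every concept, and leaves non-homonymous
        aliases byte-identical."""
        spec = FixtureSpec(
            n_concepts=40, homonym_rate=0.3, n_mentions=0, seed=seed,
            composite_rate=0, oov_rate=0, seen_overlap_rate=0,
        )
        kb = generate_kb(spec)
        entries = disambiguate_homonyms(kb)
        surfaces = [e.surface_form for e in entries]
        assert len(surfaces) == len(set(surfaces)), "surface->cui must be a function"
        assert {e.cui for e in entries} == kb.cuis, "disambiguation must cover every concept"
        for e in entries:
            if not e.was_homonym:
                assert e.surface_form == e.original_form
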