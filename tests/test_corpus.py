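from types import SimpleNamespace

import pytest

import phenorag as pr
from phenorag.errors import ParseError, ValidationError


@pytest.fixture()
def height_term():
    return pr.HpoTerm(term_id="HP:0000001", label="Abnormality of body height")


class TestBuildPrompt:
    def test_missing_fields_render_none(self, height_term):
        prompt = pr.build_prompt(height_term)
        assert "HPO label: Abnormality of body height" in prompt
        assert "Definition: None" in prompt
        assert "Comments: None" in prompt
        assert "Synonyms: None" in prompt
        assert "<" not in prompt  # no residual placeholders

    def test_sentence_budget_substituted(self, height_term):
        prompt = pr.build_prompt(height_term, pr.PromptSpec(n_sentences_requested=40))
        assert prompt.startswith("Generate 40 unique sentences")

    def test_synonyms_joined_with_semicolons(self):
        term = pr.HpoTerm(
            term_id="HP:0000001",
            label="Abnormality of body height",
            synonyms=("Tall stature", "Short stature"),
        )
        assert "Synonyms: Tall stature; Short stature" in pr.build_prompt(term)

    def test_empty_label_rejected(self):
        stub = SimpleNamespace(
            term_id="HP:0000001", label="  ", definition=None, comments=None,
            synonyms=(),
        )
        with pytest.raises(ValidationError):
            pr.build_prompt(stub)


class TestParseBulletedResponse:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("- s1\n- s2\n\n- s3", ["s1", "s2", "s3"]),
            ("• s1\n1. s2", ["s1", "s2"]),
            ("* s1\n2) s2\n   - s3  ", ["s1", "s2", "s3"]),
        ],
    )
    def test_markers_stripped_in_order(self, raw, expected):
        assert pr.parse_bulleted_response(raw) == expected

    def test_empty_completion_raises_with_raw(self):
        with pytest.raises(ParseError):
            pr.parse_bulleted_response("")
        with pytest.raises(ParseError):
            pr.parse_bulleted_response("\n\n  \n")


@pytest.fixture(scope="module")
def terms():
    return pr.filter_terms(pr.make_toy_ontology(3, seed=2))


class TestGenerateCorpus:
    def test_count_and_determinism(self, terms):
        a = pr.generate_corpus(terms, n_per_term=40, seed=7)
        b = pr.generate_corpus(terms, n_per_term=40, seed=7)
        assert len(a) == 120
        assert [s.text for s in a] == [s.text for s in b]
        c = pr.generate_corpus(terms, n_per_term=40, seed=8)
        assert [s.text for s in a] != [s.text for s in c]

    def test_every_sentence_contains_a_surface_form(self, terms):
        by_id = {t.term_id: t for t in terms}
        for s in pr.generate_corpus(terms, n_per_term=40, seed=7):
            names = by_id[s.term_id].names
            assert any(name in s.text for name in names), s.text

    def test_unique_within_term(self, terms):
        corpus = pr.generate_corpus(terms, n_per_term=60, seed=7)
        for term in terms:
            texts = [s.text for s in corpus if s.term_id == term.term_id]
            assert len(set(texts)) == len(texts) == 60

    def test_per_term_streams_independent_of_iteration_order(self, terms):
        fwd = pr.generate_corpus(terms, n_per_term=10, seed=7)
        rev = pr.generate_corpus(list(reversed(terms)), n_per_term=10, seed=7)
        fwd_map = {(s.term_id, s.index): s.text for s in fwd}
        rev_map = {(s.term_id, s.index): s.text for s in rev}
        assert fwd_map == rev_map

    def test_external_backend_parsed_via_bullets(self, terms):
        client = lambda prompt: "- Alpha finding noted.\n- Beta finding noted."
        corpus = pr.generate_corpus(terms[:1], n_per_term=5, seed=0, backend=client)
        assert [s.text for s in corpus] == [
            "Alpha finding noted.", "Beta finding noted."
        ]

    def test_external_backend_failure_names_term(self, terms):
        def broken(prompt):
            raise RuntimeError("socket closed")

        with pytest.raises(ParseError, match=terms[0].term_id):
            pr.generate_corpus(terms[:1], n_per_term=5, seed=0, backend=broken)


def _sentences(term_id: str, n: int) -> list[pr.SyntheticSentence]:
    return [
        pr.SyntheticSentence(term_id=term_id, text=f"s{i}", index=i)
        for i in range(n)
    ]


class TestSplitCorpus:
    def test_full_budget_split(self):
        out, summary = pr.split_corpus(_sentences("HP:0000001", 40))
        splits = [s.split for s in sorted(out, key=lambda s: s.index)]
        assert splits == ["kb"] * 32 + ["test"] * 2 + ["unused"] * 6
        assert summary.per_term["HP:0000001"] == {"kb": 32, "test": 2, "unused": 6}
        assert not summary.untestable_terms

    def test_shortfall_protects_test_side(self):
        out, _ = pr.split_corpus(_sentences("HP:0000001", 20))
        splits = [s.split for s in sorted(out, key=lambda s: s.index)]
        assert splits == ["kb"] * 18 + ["test"] * 2

    def test_tiny_terms_flagged_untestable(self):
        out, summary = pr.split_corpus(_sentences("HP:0000001", 2))
        assert all(s.split == "kb" for s in out)
        assert summary.untestable_terms == ["HP:0000001"]

    def test_duplicate_keys_rejected(self):
        dup = _sentences("HP:0000001", 3) + _sentences("HP:0000001", 1)
        with pytest.raises(ValidationError):
            pr.split_corpus(dup)

    def test_marking_is_pure(self):
        original = _sentences("HP:0000001", 40)
        out, _ = pr.split_corpus(original)
        assert [s.text for s in out] == [s.text for s in original]
        assert all(s.split == "unused" for s in original)

    def test_kb_and_test_disjoint_per_term(self):
        corpus = _sentences("HP:0000001", 40) + _sentences("HP:0000002", 20)
        out, _ = pr.split_corpus(corpus)
        keys: dict[str, set] = {}
        for s in out:
            keys.setdefault(s.split, set()).add((s.term_id, s.index))
        assert not (keys.get("kb", set()) & keys.get("test", set()))


class TestCorpusJsonl:
    def test_round_trip(self, tmp_path):
        corpus, _ = pr.split_corpus(_sentences("HP:0000001", 40))
        path = tmp_path / "corpus.jsonl"
        pr.save_corpus(corpus, path)
        assert pr.load_corpus(path) == corpus

    def test_bad_record_raises(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"term_id": "HP:0000001"}\n')
        with pytest.raises(ParseError):
            pr.load_corpus(path)
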