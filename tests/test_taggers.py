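import pytest

import phenorag as pr
from phenorag.errors import ConfigurationError, FormatError, ValidationError


@pytest.fixture(scope="module")
def height_kb():
    """Engineered KB: one term described by 'discrepancy in height', one by
    'short stature' phrasing — mirrors a stature-vs-height retrieval case."""
    spec = pr.BackendSpec(dim=128)
    sentences = [
        ("HP:0000002", "Abnormality of body height",
         "Marked discrepancy in height noted relative to age-matched peers."),
        ("HP:0000002", "Abnormality of body height",
         "Growth charts show a persistent discrepancy in height."),
        ("HP:0000002", "Abnormality of body height",
         "Documented discrepancy in height at consecutive visits."),
        ("HP:0000098", "Tall stature",
         "Patient exhibits tall stature compared with siblings."),
        ("HP:0000098", "Tall stature",
         "Tall stature appreciated on physical examination."),
    ]
    vectors = pr.embed([s[2] for s in sentences], spec)
    return pr.build_kb(vectors, sentences, spec), spec


class TestEmPredict:
    def test_retrieves_height_discrepancy_term(self, height_kb):
        kb, spec = height_kb
        query = ("Clinically significant discrepancy in height observed "
                 "between patient and their peers.")
        pred = pr.em_predict(query, kb, spec, k=1)
        assert pred.labels == ("HP:0000002",)
        assert pred.source == "em"

    def test_emits_min_k_kb_size_labels(self, height_kb):
        kb, spec = height_kb
        pred = pr.em_predict("tall stature", kb, spec, k=50)
        assert len(pred.labels) == len(kb)

    def test_backend_mismatch_is_configuration_error(self, height_kb):
        kb, _ = height_kb
        with pytest.raises(ConfigurationError):
            pr.em_predict("text", kb, pr.BackendSpec(dim=64), k=1)

    def test_deterministic(self, height_kb):
        kb, spec = height_kb
        a = pr.em_predict("growth concern", kb, spec, k=3)
        b = pr.em_predict("growth concern", kb, spec, k=3)
        assert a.labels == b.labels


@pytest.fixture(scope="module")
def ontology():
    return pr.Ontology(
        terms={
            "HP:0000098": pr.HpoTerm(term_id="HP:0000098", label="Tall stature"),
            "HP:0000002": pr.HpoTerm(
                term_id="HP:0000002",
                label="Abnormality of body height",
                synonyms=("Height anomaly",),
            ),
        }
    )


class TestLexicalPredict:
    def test_exact_label_match_case_insensitive(self, ontology):
        pred = pr.lexical_predict("Noted TALL STATURE on exam.", ontology, k=1)
        assert pred.labels == ("HP:0000098",)

    def test_no_match_yields_empty_prediction(self, ontology):
        pred = pr.lexical_predict("Unremarkable cardiac exam.", ontology, k=5)
        assert pred.labels == ()

    def test_longest_match_ranked_first(self, ontology):
        text = "Tall stature with abnormality of body height documented."
        pred = pr.lexical_predict(text, ontology, k=1)
        assert pred.labels == ("HP:0000002",)  # 26-char label beats 12-char
        both = pr.lexical_predict(text, ontology, k=5)
        assert both.labels == ("HP:0000002", "HP:0000098")

    def test_synonym_matches(self, ontology):
        pred = pr.lexical_predict("Possible height anomaly flagged.", ontology, k=1)
        assert pred.labels == ("HP:0000002",)

    def test_whole_phrase_only(self, ontology):
        # "tall statures" should not match "Tall stature" (word boundary)
        pred = pr.lexical_predict("family of tall statures", ontology, k=1)
        assert pred.labels == ()


class TestPubTator:
    def test_read_two_records(self, tmp_path):
        path = tmp_path / "docs.pubtator"
        path.write_text(
            "001|t|Patient idx: 001\n001|a|notes: discrepancy in height.\n"
            "\n"
            "002|t|Patient idx: 002\n002|a|notes: tall stature.\n"
        )
        records = pr.read_pubtator(path)
        assert [r.doc_id for r in records] == ["001", "002"]
        assert records[0].abstract == "notes: discrepancy in height."

    def test_round_trip(self, tmp_path):
        records = [
            pr.PubTatorRecord(doc_id="a1", title="Title one", abstract="Abstract one"),
            pr.PubTatorRecord(doc_id="b2", title="Title two", abstract=""),
        ]
        path = tmp_path / "rt.pubtator"
        pr.write_pubtator(records, path)
        assert pr.read_pubtator(path) == records

    def test_single_pipe_line_is_format_error(self, tmp_path):
        path = tmp_path / "bad.pubtator"
        path.write_text("001|t only one pipe\n")
        with pytest.raises(FormatError, match="1"):
            pr.read_pubtator(path)

    def test_abstract_without_title_is_format_error(self, tmp_path):
        path = tmp_path / "orphan.pubtator"
        path.write_text("001|a|orphan abstract\n")
        with pytest.raises(FormatError, match="orphan.pubtator:1"):
            pr.read_pubtator(path)


class TestExternalTaggerAdapter:
    RECORDS = [
        pr.PubTatorRecord(doc_id="001", title="t", abstract="a"),
        pr.PubTatorRecord(doc_id="002", title="t", abstract="a"),
    ]

    def test_mock_passthrough(self):
        mock = lambda records: {"001": ["HP:0000001"], "002": ["HP:0000002"]}
        preds = pr.external_tagger_adapter(self.RECORDS, k=1, tagger=mock)
        assert [p.labels for p in preds] == [("HP:0000001",), ("HP:0000002",)]
        assert all(p.source == "pt" for p in preds)

    def test_truncated_to_k(self):
        mock = lambda records: {"001": [f"HP:{i:07d}" for i in range(1, 8)]}
        preds = pr.external_tagger_adapter(self.RECORDS, k=5, tagger=mock)
        assert len(preds[0].labels) == 5

    def test_missing_documents_yield_empty_sets(self):
        preds = pr.external_tagger_adapter(self.RECORDS, k=5, tagger=lambda r: {})
        assert all(p.labels == () for p in preds)

    def test_non_hp_label_is_format_error(self):
        mock = lambda records: {"001": ["MONDO:0000001"]}
        with pytest.raises(FormatError):
            pr.external_tagger_adapter(self.RECORDS, k=1, tagger=mock)

    def test_missing_executable_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            pr.external_tagger_adapter(
                self.RECORDS, k=1, tagger="no-such-binary-xyz {input}"
            )

    def test_template_without_placeholder_rejected(self):
        with pytest.raises(ConfigurationError):
            pr.external_tagger_adapter(self.RECORDS, k=1, tagger="cat file")


class TestPredictionSetInvariants:
    def test_labels_bounded_by_k(self):
        with pytest.raises(ValidationError):
            pr.PredictionSet(source="em", sentence_key="s", k=1,
                             labels=("HP:0000001", "HP:0000002"))

    def test_duplicates_permitted(self):
        p = pr.PredictionSet(source="pt", sentence_key="s", k=5,
                             labels=("HP:0000001",) * 4)
        assert p.labels.count("HP:0000001") == 4
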