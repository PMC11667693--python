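from pathlib import Path

import pytest

import phenorag as pr

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_obo_path() -> Path:
    return DATA_DIR / "toy.obo"


@pytest.fixture(scope="session")
def toy_ontology(toy_obo_path) -> pr.Ontology:
    return pr.parse_ontology(toy_obo_path)


@pytest.fixture(scope="session")
def generated_study():
    """A 3-term generated study: ontology, split corpus, and knowledge base."""
    ontology = pr.make_toy_ontology(3, seed=11)
    terms = pr.filter_terms(ontology)
    corpus, summary = pr.split_corpus(
        pr.generate_corpus(terms, n_per_term=40, seed=5)
    )
    spec = pr.BackendSpec()
    kb_sentences = [s for s in corpus if s.split == "kb"]
    kb = pr.build_kb(
        pr.embed([s.text for s in kb_sentences], spec),
        [(s.term_id, ontology[s.term_id].label, s.text) for s in kb_sentences],
        spec,
    )
    return {
        "ontology": ontology,
        "corpus": corpus,
        "summary": summary,
        "kb": kb,
        "spec": spec,
        "test_sentences": [s for s in corpus if s.split == "test"],
    }
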