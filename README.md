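# phenorag

Retrieval-augmented extraction of Human Phenotype Ontology (HPO) terms from
clinical free text.

Clinical genetics workflows depend on structured phenotypes: every
observation in a patient note ("marked discrepancy in height", "tall
stature") should map to an HPO concept (`HP:0000002`, `HP:0000098`, …) so
that gene–phenotype associations can prioritize genomic variants.
Dictionary- and NLP-based taggers do this with limited recall, because
clinicians rarely write the ontology's exact phrasing. `phenorag` implements
an alternative: instead of matching the text against the ontology, it
matches the text against a **knowledge base of synthetic clinical sentences**,
each generated for a single HPO term and stored with that term as metadata.

## Method

1. **Corpus generation.** For each ontology term (id, label, definition,
   comments, synonyms) a fixed prompt template requests 40 unique clinical
   sentences from an LLM. The package ships both the prompt/response
   machinery for an external LLM client and a deterministic built-in
   generator for fully offline, reproducible runs.
2. **Knowledge base.** Per term, the first 32 sentences are embedded and
   inserted into a vector store together with their source term; the next 2
   are held out as a test set. The reference store is an exact dense matrix
   scan with bit-stable persistence.
3. **Embedding model (EM).** A query sentence *q* is embedded and the top-*k*
   stored sentences by cosine similarity
   cos(u, v) = u·v / (‖u‖‖v‖)
   are retrieved; their term ids, duplicates included, are the ranked
   prediction. There is no trained classifier — the database lookup *is* the
   prediction, which also rules out hallucinated term ids.
4. **Fused model (FM).** Predictions from an external tagger (PT, e.g. a
   PhenoTagger-style tool behind the bundled PubTator-format adapter) and
   from EM are pooled, and the label with the highest combined vote count
   wins. At k = 1 the rule degenerates to precedence: agreement wins,
   disagreement defers to PT, an empty side falls through to the other.
5. **Evaluation.** Each held-out sentence has one gold term. Top-1 scoring:
   correct → TP; wrong → FP *and* FN; abstention → FN (so TP + FN = number
   of sentences). Top-k scoring: gold anywhere in the list → TP, and every
   non-gold occurrence counts toward FP. Sensitivity = TP/(TP+FN),
   PPV = TP/(TP+FP), F1 = 2·TP/(2·TP+FP+FN).

The default embedding backend is a hashed character 3-gram bag (FNV-1a,
dim 256, L2-normalized) — deterministic and dependency-free. Pretrained
sentence encoders can be plugged in via `register_backend`.

## Worked example

```python
import phenorag as pr

ontology = pr.make_toy_ontology(5, seed=3)
terms = pr.filter_terms(ontology)
corpus, summary = pr.split_corpus(pr.generate_corpus(terms, n_per_term=40, seed=4))
spec = pr.BackendSpec()          # hash-ngram, dim=256, l2
kb_sentences = [s for s in corpus if s.split == "kb"]
kb = pr.build_kb(
    pr.embed([s.text for s in kb_sentences], spec),
    [(s.term_id, ontology[s.term_id].label, s.text) for s in kb_sentences],
    spec,
)
print(f"knowledge base: {len(kb)} entries for {len(terms)} terms")

test = [s for s in corpus if s.split == "test"]
query = test[0]
print("query:", query.text)
print("gold: ", query.term_id, "=", ontology[query.term_id].label)
print("top-5:", ", ".join(pr.em_predict(query.text, kb, spec, k=5).labels))

report, _ = pr.evaluate_pipeline(test, kb, spec, None, mode="em", k=1)
print(f"EM top-1  sensitivity={report.sensitivity:.2f}  ppv={report.ppv:.2f}  f1={report.f1:.2f}")
```

prints

```
knowledge base: 160 entries for 5 terms
query: Discharge summary lists Distal aortic pallor as an active problem. (obs 33)
gold:  HP:0000001 = Distal aortic pallor
top-5: HP:0000001, HP:0000001, HP:0000001, HP:0000001, HP:0000001
EM top-1  sensitivity=1.00  ppv=1.00  f1=1.00
```

All five nearest neighbours come from the gold term's 32 knowledge-base
sentences, so the top-1 prediction is correct and, on this deliberately
separable toy corpus, every held-out sentence is recovered (F1 = 1.0). See
`docs/methods.md` for what that does and does not demonstrate.

The same pipeline is available from the shell:

```bash
phenorag generate --ontology hp.obo --out corpus.jsonl --seed 1
phenorag build-kb --corpus corpus.jsonl --ontology hp.obo --out kb/
phenorag tag --kb kb/ --input notes.txt --k 5
phenorag evaluate --corpus corpus.jsonl --kb kb/ --mode em --k 1
```

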