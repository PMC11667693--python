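# Methods

## Model

`phenorag` treats HPO term assignment as nearest-neighbour retrieval. A
knowledge base holds one embedding vector per synthetic sentence, each tagged
with the HPO term the sentence was generated for. A query sentence is
embedded with the same backend and the term ids of its top-k neighbours by
cosine similarity are returned as a ranked multiset. The modelling
assumptions are:

* each sentence expresses exactly one phenotype concept (the corpus is
  generated that way, and evaluation assigns one gold term per sentence);
* semantic proximity in the embedding space tracks phenotype identity well
  enough that a sentence lies closer to other sentences of its own term than
  to sentences of any other term;
* no negation, family-history, or span-level reasoning — the unit of
  prediction is the whole sentence.

The fused model combines the retrieval prediction with an external
dictionary/ML tagger by pooled majority vote. At k = 1 a vote is degenerate,
so the rule is precedence: agreement wins, disagreement defers to the
external tagger, and an empty side falls through to the other (a
no-prediction is returned only when both sides abstain — this keeps
false-negative accounting meaningful while maximizing answer coverage). At
k ≥ 2, ties in the pooled count are broken by best rank in the external
tagger's list, then best rank in the retrieval list, then ascending term id:
a total order that generalizes the k = 1 precedence rule and makes fusion
deterministic.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_per_term` | 40 | sentences requested/generated per ontology term |
| `kb_per_term` | 32 | sentences per term embedded into the knowledge base |
| `test_per_term` | 2 | sentences per term held out for evaluation |
| `k` | 1 (also 5) | neighbours retrieved / labels fused per sentence |
| `embedding.dim` | 256 | hash buckets of the reference backend |
| `eval.topk_fp` | `multiset` | FP counting at top-k (see below) |

The 40/32/2 budget is the study design this package reproduces; the
remaining 6 sentences per term are generated but unused, mirroring a
pipeline in which the sentence source may under-deliver. When a term has
fewer than 34 sentences the test side is protected: the last 2 sentences are
held out and the knowledge-base share shrinks. Terms with ≤ 2 sentences
contribute only knowledge-base entries and are flagged untestable in the
split summary.

## The reference embedding backend

Pretrained sentence encoders enter only through the backend registry; the
shipped backend is a hashed character 3-gram bag: NFC-normalize, lowercase,
pad with `^`/`$`, hash every 3-gram with 64-bit FNV-1a into `dim` buckets,
L2-normalize the counts. It is pure (no randomized hashing, no state), so
knowledge bases and query results are bit-reproducible across processes and
platforms. dim = 256 keeps collisions rare on toy vocabularies while
making the exact scan essentially free.

## The synthetic-data generator

The built-in generator emulates the role of an LLM asked for clinical
sentences: 44 clinical framing templates (presentation, imaging, history,
assessment, …) instantiated with the term's label or a synonym, chosen by a
seeded RNG keyed on `(seed, term_id, index)` so per-term output is
independent of term iteration order; an index stamp (`(obs n)`) guarantees
uniqueness within a term. Every generated sentence therefore contains one of
the term's surface forms verbatim.

The companion toy ontology builds terms from an adjective–anatomy–finding
vocabulary in which the anatomy–finding core pair is unique per term while
adjectives and framing vocabulary are shared. That makes the corpus
*separable by construction*: a character n-gram embedding must recover the
source term of every held-out sentence, and the retrieval-recovery tests
assert exactly that (F1 = 1.0 at 3–50 terms).

What this does **not** show: real clinical text paraphrases, misspells, and
negates; real LLM corpora do not guarantee that the label appears verbatim,
and pretrained encoders have very different geometry from n-gram bags.
Passing tests establish that the pipeline's mechanics — splitting,
embedding, exact retrieval, fusion, scoring — are correct, not that any
particular corpus-level accuracy transfers to real notes.

## Numerical and design choices

* **Exact retrieval.** The store is a dense float64 matrix scan; similarity
  ties are broken by ascending insertion index. Persistence writes raw
  little-endian float64, so `load(save(kb))` answers every query identically
  (similarities to < 1e-12, same tie order). Approximate stores may be
  plugged in but must pass the same brute-force oracle at small scale.
* **Cosine clamping.** Similarities are clamped to [-1, 1] to absorb
  floating-point drift; zero-norm vectors are rejected rather than patched.
* **Top-1 scoring double-counts errors** (a wrong prediction is both an FP
  and an FN): with single-label predictions each mistaken sentence both
  asserts a wrong term and misses its true one, and it is the rule under
  which TP + FN always equals the number of scored sentences.
* **Top-k FP counting** defaults to multiset occurrences (duplicate wrong
  labels each count, including alongside a TP); a `distinct` policy counts
  each unique wrong label once. The choice is configurable because ranked
  retrieval lists legitimately repeat terms and either convention is
  defensible.
* **Metric boundary cases.** PPV is defined as 0 when nothing was predicted;
  F1 as 0 when TP = 0; metrics are refused outright when no gold-bearing
  records exist. Metrics are reported at full precision; comparisons against
  two-decimal reference values round half-up.
* **Empty inputs.** Empty texts are rejected at the embedding boundary (with
  the offending index), empty ontologies at parse time, and empty knowledge
  bases at construction time, so downstream code never sees degenerate
  geometry.
* **Obsolete terms** are parsed and retained but excluded from corpus
  generation and knowledge-base construction by default; all synonym scopes
  (EXACT/BROAD/NARROW/RELATED) are accepted as surface forms.

## Problem sizes

The shipped study sizes — 3–50 toy terms, 40 sentences per term, dim-256
vectors, knowledge bases up to 1,600 entries (tests exercise random stores
up to 1,000 entries) — were chosen so that the exact scan, not an index, is
the natural store and every check runs in seconds while still exercising
every code path at the per-term budget of the full-scale design (the
split-arithmetic check instantiates the full 18,696-term accounting
symbolically, without embedding).

## Known limitations

* Whole-sentence classification only: no mention spans, no multi-concept
  sentences, no negation or family-history handling.
* The external tagger is wrapped, not reimplemented; its internal ranking is
  taken as given, and fusion assumes exactly two models.
* Ontology graph structure is ignored — no partial credit for ancestor
  matches, no information-content weighting.
* The built-in generator's separability guarantee is a fixture property;
  corpus-level scores on generated data are upper bounds, not estimates, of
  real-world performance.
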