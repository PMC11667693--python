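"""Synthetic clinical-sentence corpus: prompt building, generation, splitting.

The knowledge base is populated not with curated annotations but with
machine-generated sentences that each use one HPO term in a clinical context.
This module provides:

* the prompt template used to request sentences from an external LLM, and a
  parser for its bulleted completions;
* a built-in, fully deterministic sentence generator that emulates the LLM
  output for offline use (every sentence contains its term's label or a
  synonym verbatim — a separability guarantee the retrieval tests rely on);
* the knowledge-base/test split: per term, the first ``kb_per_term`` (default
  32) sentences seed the knowledge base and the next ``test_per_term``
  (default 2) form the held-out test set.

Corpora are persisted as JSON Lines, one record per sentence with keys
``term_id``, ``index``, ``text``, ``split``.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

from .errors import ParseError, ValidationError
from .ontology import HpoTerm

Split = Literal["kb", "test", "unused"]

#: Prompt sent to an external LLM for one term. ``<N>`` is the sentence
#: budget; the four term placeholders render "None" when the field is absent
#: so the prompt structure is fixed across terms.
PROMPT_TEMPLATE = (
    "Generate <N> unique sentences that describe the provided HPO label as "
    "they would appear in a clinical narrative or interpretive report. Each "
    "sentence should offer a different perspective or detail, similar to how "
    "various clinicians might report observations or diagnoses in clinical "
    "notes. Avoid using the exact phrase in every sentence to ensure "
    "diversity and reflect the range of clinical expression. Sometimes, I "
    "will provide comments, synonyms, and definitions that can help provide "
    "more context for your thoughts. Return a bulleted list instead of "
    "numbered. Feel free to use clinical shorthand that a physician might "
    "use in writing reports.\n"
    "HPO label: <Label>\n"
    "Definition: <Definition>\n"
    "Comments: <Comments>\n"
    "Synonyms: <Synonyms>"
)


@dataclass(frozen=True)
class PromptSpec:
    """Template plus requested sentence count (default 40 per term)."""

    template_text: str = PROMPT_TEMPLATE
    n_sentences_requested: int = 40

    def __post_init__(self) -> None:
        if self.n_sentences_requested < 1:
            raise ValidationError("n_sentences_requested must be positive")


@dataclass(frozen=True)
class SyntheticSentence:
    """One generated sentence bound to its source term.

    ``index`` is the 0-based generation order within the term; ``split`` is
    assigned by :func:`split_corpus` and defaults to ``"unused"``.
    """

    term_id: str
    text: str
    index: int
    split: Split = "unused"

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValidationError(
                f"empty sentence text for {self.term_id}[{self.index}]"
            )
        if self.index < 0:
            raise ValidationError("sentence index must be >= 0")


@dataclass(frozen=True)
class SplitConfig:
    """Knowledge-base / test sentence budget per term (defaults 32 / 2)."""

    kb_per_term: int = 32
    test_per_term: int = 2

    def __post_init__(self) -> None:
        if self.kb_per_term < 1 or self.test_per_term < 1:
            raise ValidationError("split sizes must be positive")


def build_prompt(term: HpoTerm, spec: PromptSpec | None = None) -> str:
    """Render the generation prompt for one term.

    Missing definition/comments render as the literal "None"; synonyms are
    joined with "; ". The result contains no residual angle-bracket
    placeholders.
    """
    spec = spec or PromptSpec()
    if not term.label.strip():
        raise ValidationError(f"term {term.term_id} has no label")
    text = (
        spec.template_text
        .replace("<N>", str(spec.n_sentences_requested))
        .replace("<Label>", term.label)
        .replace("<Definition>", term.definition or "None")
        .replace("<Comments>", term.comments or "None")
        .replace("<Synonyms>", "; ".join(term.synonyms) or "None")
    )
    leftover = re.findall(r"<[A-Za-z]+>", text)
    if leftover:
        raise ValidationError(f"unfilled placeholders in prompt: {leftover}")
    return text


_BULLET_RE = re.compile(r"^\s*(?:[-*•]\s*|\d+[.)]\s+)?(?P<body>.*?)\s*$")


def parse_bulleted_response(raw: str) -> list[str]:
    """Extract sentences from a bulleted LLM completion, in order.

    Bullet markers (``-``, ``*``, ``•``) are stripped; numbered-list lines
    ("1.", "2)") are accepted as a fallback; blank lines are skipped.

    Raises :class:`ParseError` (carrying the raw text) if nothing is
    recovered.
    """
    sentences: list[str] = []
    for line in raw.splitlines():
        body = _BULLET_RE.match(line).group("body")
        if body:
            sentences.append(body)
    if not sentences:
        raise ParseError("no sentences recovered from completion", raw=raw)
    return sentences


# 44 clinical framing templates; {phrase} is the term label or a synonym,
# inserted verbatim. The index stamp appended by the generator guarantees
# uniqueness within a term even when a template/phrase pair repeats.
SENTENCE_TEMPLATES: tuple[str, ...] = (
    "Patient presents with {phrase}.",
    "Exam notable for {phrase} at follow-up.",
    "Findings are consistent with {phrase}.",
    "Imaging demonstrates {phrase} without interval change.",
    "History significant for {phrase} since early childhood.",
    "Assessment: {phrase}, stable on current management.",
    "The patient reports symptoms attributable to {phrase}.",
    "Clinical impression remains {phrase}.",
    "Review of systems positive for {phrase}.",
    "Physical examination reveals {phrase} on the right.",
    "Workup was initiated for suspected {phrase}.",
    "Documented {phrase} noted in prior records.",
    "No family history, but {phrase} observed on exam.",
    "Referred for evaluation of {phrase}.",
    "Progressive course of {phrase} over the past year.",
    "Mother reports {phrase} first noticed in infancy.",
    "Specialist consultation confirmed {phrase}.",
    "Laboratory results support a diagnosis of {phrase}.",
    "Differential includes {phrase} among other considerations.",
    "Serial measurements confirm {phrase}.",
    "Mild {phrase} appreciated on today's visit.",
    "Longstanding {phrase} managed conservatively.",
    "Patient denies pain but exhibits {phrase}.",
    "Follow-up recommended given persistent {phrase}.",
    "Genetic testing pursued in the context of {phrase}.",
    "Chart review documents {phrase} at multiple encounters.",
    "New finding of {phrase} compared with baseline.",
    "Clinician notes {phrase} during routine screening.",
    "Consult requested to address {phrase}.",
    "Symptoms consistent with {phrase} reported by caregiver.",
    "Initial presentation included {phrase}.",
    "Radiology impression: {phrase}.",
    "Discharge summary lists {phrase} as an active problem.",
    "Phenotype remarkable for {phrase}.",
    "Growth charts corroborate {phrase}.",
    "Pediatric exam identified {phrase} at age two.",
    "Persistent {phrase} despite therapy.",
    "Clinically significant {phrase} observed between visits.",
    "Bedside evaluation suggests {phrase}.",
    "Records from the outside hospital mention {phrase}.",
    "Treatment plan adjusted on account of {phrase}.",
    "Screening flagged possible {phrase}; confirmed on re-exam.",
    "Interval development of {phrase} since the last visit.",
    "Problem list updated to include {phrase}.",
)

#: An external sentence source: prompt text in, raw completion text out.
LlmClient = Callable[[str], str]


def _builtin_sentences(
    term: HpoTerm, n_per_term: int, seed: int
) -> list[str]:
    if not term.label.strip():
        raise ValidationError(f"term {term.term_id} has no label")
    sentences = []
    for i in range(n_per_term):
        # Per-sentence stream keyed on (seed, term_id, index): output is
        # independent of term iteration order and of n_per_term prefixes.
        rng = random.Random(f"{seed}:{term.term_id}:{i}")
        phrase = rng.choice(term.names)
        template = SENTENCE_TEMPLATES[i % len(SENTENCE_TEMPLATES)]
        sentences.append(template.format(phrase=phrase) + f" (obs {i + 1})")
    return sentences


def generate_corpus(
    terms: Sequence[HpoTerm],
    n_per_term: int = 40,
    seed: int = 0,
    backend: LlmClient | None = None,
    prompt_spec: PromptSpec | None = None,
) -> list[SyntheticSentence]:
    """Generate ``n_per_term`` sentences per term.

    With no ``backend`` the built-in deterministic generator is used: exactly
    ``n_per_term`` unique sentences per term, each containing the term's
    label or a synonym verbatim, fully determined by ``(term_id, index,
    seed)``. With an external LLM client, the prompt is sent and whatever
    :func:`parse_bulleted_response` recovers is kept (possibly fewer than
    requested).
    """
    if n_per_term < 1:
        raise ValidationError("n_per_term must be >= 1")
    out: list[SyntheticSentence] = []
    for term in terms:
        if backend is None:
            texts = _builtin_sentences(term, n_per_term, seed)
        else:
            prompt = build_prompt(
                term,
                prompt_spec
                or PromptSpec(n_sentences_requested=n_per_term),
            )
            try:
                raw = backend(prompt)
            except Exception as exc:
                raise ParseError(
                    f"external backend failed for {term.term_id}: {exc}"
                ) from exc
            texts = parse_bulleted_response(raw)[:n_per_term]
        out.extend(
            SyntheticSentence(term_id=term.term_id, text=t, index=i)
            for i, t in enumerate(texts)
        )
    return out


@dataclass
class SplitSummary:
    """Per-term accounting of the knowledge-base/test split."""

    per_term: dict[str, dict[str, int]] = field(default_factory=dict)
    untestable_terms: list[str] = field(default_factory=list)

    @property
    def n_kb(self) -> int:
        return sum(c["kb"] for c in self.per_term.values())

    @property
    def n_test(self) -> int:
        return sum(c["test"] for c in self.per_term.values())


def split_corpus(
    sentences: Sequence[SyntheticSentence],
    cfg: SplitConfig | None = None,
) -> tuple[list[SyntheticSentence], SplitSummary]:
    """Assign each sentence to the knowledge base, test set, or neither.

    Per term with ``n`` available sentences (ordered by index):

    * ``n >= kb+test`` — first ``kb_per_term`` marked ``kb``, next
      ``test_per_term`` marked ``test``, remainder ``unused``;
    * ``test < n < kb+test`` — the last ``test_per_term`` marked ``test``,
      the rest ``kb`` (the test side is protected, the KB side shrinks);
    * ``n <= test_per_term`` — all marked ``kb`` and the term is flagged
      untestable in the summary.

    Marking is pure: sentence texts and order are unchanged.
    """
    cfg = cfg or SplitConfig()
    seen: set[tuple[str, int]] = set()
    by_term: dict[str, list[SyntheticSentence]] = {}
    for s in sentences:
        key = (s.term_id, s.index)
        if key in seen:
            raise ValidationError(f"duplicate sentence key {key}")
        seen.add(key)
        by_term.setdefault(s.term_id, []).append(s)

    assignment: dict[tuple[str, int], Split] = {}
    summary = SplitSummary()
    for term_id, group in by_term.items():
        group = sorted(group, key=lambda s: s.index)
        n = len(group)
        if n >= cfg.kb_per_term + cfg.test_per_term:
            splits = (
                ["kb"] * cfg.kb_per_term
                + ["test"] * cfg.test_per_term
                + ["unused"] * (n - cfg.kb_per_term - cfg.test_per_term)
            )
        elif n > cfg.test_per_term:
            splits = ["kb"] * (n - cfg.test_per_term) + ["test"] * cfg.test_per_term
        else:
            splits = ["kb"] * n
            summary.untestable_terms.append(term_id)
        counts = {"kb": 0, "test": 0, "unused": 0}
        for s, sp in zip(group, splits):
            assignment[(s.term_id, s.index)] = sp  # type: ignore[assignment]
            counts[sp] += 1
        summary.per_term[term_id] = counts

    return (
        [replace(s, split=assignment[(s.term_id, s.index)]) for s in sentences],
        summary,
    )


def save_corpus(sentences: Iterable[SyntheticSentence], path: str | Path) -> None:
    """Write a corpus as JSON Lines (term_id, index, text, split)."""
    with open(path, "w") as fh:
        for s in sentences:
            fh.write(
                json.dumps(
                    {
                        "term_id": s.term_id,
                        "index": s.index,
                        "text": s.text,
                        "split": s.split,
                    }
                )
                + "\n"
            )


def load_corpus(path: str | Path) -> list[SyntheticSentence]:
    """Read a corpus written by :func:`save_corpus`."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                out.append(
                    SyntheticSentence(
                        term_id=rec["term_id"],
                        index=rec["index"],
                        text=rec["text"],
                        split=rec.get("split", "unused"),
                    )
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ParseError(
                    f"bad corpus record at {path}:{lineno}: {exc}", raw=line
                ) from exc
    return out
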