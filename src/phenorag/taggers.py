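"""Ranked HPO predictions per sentence, from three sources.

* ``em_predict`` — the embedding-retrieval model (EM): embed the sentence,
  take the term ids of the top-k nearest knowledge-base sentences. Always
  emits exactly ``min(k, kb size)`` labels, duplicates included.
* ``lexical_predict`` — a dictionary tagger over ontology labels/synonyms,
  used as the offline stand-in for an external hybrid tagger. Like real
  taggers it may emit *no* prediction for a sentence.
* ``external_tagger_adapter`` — bridges a PhenoTagger-style external tool
  (callable or shell command) through the PubTator exchange format; the real
  tool is wrapped, never reimplemented.
"""

from __future__ import annotations

import re
import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

from .embeddings import BackendSpec, embed
from .errors import ConfigurationError, FormatError, ValidationError
from .knowledge_base import KnowledgeBase
from .ontology import HP_ID_PATTERN, Ontology

Source = Literal["em", "pt", "lexical", "fused"]


@dataclass(frozen=True)
class PredictionSet:
    """Ordered multiset of term-id predictions from one model for one input.

    ``labels`` holds 0..k HP identifiers, best first; duplicates are allowed
    (nearest-neighbour lists legitimately repeat a term).
    """

    source: Source
    sentence_key: str
    k: int
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if len(self.labels) > self.k:
            raise ValidationError(
                f"{len(self.labels)} labels exceed k={self.k}"
            )
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class PubTatorRecord:
    """One document in PubTator pipe format: ``id|t|title`` + ``id|a|abstract``."""

    doc_id: str
    title: str
    abstract: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("PubTator doc_id must be non-empty")

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


def em_predict(
    sentence: str,
    kb: KnowledgeBase,
    backend_spec: BackendSpec,
    k: int,
    sentence_key: str = "",
) -> PredictionSet:
    """Retrieval prediction: term ids of the top-k KB neighbours, in rank order."""
    if backend_spec != kb.backend_spec:
        raise ConfigurationError(
            f"backend {backend_spec} does not match the knowledge base's "
            f"{kb.backend_spec}"
        )
    vector = embed([sentence], backend_spec)[0]
    hits = kb.query(vector, k)
    return PredictionSet(
        source="em",
        sentence_key=sentence_key or sentence[:40],
        k=k,
        labels=tuple(h.term_id for h in hits),
    )


def lexical_predict(
    sentence: str,
    ontology: Ontology,
    k: int,
    sentence_key: str = "",
) -> PredictionSet:
    """Dictionary tagging: case-insensitive whole-phrase label/synonym search.

    Matches are ranked by matched phrase length descending, then ascending
    term id; at most ``k`` labels, possibly none.
    """
    matches: list[tuple[int, str]] = []  # (-len, term_id) sort keys
    lowered = sentence.lower()
    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        best = 0
        for name in term.names:
            phrase = name.lower()
            if re.search(rf"(?<!\w){re.escape(phrase)}(?!\w)", lowered):
                best = max(best, len(phrase))
        if best:
            matches.append((-best, term_id))
    matches.sort()
    return PredictionSet(
        source="lexical",
        sentence_key=sentence_key or sentence[:40],
        k=k,
        labels=tuple(tid for _, tid in matches[:k]),
    )


def read_pubtator(path: str | Path) -> list[PubTatorRecord]:
    """Parse pipe-delimited ``id|t|...`` / ``id|a|...`` documents.

    Documents are blank-line separated; annotation lines (tab-delimited)
    after the t/a pair are ignored. An abstract line without a preceding
    title line for the same id is a format error.
    """
    records: list[PubTatorRecord] = []
    pending: dict[str, str] = {}  # doc_id -> title, in file order
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" in line and "|" not in line.split("\t", 1)[0]:
                continue  # annotation row
            parts = line.split("|", 2)
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'id|t|text' or 'id|a|text', "
                    f"got {line!r}"
                )
            doc_id, kind, text = parts
            if kind == "t":
                pending[doc_id] = text
                order.append(doc_id)
            elif kind == "a":
                if doc_id not in pending:
                    raise FormatError(
                        f"{path}:{lineno}: abstract line for {doc_id!r} "
                        "without a preceding title line"
                    )
                records.append(
                    PubTatorRecord(
                        doc_id=doc_id,
                        title=pending.pop(doc_id),
                        abstract=text,
                    )
                )
            else:
                raise FormatError(
                    f"{path}:{lineno}: unknown field {kind!r} (expected t/a)"
                )
    # title-only documents (no abstract line)
    for doc_id in order:
        if doc_id in pending:
            records.append(
                PubTatorRecord(doc_id=doc_id, title=pending.pop(doc_id), abstract="")
            )
    return records


def write_pubtator(records: Sequence[PubTatorRecord], path: str | Path) -> None:
    """Emit records in the same pipe dialect; round-trips with the reader."""
    blocks = [
        f"{r.doc_id}|t|{r.title}\n{r.doc_id}|a|{r.abstract}\n" for r in records
    ]
    Path(path).write_text("\n".join(blocks))


#: External tagger contract: records in, per-doc ranked HP id lists out.
TaggerFn = Callable[[Sequence[PubTatorRecord]], dict[str, Sequence[str]]]


def external_tagger_adapter(
    records: Sequence[PubTatorRecord],
    k: int,
    tagger: TaggerFn | str,
    timeout: float | None = None,
) -> list[PredictionSet]:
    """Run an external PhenoTagger-style tagger and truncate to top-k.

    ``tagger`` is either a Python callable (records → {doc_id: ranked HP
    ids}) or a shell command template containing ``{input}``; the command
    receives a PubTator file and must print ``doc_id<TAB>HP:nnnnnnn`` lines
    in the tagger's own rank order. Predictions beyond ``k`` are dropped;
    documents the tagger skips yield empty prediction sets.
    """
    if callable(tagger):
        raw = {str(d): list(ids) for d, ids in tagger(records).items()}
    else:
        raw = _run_command_tagger(records, tagger, timeout)
    out = []
    for rec in records:
        labels = [str(l) for l in raw.get(rec.doc_id, [])][:k]
        for label in labels:
            if not HP_ID_PATTERN.match(label):
                raise FormatError(
                    f"tagger returned a non-HP label {label!r} "
                    f"for document {rec.doc_id}"
                )
        out.append(
            PredictionSet(
                source="pt", sentence_key=rec.doc_id, k=k, labels=tuple(labels)
            )
        )
    return out


def _run_command_tagger(
    records: Sequence[PubTatorRecord], command_template: str, timeout: float | None
) -> dict[str, list[str]]:
    import tempfile

    if "{input}" not in command_template:
        raise ConfigurationError(
            "tagger command template must contain an {input} placeholder"
        )
    with tempfile.TemporaryDirectory() as tmp:
        input_path = Path(tmp) / "input.pubtator"
        write_pubtator(records, input_path)
        cmd = [
            part.replace("{input}", str(input_path))
            for part in shlex.split(command_template)
        ]
        try:
            proc = subprocess.run(
                cmd, capture_output=True, text=True, timeout=timeout, check=True
            )
        except FileNotFoundError as exc:
            raise ConfigurationError(f"tagger executable not found: {exc}") from exc
        except subprocess.CalledProcessError as exc:
            raise FormatError(
                f"tagger exited with {exc.returncode}: {exc.stderr}"
            ) from exc
    raw: dict[str, list[str]] = {}
    for line in proc.stdout.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(
                f"unparsable tagger output line {line!r} "
                "(expected doc_id<TAB>HP:id)"
            )
        raw.setdefault(parts[0], []).append(parts[1])
    return raw
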