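"""Reading Human Phenotype Ontology (HPO) term records.

The unit of annotation throughout the package is the :class:`HpoTerm`: one
ontology concept carrying the five text fields the sentence-generation prompt
consumes (id, label, definition, comments, synonyms). Two on-disk dialects are
supported: OBO 1.4 flat files (parsed with :mod:`obonet`) and the
``graphs[0].nodes`` OBO-JSON layout of the official ``hp.json``.

Graph structure (is_a edges, ancestors, information content) is deliberately
out of scope: retrieval classification only needs the term records.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import obonet

from .errors import FormatError, InputError, ValidationError

HP_ID_PATTERN = re.compile(r"^HP:\d{7}$")

# OBO synonym line payload: "text" SCOPE [xrefs] — scope and trailer optional.
_SYNONYM_RE = re.compile(
    r'^"(?P<text>.*)"\s*(?:EXACT|BROAD|NARROW|RELATED)?\s*(?:\[.*\])?\s*$',
    re.DOTALL,
)
_QUOTED_RE = re.compile(r'^"(?P<text>.*)"\s*(?:\[.*\])?\s*$', re.DOTALL)


@dataclass(frozen=True)
class HpoTerm:
    """One HPO concept.

    Parameters
    ----------
    term_id:
        Identifier of the form ``HP:`` followed by exactly seven digits.
    label:
        The term name; non-empty after trimming.
    definition, comments:
        Optional free text (``None`` when absent in the source file).
    synonyms:
        Ordered, de-duplicated synonym texts; never contains the label itself.
        All OBO scopes (EXACT/BROAD/NARROW/RELATED) are accepted.
    is_obsolete:
        Obsolete terms are parsed and retained; downstream steps exclude them
        by default via :func:`filter_terms`.
    """

    term_id: str
    label: str
    definition: str | None = None
    comments: str | None = None
    synonyms: tuple[str, ...] = ()
    is_obsolete: bool = False

    def __post_init__(self) -> None:
        if not HP_ID_PATTERN.match(self.term_id):
            raise ValidationError(f"not an HP identifier: {self.term_id!r}")
        if not self.label or not self.label.strip():
            raise ValidationError(f"term {self.term_id} has an empty label")
        object.__setattr__(self, "label", self.label.strip())
        seen: dict[str, None] = {}
        for syn in self.synonyms:
            s = syn.strip()
            if s and s != self.label and s not in seen:
                seen[s] = None
        object.__setattr__(self, "synonyms", tuple(seen))

    @property
    def names(self) -> tuple[str, ...]:
        """Label followed by synonyms — every surface form of the concept."""
        return (self.label, *self.synonyms)


@dataclass
class Ontology:
    """A parsed set of HPO terms keyed by term id."""

    terms: dict[str, HpoTerm]
    source_path: str = ""
    source_format: Literal["obo", "obo_json", "memory"] = "memory"

    def __post_init__(self) -> None:
        for key, term in self.terms.items():
            if key != term.term_id:
                raise ValidationError(
                    f"ontology key {key!r} != term id {term.term_id!r}"
                )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> HpoTerm:
        return self.terms[term_id]


def _strip_quoted(raw: str, pattern: re.Pattern = _QUOTED_RE) -> str:
    m = pattern.match(raw.strip())
    return m.group("text") if m else raw.strip()


def _join(raw: str | list[str] | None) -> str | None:
    # Multiple def/comment lines are concatenated with a single space.
    if raw is None:
        return None
    parts = raw if isinstance(raw, list) else [raw]
    text = " ".join(_strip_quoted(p) for p in parts).strip()
    return text or None


def _parse_obo(path: Path) -> dict[str, HpoTerm]:
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # malformed stanza inside obonet
        raise FormatError(f"malformed OBO file {path}: {exc}") from exc
    terms: dict[str, HpoTerm] = {}
    for node_id, data in graph.nodes(data=True):
        if not HP_ID_PATTERN.match(str(node_id)):
            continue
        label = data.get("name")
        if not label:
            raise FormatError(f"term {node_id} in {path} has no name line")
        synonyms = [
            _strip_quoted(s, _SYNONYM_RE) for s in data.get("synonym", [])
        ]
        terms[node_id] = HpoTerm(
            term_id=node_id,
            label=label,
            definition=_join(data.get("def")),
            comments=_join(data.get("comment")),
            synonyms=tuple(synonyms),
            is_obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
        )
    return terms


def _iri_to_hp(node_id: str) -> str | None:
    # "http://purl.obolibrary.org/obo/HP_0000118" -> "HP:0000118"
    tail = node_id.rsplit("/", 1)[-1].replace("_", ":")
    return tail if HP_ID_PATTERN.match(tail) else None


def _parse_obo_json(path: Path) -> dict[str, HpoTerm]:
    try:
        doc = json.loads(path.read_text())
        nodes = doc["graphs"][0]["nodes"]
    except (json.JSONDecodeError, KeyError, IndexError, TypeError) as exc:
        raise FormatError(
            f"{path} is not a graphs[0].nodes OBO-JSON document: {exc}"
        ) from exc
    terms: dict[str, HpoTerm] = {}
    for node in nodes:
        term_id = _iri_to_hp(str(node.get("id", "")))
        if term_id is None:
            continue
        label = node.get("lbl")
        if not label:
            continue
        meta = node.get("meta", {}) or {}
        definition = (meta.get("definition") or {}).get("val")
        comments = " ".join(meta.get("comments", [])) or None
        synonyms = tuple(
            s["val"] for s in meta.get("synonyms", []) if s.get("val")
        )
        terms[term_id] = HpoTerm(
            term_id=term_id,
            label=label,
            definition=definition,
            comments=comments,
            synonyms=synonyms,
            is_obsolete=bool(meta.get("deprecated", False)),
        )
    return terms


def parse_ontology(
    path: str | Path, format: Literal["obo", "obo_json", "auto"] = "auto"
) -> Ontology:
    """Parse an HPO release file into an :class:`Ontology`.

    With ``format="auto"`` the dialect is chosen by extension (``.json`` →
    OBO-JSON) and, failing that, by sniffing the first non-blank character
    (``{`` → JSON).

    Raises
    ------
    InputError
        If the file does not exist or cannot be read.
    FormatError
        If no HP-prefixed terms are found or a record is malformed.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"ontology file not found: {path}")
    if format == "auto":
        if path.suffix.lower() == ".json":
            format = "obo_json"
        else:
            head = path.read_text(errors="replace").lstrip()[:1]
            format = "obo_json" if head == "{" else "obo"
    terms = _parse_obo(path) if format == "obo" else _parse_obo_json(path)
    if not terms:
        raise FormatError(f"no HP terms parsed from {path} (format={format})")
    return Ontology(terms=terms, source_path=str(path), source_format=format)


def filter_terms(
    ontology: Ontology, include_obsolete: bool = False
) -> list[HpoTerm]:
    """Terms in ascending term-id order, excluding obsoletes by default."""
    return [
        ontology.terms[tid]
        for tid in sorted(ontology.terms)
        if include_obsolete or not ontology.terms[tid].is_obsolete
    ]


def write_obo(terms: Iterable[HpoTerm], path: str | Path) -> None:
    """Write terms as a minimal OBO 1.4 file (fixture writer).

    Emits only the tags this package reads back (id, name, def, comment,
    synonym, is_obsolete); synonyms are written with EXACT scope. Round-trips
    through :func:`parse_ontology` losslessly for those fields.
    """
    lines = ["format-version: 1.4", ""]
    for term in sorted(terms, key=lambda t: t.term_id):
        lines.append("[Term]")
        lines.append(f"id: {term.term_id}")
        lines.append(f"name: {term.label}")
        if term.definition:
            lines.append(f'def: "{term.definition}" []')
        if term.comments:
            lines.append(f"comment: {term.comments}")
        for syn in term.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        if term.is_obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Deterministic toy ontology
# ---------------------------------------------------------------------------

_ADJECTIVES = [
    "proximal", "distal", "bilateral", "unilateral", "progressive",
    "congenital", "recurrent", "transient", "generalized", "focal",
    "severe", "episodic", "chronic", "asymmetric", "diffuse", "juvenile",
]
_ANATOMY = [
    "femoral", "cranial", "retinal", "hepatic", "renal", "cardiac",
    "vertebral", "digital", "palmar", "ocular", "aortic", "dental",
    "dermal", "neural", "pulmonary", "lingual",
]
_FINDINGS = [
    "overgrowth", "hypoplasia", "dysplasia", "stenosis", "atrophy",
    "sclerosis", "effusion", "calcification", "hypertrophy", "agenesis",
    "fibrosis", "edema", "erosion", "duplication", "exostosis", "pallor",
]


def make_toy_ontology(n_terms: int, seed: int = 0) -> Ontology:
    """Build a small synthetic ontology for demos and tests.

    Each term receives an adjective–anatomy–finding label (e.g. "Bilateral
    retinal atrophy"), one synonym sharing the anatomy and finding words, a
    definition, and a comment. Adjectives repeat across terms, but the
    anatomy–finding core phrase is unique per term: every surface form of a
    term contains a two-word phrase no other term uses, which is what makes
    the set lexically separable — the regime the retrieval classifier is
    designed for. Ids are ``HP:0000001`` upward; output is fully determined
    by ``(n_terms, seed)``.
    """
    import random

    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    max_terms = len(_ANATOMY) * len(_FINDINGS)
    if n_terms > max_terms:
        raise ValidationError(f"toy ontology supports at most {max_terms} terms")
    rng = random.Random(f"toy-ontology:{seed}")
    triples: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(triples) < n_terms:
        core = (rng.choice(_ANATOMY), rng.choice(_FINDINGS))
        if core not in seen:
            seen.add(core)
            triples.append((rng.choice(_ADJECTIVES), *core))
    terms: dict[str, HpoTerm] = {}
    for i, (adj, anat, finding) in enumerate(triples, start=1):
        term_id = f"HP:{i:07d}"
        label = f"{adj.capitalize()} {anat} {finding}"
        synonym = f"{anat.capitalize()} {finding}, {adj} type"
        terms[term_id] = HpoTerm(
            term_id=term_id,
            label=label,
            definition=f"A {adj} form of {finding} affecting the {anat} region.",
            comments=f"Typically documented as {anat} {finding} on imaging.",
            synonyms=(synonym,),
        )
    return Ontology(terms=terms, source_format="memory")


def normalize_text(text: str) -> str:
    """NFC-normalize; shared by the embedding and tagging layers."""
    return unicodedata.normalize("NFC", text)
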