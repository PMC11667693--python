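"""Vector knowledge base: exact top-k cosine retrieval with HPO metadata.

Each entry pairs one sentence vector with the HPO material it came from
(term id, label, sentence text), so a nearest-neighbour lookup doubles as a
term assignment: the metadata of the closest stored sentences *is* the
prediction. The reference store is an exact in-memory matrix scan — the
method's results do not depend on approximate-nearest-neighbour shortcuts,
and at desk scale a dense scan is both faster and bit-reproducible.
Approximate/persistent stores can be plugged in but must reproduce the exact
semantics at small scale.

Ties in similarity are broken by ascending insertion index, which makes
query results order-reproducible. Persistence uses a human-inspectable
layout: ``manifest.json`` (backend, dim, count), ``metadata.jsonl`` (one
entry per line, insertion order), and ``vectors.f64le`` (raw little-endian
float64 matrix) — queries round-trip bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import BackendSpec
from .errors import FormatError, ValidationError

_MANIFEST = "manifest.json"
_METADATA = "metadata.jsonl"
_VECTORS = "vectors.f64le"


@dataclass(frozen=True)
class KbEntry:
    """Metadata stored alongside one vector."""

    term_id: str
    label: str
    sentence_text: str
    insert_index: int


@dataclass(frozen=True)
class RetrievalHit:
    """One query result; ``rank`` is 1-based, best first.

    Repeated term ids across hits are expected and are *not* collapsed —
    vote counting downstream relies on the raw multiset.
    """

    term_id: str
    similarity: float
    rank: int
    kb_insert_index: int


class KnowledgeBase:
    """Dense matrix of sentence vectors plus per-row metadata."""

    def __init__(
        self,
        matrix: np.ndarray,
        entries: Sequence[KbEntry],
        backend_spec: BackendSpec,
    ):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != len(entries):
            raise ValidationError(
                f"matrix shape {matrix.shape} inconsistent with "
                f"{len(entries)} entries"
            )
        if matrix.shape[1] != backend_spec.dim:
            raise ValidationError(
                f"matrix dim {matrix.shape[1]} != backend dim {backend_spec.dim}"
            )
        self.matrix = matrix
        self.entries = list(entries)
        self.backend_spec = backend_spec
        self._norms = np.linalg.norm(matrix, axis=1)
        if np.any(self._norms == 0):
            raise ValidationError("knowledge base contains a zero vector")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def query(self, vector: np.ndarray, k: int) -> list[RetrievalHit]:
        """Exact top-k by cosine similarity; ties by ascending insert index."""
        vector = np.asarray(vector, dtype=np.float64).ravel()
        if vector.shape[0] != self.dim:
            raise ValidationError(
                f"query dim {vector.shape[0]} != kb dim {self.dim}"
            )
        if k < 1:
            raise ValidationError("k must be >= 1")
        qnorm = np.linalg.norm(vector)
        if qnorm == 0:
            raise ValidationError("cannot query with a zero vector")
        sims = np.clip((self.matrix @ vector) / (self._norms * qnorm), -1.0, 1.0)
        # lexsort: primary key similarity descending, secondary insert index
        # ascending (np.lexsort sorts by the last key first; equal -sims fall
        # back to the positional key, which is already ascending and stable).
        order = np.lexsort((np.arange(len(sims)), -sims))[: min(k, len(sims))]
        return [
            RetrievalHit(
                term_id=self.entries[idx].term_id,
                similarity=float(sims[idx]),
                rank=rank,
                kb_insert_index=int(idx),
            )
            for rank, idx in enumerate(order, start=1)
        ]

    def save(self, path: str | Path) -> None:
        """Persist to a directory (manifest + metadata JSONL + raw matrix)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "backend": self.backend_spec.name,
            "dim": self.backend_spec.dim,
            "normalization": self.backend_spec.normalization,
            "count": len(self),
        }
        (path / _MANIFEST).write_text(json.dumps(manifest, indent=2) + "\n")
        with open(path / _METADATA, "w") as fh:
            for e in self.entries:
                fh.write(
                    json.dumps(
                        {
                            "term_id": e.term_id,
                            "label": e.label,
                            "sentence_text": e.sentence_text,
                            "insert_index": e.insert_index,
                        }
                    )
                    + "\n"
                )
        # IEEE-754 float64, fixed little-endian byte order: exact round-trip.
        self.matrix.astype("<f8").tofile(path / _VECTORS)

    @classmethod
    def load(cls, path: str | Path) -> "KnowledgeBase":
        path = Path(path)
        manifest_path = path / _MANIFEST
        if not manifest_path.is_file():
            raise FormatError(f"missing manifest: {manifest_path}")
        try:
            manifest = json.loads(manifest_path.read_text())
            backend = BackendSpec(
                name=manifest["backend"],
                dim=manifest["dim"],
                normalization=manifest.get("normalization", "l2"),
            )
            count = int(manifest["count"])
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"corrupt manifest {manifest_path}: {exc}") from exc
        entries = []
        with open(path / _METADATA) as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    entries.append(
                        KbEntry(
                            term_id=rec["term_id"],
                            label=rec["label"],
                            sentence_text=rec["sentence_text"],
                            insert_index=rec["insert_index"],
                        )
                    )
        raw = np.fromfile(path / _VECTORS, dtype="<f8")
        if raw.size != count * backend.dim or len(entries) != count:
            raise FormatError(
                f"{path / _VECTORS}: expected {count}x{backend.dim} doubles "
                f"and {count} metadata lines, found {raw.size} doubles and "
                f"{len(entries)} lines"
            )
        return cls(raw.reshape(count, backend.dim), entries, backend)


def build_kb(
    vectors: np.ndarray,
    metadata: Sequence[tuple[str, str, str]],
    backend_spec: BackendSpec,
) -> KnowledgeBase:
    """Assemble a knowledge base from vectors and (term_id, label, text) rows.

    Insertion order is preserved as ``insert_index``; all vectors must share
    ``backend_spec.dim``.
    """
    try:
        vectors = np.asarray(vectors, dtype=np.float64)
    except ValueError as exc:  # ragged input: rows of different dimension
        raise ValidationError(f"vectors have mixed dimensions: {exc}") from exc
    if vectors.size == 0 or len(metadata) == 0:
        raise ValidationError("cannot build an empty knowledge base")
    if vectors.ndim != 2:
        raise ValidationError("vectors must be a 2-D (n, dim) array")
    entries = [
        KbEntry(term_id=t, label=l, sentence_text=s, insert_index=i)
        for i, (t, l, s) in enumerate(metadata)
    ]
    return KnowledgeBase(vectors, entries, backend_spec)


def query(kb: KnowledgeBase, vector: np.ndarray, k: int) -> list[RetrievalHit]:
    """Module-level alias for :meth:`KnowledgeBase.query`."""
    return kb.query(vector, k)


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    kb.save(path)


def load_kb(path: str | Path) -> KnowledgeBase:
    return KnowledgeBase.load(path)
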