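"""Sentence embedding backends and cosine similarity.

The retrieval classifier is agnostic to the encoder: any function mapping a
batch of texts to a fixed-dimension real matrix can serve as a backend.
Pretrained transformer encoders plug in through :func:`register_backend`; the
test suite and the offline pipeline use the built-in ``hash-ngram`` backend —
a hashed character 3-gram bag with L2 normalization. It is pure and
process-restart stable (FNV-1a hashing, no randomization), so knowledge
bases built from it are bit-reproducible.

Vectors are plain ``numpy`` float64 arrays; a batch is an ``(n, dim)``
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .ontology import normalize_text

#: Default dimensionality of the reference backend — large enough that toy
#: corpora rarely collide, small enough for fast exact scans.
DEFAULT_DIM = 256

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = 0xFFFFFFFFFFFFFFFF


@dataclass(frozen=True)
class BackendSpec:
    """Identifies an embedding backend and its output geometry.

    ``normalization="l2"`` (the default) means every emitted vector has unit
    Euclidean norm, so cosine similarity reduces to a dot product.
    """

    name: str = "hash-ngram"
    dim: int = DEFAULT_DIM
    normalization: Literal["l2", "none"] = "l2"

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValidationError("embedding dim must be >= 2")


#: A backend implementation: list of texts -> (n, dim) float64 matrix.
BackendFn = Callable[[Sequence[str], "BackendSpec"], np.ndarray]

_REGISTRY: dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    """Register an encoder (e.g. a sentence-transformer adapter) by name."""
    _REGISTRY[name] = fn


def fnv1a_64(data: bytes) -> int:
    """FNV-1a 64-bit hash — the stable bucket hash of the reference backend."""
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK64
    return h


def hash_ngram_vector(text: str, dim: int = DEFAULT_DIM) -> np.ndarray:
    """Embed one text as an L2-normalized hashed character 3-gram bag.

    The text is NFC-normalized and lowercased, padded as ``"^" + text +
    "$"``, and every character 3-gram increments bucket ``fnv1a_64(gram) %
    dim``; the count vector is then L2-normalized. Deterministic across
    processes and platforms.
    """
    if dim < 2:
        raise ValidationError("dim must be >= 2")
    cleaned = normalize_text(text).lower().strip()
    if len(cleaned) < 1:
        raise ValidationError("cannot embed an empty text")
    padded = f"^{cleaned}$"
    counts = np.zeros(dim, dtype=np.float64)
    for i in range(len(padded) - 2):
        gram = padded[i : i + 3]
        counts[fnv1a_64(gram.encode("utf-8")) % dim] += 1.0
    return counts / np.linalg.norm(counts)


def _hash_ngram_backend(texts: Sequence[str], spec: BackendSpec) -> np.ndarray:
    return np.stack([hash_ngram_vector(t, spec.dim) for t in texts])


_REGISTRY["hash-ngram"] = _hash_ngram_backend


def embed(texts: Sequence[str], spec: BackendSpec | None = None) -> np.ndarray:
    """Embed a batch of texts with the backend named in ``spec``.

    Returns an ``(n, dim)`` float64 matrix, one row per input in order.
    Deterministic: identical text yields an identical vector for a fixed
    spec. With ``normalization="l2"`` every row has unit norm.
    """
    spec = spec or BackendSpec()
    if len(texts) == 0:
        raise ValidationError("embed requires at least one text")
    for i, t in enumerate(texts):
        if not t or not t.strip():
            raise ValidationError(f"empty text at index {i}")
    fn = _REGISTRY.get(spec.name)
    if fn is None:
        raise ConfigurationError(
            f"unknown embedding backend {spec.name!r}; "
            f"registered: {sorted(_REGISTRY)}"
        )
    matrix = np.asarray(fn(texts, spec), dtype=np.float64)
    if matrix.shape != (len(texts), spec.dim):
        raise ConfigurationError(
            f"backend {spec.name!r} returned shape {matrix.shape}, "
            f"expected {(len(texts), spec.dim)}"
        )
    if not np.isfinite(matrix).all():
        raise ValidationError("backend produced non-finite values")
    if spec.normalization == "l2":
        norms = np.linalg.norm(matrix, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValidationError("backend produced a zero vector")
        matrix = matrix / norms
    return matrix


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (‖u‖‖v‖), clamped to [-1, 1] against rounding."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValidationError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("cosine similarity undefined for zero vectors")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
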