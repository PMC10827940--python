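"""Sentence embeddings behind a uniform, backend-agnostic contract.

The matching model only needs a deterministic map text → R^d.  The default
backend is a feature-hashed lexical embedder: each token n-gram of a
sentence is hashed to a signed coordinate, the bag is mean-pooled over the
sentence's grams and ℓ2-normalised.  It is fully offline, bit-reproducible,
and places sentences with more shared content words at higher cosine
similarity — sufficient structure for the comparator to learn from.  A
pretrained transformer sentence encoder can be plugged in through the
"external" backend without touching the rest of the pipeline.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus_io import CaptionSet, Corpus, normalize_text

__all__ = [
    "EncoderSpec",
    "HashingSentenceEncoder",
    "register_backend",
    "embed",
    "EmbeddingCache",
    "precompute_cache",
    "text_key",
]

_TOKEN = re.compile(r"[a-z0-9]+")

#: fixed function-word list dropped before hashing; corpus-independent, so
#: the embedding stays a pure function of the text.  Content words (nouns,
#: adjectives) carry all the matching signal; glue words only blur it.
_STOPWORDS = frozenset({
    "a", "an", "the", "this", "that", "these", "those", "it", "its",
    "is", "are", "was", "were", "be", "been", "has", "have", "had",
    "with", "and", "or", "of", "in", "on", "at", "to", "for", "by",
    "you", "can", "see", "they", "we", "he", "she", "his", "her",
})


@dataclass(frozen=True)
class EncoderSpec:
    """Identifies a backend so cached vectors are never mixed across
    incompatible encoders."""

    backend_id: str = "hash"
    dim: int = 256
    pooling: str = "mean"
    version: str = "1"


def text_key(text: str) -> str:
    """Cache key: digest of the NFC/whitespace-normalised text, so caption
    and corpus pipelines share entries for identical sentences."""
    return hashlib.sha1(normalize_text(text).encode("utf-8")).hexdigest()


def _grams(text: str) -> list[str]:
    toks = [t for t in _TOKEN.findall(normalize_text(text).lower())
            if t not in _STOPWORDS]
    return toks + [f"{a}_{b}" for a, b in zip(toks, toks[1:])]


def _hash_embed(texts: Sequence[str], spec: EncoderSpec) -> np.ndarray:
    out = np.zeros((len(texts), spec.dim), dtype=np.float64)
    for row, text in enumerate(texts):
        grams = _grams(text)
        if not grams:
            continue
        for g in grams:
            d = hashlib.md5(g.encode("utf-8")).digest()
            idx = int.from_bytes(d[:8], "little") % spec.dim
            sign = 1.0 if d[8] & 1 else -1.0
            out[row, idx] += sign
        out[row] /= len(grams)
        norm = np.linalg.norm(out[row])
        if norm > 0:
            out[row] /= norm
    return out


_BACKENDS: dict[str, Callable[[Sequence[str], EncoderSpec], np.ndarray]] = {
    "hash": _hash_embed,
}


def register_backend(backend_id: str,
                     fn: Callable[[Sequence[str], EncoderSpec], np.ndarray]) -> None:
    """Register an embedding backend, e.g. an adapter around a pretrained
    mean-pooled transformer sentence encoder under the id "external"."""
    _BACKENDS[backend_id] = fn


def embed(texts: Sequence[str], spec: EncoderSpec) -> np.ndarray:
    """Embed texts under the spec's backend; pure in (spec, text)."""
    if spec.backend_id not in _BACKENDS:
        raise ValueError(
            f"unknown backend {spec.backend_id!r}; registered: {sorted(_BACKENDS)}"
        )
    vecs = _BACKENDS[spec.backend_id](list(texts), spec)
    if vecs.shape != (len(texts), spec.dim):
        raise ValueError(
            f"backend {spec.backend_id!r} returned shape {vecs.shape}, "
            f"expected {(len(texts), spec.dim)}"
        )
    if not np.all(np.isfinite(vecs)):
        raise ValueError(f"backend {spec.backend_id!r} produced non-finite values")
    return vecs


class HashingSentenceEncoder(TransformerMixin, BaseEstimator):
    """sklearn-style transformer over the feature-hashing backend.

    Stateless: ``fit`` only records the spec; ``transform`` maps a list of
    strings to an (n, dim) array.
    """

    def __init__(self, dim: int = 256, version: str = "1"):
        self.dim = dim
        self.version = version

    def fit(self, X: Sequence[str], y=None):
        self.spec_ = EncoderSpec(backend_id="hash", dim=self.dim, version=self.version)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "spec_"):
            self.fit(X)
        return embed(X, self.spec_)


class EmbeddingCache:
    """Precomputed text → vector store keyed by normalised-text digest."""

    def __init__(self, spec: EncoderSpec, index: dict[str, int], matrix: np.ndarray):
        if matrix.ndim != 2 or matrix.shape[1] != spec.dim:
            raise ValueError(f"cache matrix dim {matrix.shape} incompatible with spec dim {spec.dim}")
        self.spec = spec
        self.index = index
        self.matrix = matrix

    @classmethod
    def build(cls, texts: Iterable[str], spec: EncoderSpec) -> "EmbeddingCache":
        unique: dict[str, str] = {}
        for t in texts:
            unique.setdefault(text_key(t), t)
        keys = list(unique)
        matrix = embed([unique[k] for k in keys], spec) if keys else np.zeros((0, spec.dim))
        return cls(spec, {k: i for i, k in enumerate(keys)}, matrix)

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, text: str) -> bool:
        return text_key(text) in self.index

    def vector(self, text: str) -> np.ndarray:
        key = text_key(text)
        if key not in self.index:
            raise KeyError(f"text not in embedding cache: {text[:60]!r}")
        return self.matrix[self.index[key]]

    def vectors(self, texts: Sequence[str]) -> np.ndarray:
        return self.matrix[[self.index[text_key(t)] for t in texts]]

    def save(self, path: str | Path) -> None:
        """Persist as <path>.npy (vectors) + <path>.json (spec + index)."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.matrix)
        meta = {"spec": asdict(self.spec), "index": self.index}
        path.with_suffix(".json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, spec: EncoderSpec | None = None) -> "EmbeddingCache":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        stored = EncoderSpec(**meta["spec"])
        if spec is not None and (spec.dim != stored.dim or spec.backend_id != stored.backend_id
                                 or spec.version != stored.version):
            raise ValueError(f"cache spec {stored} incompatible with requested {spec}")
        matrix = np.load(path.with_suffix(".npy"))
        return cls(stored, meta["index"], matrix)


def precompute_cache(source: Corpus | Sequence[CaptionSet], spec: EncoderSpec) -> EmbeddingCache:
    """Embed every sentence of a corpus, or every caption of caption sets."""
    texts: list[str] = []
    if isinstance(source, Corpus):
        for doc in source.documents:
            texts.extend(doc.sentences)
    else:
        for cs in source:
            texts.extend(c.text for c in cs.captions)
    return EmbeddingCache.build(texts, spec)
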