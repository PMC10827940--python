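"""Aggregating pair scores into document rankings and posteriors.

An image's score against a document is the mean comparator score over all
caption × sentence pairs.  Softmax over the corpus turns a score row into
a posterior over documents; the top-ranked document's class labels the
image.  The same posterior feeds the batch-level training regularizer
R(B) = Σ_x [ −⟨p_x,p_x⟩ + Σ_{x'≠x} ⟨p_x,p_{x'}⟩ ], which is smallest when
every image commits to its own distinct document.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .comparator import SentencePairClassifier
from .corpus_io import CaptionSet, Corpus, Document
from .encode import EmbeddingCache, EncoderSpec, precompute_cache

__all__ = [
    "ScoreMatrix",
    "ProbMatrix",
    "Ranking",
    "ranking_from_scores",
    "score_document",
    "score_corpus",
    "document_posteriors",
    "rank_documents",
    "regularizer",
    "DocumentRetriever",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-image, per-document mean pair scores z (images × documents)."""

    image_ids: tuple[str, ...]
    class_ids: tuple[str, ...]
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape != (len(self.image_ids), len(self.class_ids)):
            raise ValueError(f"score matrix shape {self.z.shape} inconsistent with axes")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("score matrix has non-finite entries")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("image_id\t" + "\t".join(self.class_ids) + "\n")
            for i, img in enumerate(self.image_ids):
                fh.write(img + "\t" + "\t".join(f"{v:.10g}" for v in self.z[i]) + "\n")


@dataclass(frozen=True)
class ProbMatrix:
    """Row-stochastic document posteriors p(D_j | x_i) on the same axes."""

    image_ids: tuple[str, ...]
    class_ids: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self) -> None:
        if self.p.shape != (len(self.image_ids), len(self.class_ids)):
            raise ValueError("probability matrix shape inconsistent with axes")
        if np.any(self.p < 0) or np.any(np.abs(self.p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("rows must be non-negative and sum to 1")

    def entropies(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(self.p > 0, self.p * np.log(self.p), 0.0)
        return -t.sum(axis=1)


class Ranking:
    """Per-image permutation of all class ids, best first.

    Ties in the underlying score are broken by ascending class id, so
    rankings are total and deterministic.
    """

    def __init__(self, image_ids: Sequence[str], class_ids: Sequence[str],
                 order: np.ndarray, scores: np.ndarray | None = None):
        self.image_ids = list(image_ids)
        self.class_ids = list(class_ids)
        self.order = np.asarray(order)          # (n_images, K) of class indices
        self.scores = scores
        self._img_row = {img: i for i, img in enumerate(self.image_ids)}
        self._cls_col = {c: j for j, c in enumerate(self.class_ids)}
        self._rank = np.empty_like(self.order)
        rows = np.arange(self.order.shape[0])[:, None]
        self._rank[rows, self.order] = np.arange(1, self.order.shape[1] + 1)

    def order_for(self, image_id: str) -> list[str]:
        return [self.class_ids[j] for j in self.order[self._img_row[image_id]]]

    def rank_of(self, image_id: str, class_id: str) -> int:
        """1-based rank of a class in this image's ranking."""
        if class_id not in self._cls_col:
            raise KeyError(f"class {class_id!r} not in ranking")
        return int(self._rank[self._img_row[image_id], self._cls_col[class_id]])

    def top(self, image_id: str, k: int = 1) -> list[str]:
        return self.order_for(image_id)[:k]

    def to_tsv(self, path: str | Path, method: str = "fgsm") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# method={method}\nimage_id\trank\tclass_id\tscore\n")
            for i, img in enumerate(self.image_ids):
                for r, j in enumerate(self.order[i], start=1):
                    s = self.scores[i, j] if self.scores is not None else float("nan")
                    fh.write(f"{img}\t{r}\t{self.class_ids[j]}\t{s:.10g}\n")


def ranking_from_scores(image_ids: Sequence[str], class_ids: Sequence[str],
                        z: np.ndarray) -> Ranking:
    """Rank descending by score with stable ascending-class-id tie-break."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    cls = list(class_ids)
    alpha = np.argsort(np.argsort(cls))        # alphabetical rank of each column
    order = np.empty_like(z, dtype=int)
    for i in range(z.shape[0]):
        order[i] = np.lexsort((alpha, -z[i]))
    return Ranking(image_ids, cls, order, scores=z)


def score_document(caption_set: CaptionSet, document: Document,
                   model: SentencePairClassifier,
                   caption_cache: EmbeddingCache, corpus_cache: EmbeddingCache) -> float:
    """z_ij: mean comparator score over all caption × sentence pairs, the
    caption always in the first (layperson) slot."""
    if not caption_set.captions or not document.sentences:
        raise ValueError("caption set and document must be non-empty")
    A = caption_cache.vectors(caption_set.texts)
    S = corpus_cache.vectors(list(document.sentences))
    return float(model.score_pairs(A, S).mean())


def score_corpus(caption_sets: Sequence[CaptionSet], corpus: Corpus,
                 model: SentencePairClassifier,
                 caption_cache: EmbeddingCache, corpus_cache: EmbeddingCache) -> ScoreMatrix:
    """All z_ij at once (vectorised; equal to per-cell score_document)."""
    A = np.vstack([caption_cache.vectors(cs.texts) for cs in caption_sets])
    cap_counts = [len(cs.captions) for cs in caption_sets]
    cap_slices = np.concatenate([[0], np.cumsum(cap_counts)])
    S = np.vstack([corpus_cache.vectors(list(d.sentences)) for d in corpus.documents])
    sent_counts = [len(d.sentences) for d in corpus.documents]
    doc_slices = np.concatenate([[0], np.cumsum(sent_counts)])
    sc = model.score_pairs(A, S)
    z = np.empty((len(caption_sets), corpus.n_classes))
    for i in range(len(caption_sets)):
        block = sc[cap_slices[i]:cap_slices[i + 1]]
        for j in range(corpus.n_classes):
            z[i, j] = block[:, doc_slices[j]:doc_slices[j + 1]].mean()
    return ScoreMatrix(tuple(cs.image_id for cs in caption_sets),
                       tuple(corpus.class_ids), z)


def document_posteriors(Z: ScoreMatrix, sign: int = 1) -> ProbMatrix:
    """Row-wise softmax of sign·z.

    The default (+1) makes the highest-scoring document the most probable
    one, which is the convention the ranking uses; ``sign=-1`` is kept as
    an audit flag for the opposite orientation.
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    z = sign * Z.z
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return ProbMatrix(Z.image_ids, Z.class_ids, e / e.sum(axis=1, keepdims=True))


def rank_documents(Z: ScoreMatrix) -> Ranking:
    return ranking_from_scores(Z.image_ids, Z.class_ids, Z.z)


def regularizer(P: ProbMatrix | np.ndarray) -> float:
    """Batch regularizer R = Σ_x [−⟨p_x,p_x⟩ + Σ_{x'≠x} ⟨p_x,p_{x'}⟩].

    Equals ‖Σ_x p_x‖² − 2 Σ_x ‖p_x‖²; lower is better (peaked rows on
    mutually distinct documents).
    """
    rows = P.p if isinstance(P, ProbMatrix) else np.atleast_2d(np.asarray(P, dtype=np.float64))
    G = rows @ rows.T
    return float(G.sum() - 2.0 * np.trace(G))


class DocumentRetriever(BaseEstimator):
    """Recognition-as-retrieval front end over a trained comparator.

    ``fit`` embeds and caches the expert corpus; ``predict`` labels each
    image with the class of its top-ranked document.
    """

    def __init__(self, model: SentencePairClassifier | None = None,
                 spec: EncoderSpec | None = None, posterior_sign: int = 1):
        self.model = model
        self.spec = spec
        self.posterior_sign = posterior_sign

    def fit(self, corpus: Corpus, y=None):
        if self.model is None:
            raise ValueError("DocumentRetriever needs a trained comparator model")
        self.spec_ = self.spec or EncoderSpec()
        self.corpus_ = corpus
        self.corpus_cache_ = precompute_cache(corpus, self.spec_)
        self.classes_ = np.array(corpus.class_ids)
        return self

    def decision_function(self, caption_sets: Sequence[CaptionSet]) -> ScoreMatrix:
        cap_cache = precompute_cache(list(caption_sets), self.spec_)
        return score_corpus(caption_sets, self.corpus_, self.model,
                            cap_cache, self.corpus_cache_)

    def predict_proba(self, caption_sets: Sequence[CaptionSet]) -> ProbMatrix:
        return document_posteriors(self.decision_function(caption_sets),
                                   sign=self.posterior_sign)

    def rank(self, caption_sets: Sequence[CaptionSet]) -> Ranking:
        return rank_documents(self.decision_function(caption_sets))

    def predict(self, caption_sets: Sequence[CaptionSet]) -> np.ndarray:
        r = self.rank(caption_sets)
        return np.array([r.top(img, 1)[0] for img in r.image_ids])
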