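"""Classical ranking baselines: TF-IDF cosine, Okapi BM25, embedding cosine.

All three consume the same caption-set / corpus types and emit the same
Ranking as the trained comparator, so they are drop-in comparable.
TF-IDF uses word n-grams with n ∈ {2, 3}; BM25 is the classic Okapi
formula with k1 = 1.5, b = 0.75 and no flooring of negative IDF terms.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import cosine_similarity

from .corpus_io import CaptionSet, Corpus
from .encode import EncoderSpec, embed
from .retrieval import Ranking, ranking_from_scores

__all__ = [
    "TfIdfConfig",
    "Bm25Config",
    "TfidfRetriever",
    "Bm25Retriever",
    "CosineEmbeddingRetriever",
    "tfidf_rank",
    "bm25_rank",
    "cosine_embedding_rank",
]

logger = logging.getLogger(__name__)

_WORD = re.compile(r"[a-z0-9]+")


def _tokenize(text: str) -> list[str]:
    return _WORD.findall(text.lower())


def _doc_text(corpus: Corpus, j: int) -> str:
    return " ".join(corpus.documents[j].sentences)


@dataclass(frozen=True)
class TfIdfConfig:
    ngram_range: tuple[int, int] = (2, 3)
    sublinear_tf: bool = False
    analyzer: str = "word"  # "word" or "char"

    def __post_init__(self) -> None:
        lo, hi = self.ngram_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid ngram_range {self.ngram_range}")


@dataclass(frozen=True)
class Bm25Config:
    k1: float = 1.5
    b: float = 0.75

    def __post_init__(self) -> None:
        if self.k1 < 0 or not 0.0 <= self.b <= 1.0:
            raise ValueError("require k1 >= 0 and 0 <= b <= 1")


class TfidfRetriever(BaseEstimator):
    """Rank documents by cosine similarity of TF-IDF n-gram vectors; the
    query is the image's captions pooled into one text."""

    def __init__(self, ngram_range=(2, 3), sublinear_tf=False, analyzer="word"):
        self.ngram_range = ngram_range
        self.sublinear_tf = sublinear_tf
        self.analyzer = analyzer

    def fit(self, corpus: Corpus, y=None):
        TfIdfConfig(tuple(self.ngram_range), self.sublinear_tf, self.analyzer)
        self.corpus_ = corpus
        self.vectorizer_ = TfidfVectorizer(
            analyzer=self.analyzer, ngram_range=tuple(self.ngram_range),
            sublinear_tf=self.sublinear_tf)
        self.doc_matrix_ = self.vectorizer_.fit_transform(
            [_doc_text(corpus, j) for j in range(corpus.n_classes)])
        return self

    def decision_function(self, caption_sets: Sequence[CaptionSet]) -> np.ndarray:
        queries = [" ".join(cs.texts) for cs in caption_sets]
        q = self.vectorizer_.transform(queries)
        scores = cosine_similarity(q, self.doc_matrix_)
        empty = np.asarray(q.multiply(q).sum(axis=1)).ravel() == 0
        if np.any(empty):
            logger.warning("%d queries share no n-gram with the corpus "
                           "vocabulary; their scores are uniform", int(empty.sum()))
            scores[empty] = 0.0
        return scores

    def rank(self, caption_sets: Sequence[CaptionSet]) -> Ranking:
        return ranking_from_scores([cs.image_id for cs in caption_sets],
                                   self.corpus_.class_ids,
                                   self.decision_function(caption_sets))

    def predict(self, caption_sets: Sequence[CaptionSet]) -> np.ndarray:
        r = self.rank(caption_sets)
        return np.array([r.top(img)[0] for img in r.image_ids])


class Bm25Retriever(BaseEstimator):
    """Okapi BM25 over pooled caption tokens.

    score(q, d) = Σ_t idf(t) · tf·(k1+1) / (tf + k1·(1−b+b·|d|/avgdl)),
    idf(t) = ln((N − df + 0.5)/(df + 0.5)).  Terms present in most
    documents get negative IDF and are kept as-is.
    """

    def __init__(self, k1: float = 1.5, b: float = 0.75):
        self.k1 = k1
        self.b = b

    def fit(self, corpus: Corpus, y=None):
        Bm25Config(self.k1, self.b)
        self.corpus_ = corpus
        self.doc_tokens_ = [_tokenize(_doc_text(corpus, j)) for j in range(corpus.n_classes)]
        self.doc_len_ = np.array([len(t) for t in self.doc_tokens_], dtype=float)
        self.avgdl_ = float(self.doc_len_.mean())
        self.tf_ = []
        df: dict[str, int] = {}
        for toks in self.doc_tokens_:
            counts: dict[str, int] = {}
            for t in toks:
                counts[t] = counts.get(t, 0) + 1
            self.tf_.append(counts)
            for t in counts:
                df[t] = df.get(t, 0) + 1
        N = corpus.n_classes
        self.idf_ = {t: math.log((N - d + 0.5) / (d + 0.5)) for t, d in df.items()}
        return self

    def decision_function(self, caption_sets: Sequence[CaptionSet]) -> np.ndarray:
        scores = np.zeros((len(caption_sets), self.corpus_.n_classes))
        for i, cs in enumerate(caption_sets):
            query = _tokenize(" ".join(cs.texts))
            for j in range(self.corpus_.n_classes):
                norm = self.k1 * (1.0 - self.b + self.b * self.doc_len_[j] / self.avgdl_)
                s = 0.0
                for t in query:
                    tf = self.tf_[j].get(t, 0)
                    if tf:
                        s += self.idf_[t] * tf * (self.k1 + 1.0) / (tf + norm)
                scores[i, j] = s
        return scores

    def rank(self, caption_sets: Sequence[CaptionSet]) -> Ranking:
        return ranking_from_scores([cs.image_id for cs in caption_sets],
                                   self.corpus_.class_ids,
                                   self.decision_function(caption_sets))

    def predict(self, caption_sets: Sequence[CaptionSet]) -> np.ndarray:
        r = self.rank(caption_sets)
        return np.array([r.top(img)[0] for img in r.image_ids])


class CosineEmbeddingRetriever(BaseEstimator):
    """Rank by the mean cosine similarity over caption × sentence pairs,
    captions kept separate (not pooled) as in sentence-embedding ranking."""

    def __init__(self, spec: EncoderSpec | None = None):
        self.spec = spec

    def fit(self, corpus: Corpus, y=None):
        self.spec_ = self.spec or EncoderSpec()
        self.corpus_ = corpus
        self.sent_embs_ = [embed(list(d.sentences), self.spec_) for d in corpus.documents]
        self.sent_norms_ = [np.linalg.norm(e, axis=1) for e in self.sent_embs_]
        return self

    def decision_function(self, caption_sets: Sequence[CaptionSet]) -> np.ndarray:
        scores = np.zeros((len(caption_sets), self.corpus_.n_classes))
        warned = False
        for i, cs in enumerate(caption_sets):
            C = embed(cs.texts, self.spec_)
            cn = np.linalg.norm(C, axis=1)
            if np.any(cn == 0) and not warned:
                logger.warning("zero-norm embedding in captions; cosine set to 0")
                warned = True
            for j, (S, sn) in enumerate(zip(self.sent_embs_, self.sent_norms_)):
                denom = np.outer(cn, sn)
                with np.errstate(divide="ignore", invalid="ignore"):
                    cos = np.where(denom > 0, (C @ S.T) / np.where(denom > 0, denom, 1.0), 0.0)
                scores[i, j] = cos.mean()
        return scores

    def rank(self, caption_sets: Sequence[CaptionSet]) -> Ranking:
        return ranking_from_scores([cs.image_id for cs in caption_sets],
                                   self.corpus_.class_ids,
                                   self.decision_function(caption_sets))

    def predict(self, caption_sets: Sequence[CaptionSet]) -> np.ndarray:
        r = self.rank(caption_sets)
        return np.array([r.top(img)[0] for img in r.image_ids])


# -- thin functional wrappers -------------------------------------------------

def tfidf_rank(caption_set: CaptionSet, corpus: Corpus,
               config: TfIdfConfig | None = None) -> Ranking:
    cfg = config or TfIdfConfig()
    est = TfidfRetriever(ngram_range=cfg.ngram_range, sublinear_tf=cfg.sublinear_tf,
                         analyzer=cfg.analyzer).fit(corpus)
    return est.rank([caption_set])


def bm25_rank(caption_set: CaptionSet, corpus: Corpus,
              config: Bm25Config | None = None) -> Ranking:
    cfg = config or Bm25Config()
    return Bm25Retriever(k1=cfg.k1, b=cfg.b).fit(corpus).rank([caption_set])


def cosine_embedding_rank(caption_set: CaptionSet, corpus: Corpus,
                          spec: EncoderSpec | None = None) -> Ranking:
    return CosineEmbeddingRetriever(spec=spec).fit(corpus).rank([caption_set])
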