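"""Synthesis of labelled sentence pairs without any class supervision.

Positive pairs: two different descriptions of the same image.  Negative
pairs: descriptions of different images (almost always different species
at fine granularity; no further filtering is applied on purpose).
Neutral pairs: a caption paired with a corpus sentence or another
caption sharing no noun with it — sentences that talk about different
parts carry neither entailing nor contradicting signal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import CaptionSet, Corpus, NounTagger, neutral_eligible

__all__ = [
    "SentencePair",
    "PairDataset",
    "make_positive_pairs",
    "make_negative_pairs",
    "make_neutral_pairs",
    "build_pair_dataset",
    "save_pairs",
    "load_pairs",
]

logger = logging.getLogger(__name__)

LABELS = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class SentencePair:
    text_a: str           # always a layperson caption
    text_b: str           # caption or corpus sentence
    label: str            # positive | negative | neutral
    source: str = "cap-cap"  # cap-cap | cap-doc

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.source not in ("cap-cap", "cap-doc"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class PairDataset:
    pairs: list[SentencePair]
    seed: int
    label_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for p in self.pairs:
            counts[p.label] = counts.get(p.label, 0) + 1
        self.label_counts = counts

    def manifest(self) -> dict:
        return {"seed": self.seed, "n_pairs": len(self.pairs),
                "label_counts": dict(sorted(self.label_counts.items()))}


def make_positive_pairs(caption_sets: Sequence[CaptionSet]) -> list[SentencePair]:
    """All unordered pairs of distinct captions of the same image.

    An image with a single caption contributes nothing (logged); pairs of
    captions with identical text are skipped, since a self-identical pair
    carries no contrast.
    """
    out: list[SentencePair] = []
    for cs in caption_sets:
        if len(cs.captions) < 2:
            logger.warning("image %s has a single caption; no positive pairs", cs.image_id)
            continue
        for a, b in combinations(cs.captions, 2):
            if a.text == b.text:
                continue
            out.append(SentencePair(a.text, b.text, "positive", "cap-cap"))
    return out


def make_negative_pairs(caption_sets: Sequence[CaptionSet], n_per_caption: int = 1,
                        seed: int = 0) -> list[SentencePair]:
    """For each caption, sample partners uniformly from the captions of all
    *other* images (with replacement).  Class identity is deliberately
    ignored: cross-image pairs are overwhelmingly cross-class."""
    if len(caption_sets) < 2:
        raise ValueError("negative pairs need at least two images (no complement)")
    rng = np.random.default_rng(seed)
    all_caps = [(cs.image_id, c.text) for cs in caption_sets for c in cs.captions]
    image_of = np.array([i for i, (img, _) in enumerate(all_caps)])
    img_ids = [img for img, _ in all_caps]
    out: list[SentencePair] = []
    n_total = len(all_caps)
    for i, (img, text) in enumerate(all_caps):
        complement = [j for j in range(n_total) if img_ids[j] != img]
        picks = rng.choice(len(complement), size=n_per_caption, replace=True)
        for p in picks:
            out.append(SentencePair(text, all_caps[complement[p]][1], "negative", "cap-cap"))
    return out


def make_neutral_pairs(caption_sets: Sequence[CaptionSet], corpus: Corpus | None,
                       n: int, seed: int = 0,
                       tagger: NounTagger | None = None) -> list[SentencePair]:
    """Sample n caption/sentence pairs sharing no noun.

    Two pools are mixed with equal probability per pair: caption–caption
    (different images) and caption–document sentence.  Eligible pairs are
    enumerated exactly and drawn uniformly within each pool; if one pool
    is empty it is logged and the other is used alone.
    """
    rng = np.random.default_rng(seed)
    caps = [(cs.image_id, c) for cs in caption_sets for c in cs.captions]
    cap_nouns = [c.nouns for _, c in caps]

    cap_pool: list[tuple[str, str]] = []
    for i, (img_i, ci) in enumerate(caps):
        for j, (img_j, cj) in enumerate(caps):
            if i == j or img_i == img_j:
                continue
            if not (cap_nouns[i] & cap_nouns[j]):
                cap_pool.append((ci.text, cj.text))

    doc_pool: list[tuple[str, str]] = []
    if corpus is not None:
        from .corpus_io import extract_nouns
        doc_sents = [s for d in corpus.documents for s in d.sentences]
        doc_nouns = [frozenset(extract_nouns(s, tagger)) for s in doc_sents]
        for i, (_, ci) in enumerate(caps):
            for s, sn in zip(doc_sents, doc_nouns):
                if not (cap_nouns[i] & sn):
                    doc_pool.append((ci.text, s))

    if not cap_pool and not doc_pool:
        raise ValueError("no neutral-eligible pair exists in either pool")
    if not cap_pool:
        logger.warning("caption-caption neutral pool empty; using document pool only")
    if not doc_pool:
        logger.warning("caption-document neutral pool empty; using caption pool only")

    out: list[SentencePair] = []
    for _ in range(n):
        use_doc = bool(doc_pool) and (not cap_pool or rng.random() < 0.5)
        pool, source = (doc_pool, "cap-doc") if use_doc else (cap_pool, "cap-cap")
        a, b = pool[int(rng.integers(0, len(pool)))]
        out.append(SentencePair(a, b, "neutral", source))
    return out


def build_pair_dataset(caption_sets: Sequence[CaptionSet], corpus: Corpus | None = None,
                       mode: str = "2-class", size_per_label: int = 1000,
                       seed: int = 0, tagger: NounTagger | None = None,
                       both_orders: bool = False) -> PairDataset:
    """Balanced, shuffled training set of labelled pairs.

    2-class mode emits positives and negatives; 3-class mode adds an equal
    number of neutral pairs (which need a corpus or a noun-disjoint
    caption pool).  Each unordered pair is emitted in one canonical order;
    ``both_orders=True`` additionally emits the swapped order of every
    pair (the comparator input is order-sensitive).
    """
    if mode not in ("2-class", "3-class"):
        raise ValueError(f"mode must be '2-class' or '3-class', got {mode!r}")
    rng = np.random.default_rng(seed)

    positives = make_positive_pairs(caption_sets)
    if size_per_label > len(positives):
        raise ValueError(
            f"requested {size_per_label} positives but only {len(positives)} "
            f"are attainable from these caption sets")
    pos_idx = rng.choice(len(positives), size=size_per_label, replace=False)
    chosen = [positives[i] for i in pos_idx]

    negatives = make_negative_pairs(caption_sets, n_per_caption=1,
                                    seed=int(rng.integers(0, 2**31)))
    if size_per_label <= len(negatives):
        neg_idx = rng.choice(len(negatives), size=size_per_label, replace=False)
        chosen += [negatives[i] for i in neg_idx]
    else:
        extra = make_negative_pairs(
            caption_sets,
            n_per_caption=int(np.ceil(size_per_label / len(negatives))),
            seed=int(rng.integers(0, 2**31)))
        neg_idx = rng.choice(len(extra), size=size_per_label, replace=False)
        chosen += [extra[i] for i in neg_idx]

    if mode == "3-class":
        chosen += make_neutral_pairs(caption_sets, corpus, n=size_per_label,
                                     seed=int(rng.integers(0, 2**31)), tagger=tagger)

    if both_orders:
        chosen += [SentencePair(p.text_b, p.text_a, p.label, p.source)
                   for p in chosen]
    order = rng.permutation(len(chosen))
    return PairDataset(pairs=[chosen[i] for i in order], seed=seed)


def save_pairs(dataset: PairDataset, path: str | Path) -> None:
    """Write pairs as JSONL plus a <path>.manifest.json with seed/counts."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for p in dataset.pairs:
            fh.write(json.dumps({"a": p.text_a, "b": p.text_b,
                                 "label": p.label, "source": p.source}) + "\n")
    manifest = dataset.manifest()
    manifest["generator_version"] = 1
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1),
                                                  encoding="utf-8")


def load_pairs(path: str | Path) -> PairDataset:
    path = Path(path)
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                pairs.append(SentencePair(rec["a"], rec["b"], rec["label"], rec["source"]))
    manifest_path = Path(str(path) + ".manifest.json")
    seed = -1
    if manifest_path.exists():
        seed = json.loads(manifest_path.read_text())["seed"]
    return PairDataset(pairs=pairs, seed=seed)
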