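"""Reading, normalising and segmenting caption sets and expert corpora.

The retrieval pipeline works on two kinds of text: free-form layperson
descriptions of an image (captions) and expert articles, one per species
(documents).  This module owns the shared plumbing: sentence segmentation,
class-name masking (so a model can never cheat by reading the species name
inside its own article), and noun extraction, which downstream pair mining
uses to decide whether two sentences could possibly talk about the same
body part.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

__all__ = [
    "Caption",
    "CaptionSet",
    "Document",
    "Corpus",
    "NounTagger",
    "DictionaryNounTagger",
    "DEFAULT_NOUN_LEXICON",
    "normalize_text",
    "split_sentences",
    "mask_class_names",
    "extract_nouns",
    "neutral_eligible",
    "load_captions",
    "load_corpus",
    "save_corpus",
]


def normalize_text(text: str) -> str:
    """NFC-normalise and collapse runs of whitespace; surface case is kept."""
    text = unicodedata.normalize("NFC", text)
    return re.sub(r"\s+", " ", text).strip()


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

#: words after which a period does not end a sentence
_ABBREVIATIONS = {
    "approx", "e.g", "i.e", "cf", "ca", "vs", "etc", "al", "fig", "sp",
    "subsp", "no", "dr", "mr", "mrs", "ms", "st", "mt", "cm", "mm", "in",
}

_BOUNDARY = re.compile(r"([.!?]+)(\s+|$)")


def split_sentences(text: str) -> list[str]:
    """Split text into sentences with a rule-based segmenter.

    Splits at ``.``/``!``/``?`` followed by whitespace, except after a known
    abbreviation or a single letter (initials).  The concatenation of the
    returned sentences covers all non-whitespace content of the input.
    """
    text = normalize_text(text)
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        prev_word = text[start:m.start()].rsplit(None, 1)[-1] if text[start:m.start()].strip() else ""
        prev_word = prev_word.rstrip(".").lower()
        if m.group(1) == "." and (prev_word in _ABBREVIATIONS
                                  or (len(prev_word) == 1 and prev_word.isalpha())):
            continue
        chunk = text[start:m.end(1)].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# class-name masking
# ---------------------------------------------------------------------------

def mask_class_names(text: str, class_names: Sequence[str], mask_token: str) -> str:
    """Replace every whole-word, case-insensitive mention of a class name.

    Longest names are tried first, so "Downy Woodpecker" wins over
    "Woodpecker" and yields a single replacement.  The operation is
    idempotent provided ``mask_token`` itself matches no class name.
    """
    if not text:
        return text
    names = sorted({n for n in class_names if n.strip()}, key=len, reverse=True)
    if not names:
        raise ValueError("class_names must contain at least one non-empty name")
    pattern = re.compile(
        r"\b(?:" + "|".join(re.escape(n) for n in names) + r")\b",
        flags=re.IGNORECASE,
    )
    return pattern.sub(mask_token, text)


# ---------------------------------------------------------------------------
# noun extraction
# ---------------------------------------------------------------------------

class NounTagger(Protocol):
    """Anything that maps raw text to a set of lowercased noun lemmas."""

    def nouns(self, text: str) -> set[str]: ...


#: Closed noun lexicon for the offline dictionary tagger: body parts and
#: their expert jargon, common natural-history nouns, and generic terms
#: that show up in species articles.  Entries are singular lemmas.
DEFAULT_NOUN_LEXICON: frozenset[str] = frozenset({
    # subjects
    "bird", "flower", "plant", "species", "male", "female", "adult",
    # layperson part vocabulary
    "wing", "belly", "head", "beak", "tail", "breast", "crown", "throat",
    "eye", "leg", "bill", "nape", "chest", "back", "side", "body",
    "feather", "plumage", "petal", "stem", "leaf", "bloom",
    # expert jargon (kept injective with the plain terms above)
    "remex", "venter", "pileum", "culmen", "rectrix", "pectus", "vertex",
    # appearance nouns
    "color", "colour", "pattern", "spot", "stripe", "bar", "patch",
    "tone", "marking", "tint", "hue",
    # habitat / behaviour filler vocabulary
    "seed", "insect", "berry", "fruit", "tree", "forest", "woodland",
    "wetland", "marsh", "meadow", "shrub", "ground", "garden",
    "winter", "summer", "spring", "autumn", "migration", "nest", "song",
    "flock", "pair", "region", "range", "area", "habitat", "altitude",
    "coast", "mountain", "river", "population", "status", "diet",
})

_TOKEN = re.compile(r"[a-zA-Z]+")


def _lemmatize(token: str) -> str:
    """Strip regular English plural endings (ies→y, -es, -s)."""
    t = token.lower()
    if t.endswith("ies") and len(t) > 4:
        return t[:-3] + "y"
    if t.endswith(("ches", "shes", "sses", "xes", "zes")):
        return t[:-2]
    if t.endswith("s") and not t.endswith("ss") and len(t) > 3:
        return t[:-1]
    return t


@dataclass(frozen=True)
class DictionaryNounTagger:
    """Deterministic tagger over a closed noun lexicon.

    A token counts as a noun iff its lemma (after plural stripping) is in
    the lexicon.  Irregular plurals can be added to the lexicon directly.
    """

    lexicon: frozenset[str] = DEFAULT_NOUN_LEXICON

    def nouns(self, text: str) -> set[str]:
        out: set[str] = set()
        for tok in _TOKEN.findall(text):
            low = tok.lower()
            if low in self.lexicon:
                out.add(low)
                continue
            lemma = _lemmatize(low)
            if lemma in self.lexicon:
                out.add(lemma)
        return out


_DEFAULT_TAGGER = DictionaryNounTagger()


def extract_nouns(text: str, tagger: NounTagger | None = None) -> set[str]:
    """Lowercased noun lemmas of ``text`` under the configured tagger."""
    return (tagger or _DEFAULT_TAGGER).nouns(text)


def neutral_eligible(text_a: str, text_b: str, tagger: NounTagger | None = None) -> bool:
    """True iff the two sentences share no noun — the single source of truth
    for the neutral-pair predicate used during pair synthesis."""
    return not (extract_nouns(text_a, tagger) & extract_nouns(text_b, tagger))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Caption:
    """One layperson description of one image."""

    image_id: str
    text: str
    sentences: tuple[str, ...] = field(default=())
    nouns: frozenset[str] = field(default=frozenset())

    @classmethod
    def create(cls, image_id: str, text: str, tagger: NounTagger | None = None) -> "Caption":
        norm = normalize_text(text)
        if not norm:
            raise ValueError(f"caption for image {image_id!r} is empty after normalization")
        return cls(
            image_id=image_id,
            text=norm,
            sentences=tuple(split_sentences(norm)),
            nouns=frozenset(extract_nouns(norm, tagger)),
        )


@dataclass(frozen=True)
class CaptionSet:
    """All captions attached to one image; the true class is evaluation-only."""

    image_id: str
    captions: tuple[Caption, ...]
    true_class_id: str | None = None

    def __post_init__(self) -> None:
        if not self.captions:
            raise ValueError(f"CaptionSet {self.image_id!r} has no captions")
        if any(c.image_id != self.image_id for c in self.captions):
            raise ValueError(f"CaptionSet {self.image_id!r} mixes image ids")

    @property
    def texts(self) -> list[str]:
        return [c.text for c in self.captions]


@dataclass(frozen=True)
class Document:
    """Sentence-segmented expert article for one class."""

    class_id: str
    title: str
    sentences: tuple[str, ...]
    section_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sentences:
            raise ValueError(f"document {self.class_id!r} has no sentences")
        if self.section_labels is not None and len(self.section_labels) != len(self.sentences):
            raise ValueError("section_labels must parallel sentences")


@dataclass(frozen=True)
class Corpus:
    """One document per class; K = len(documents)."""

    documents: tuple[Document, ...]
    mask_token: str = "a bird"

    def __post_init__(self) -> None:
        ids = [d.class_id for d in self.documents]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate class ids in corpus: {dupes}")
        if len(ids) < 2:
            raise ValueError("a corpus needs at least two documents")

    @property
    def class_ids(self) -> list[str]:
        return [d.class_id for d in self.documents]

    @property
    def n_classes(self) -> int:
        return len(self.documents)

    def masked(self, class_names: Iterable[str]) -> "Corpus":
        """Return a corpus with every class-name mention replaced by the
        mask token in every document."""
        names = list(class_names)
        docs = tuple(
            Document(
                class_id=d.class_id,
                title=mask_class_names(d.title, names, self.mask_token),
                sentences=tuple(mask_class_names(s, names, self.mask_token) for s in d.sentences),
                section_labels=d.section_labels,
            )
            for d in self.documents
        )
        return Corpus(documents=docs, mask_token=self.mask_token)


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_captions(path: str | Path, tagger: NounTagger | None = None) -> list[CaptionSet]:
    """Load caption sets from a JSONL file.

    Each record must carry ``image_id`` and non-empty ``text``; an optional
    ``class_id`` is kept as the evaluation-only truth label.  Records are
    grouped by image in order of first appearance, per-image caption order
    preserved.
    """
    path = Path(path)
    groups: dict[str, list[Caption]] = {}
    truth: dict[str, str | None] = {}
    n = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n += 1
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON record: {exc}") from exc
            if not isinstance(rec, dict) or "image_id" not in rec or "text" not in rec:
                raise ValueError(f"{path}:{lineno}: record must have image_id and text fields")
            image_id = str(rec["image_id"])
            text = rec["text"]
            if not isinstance(text, str) or not normalize_text(text):
                raise ValueError(f"{path}:{lineno}: empty or non-string text")
            groups.setdefault(image_id, []).append(Caption.create(image_id, text, tagger))
            cls = rec.get("class_id")
            if image_id in truth and truth[image_id] != cls:
                raise ValueError(f"{path}:{lineno}: conflicting class_id for image {image_id!r}")
            truth[image_id] = cls
    if n == 0:
        raise ValueError(f"{path}: no caption records")
    return [
        CaptionSet(image_id=i, captions=tuple(caps), true_class_id=truth[i])
        for i, caps in groups.items()
    ]


def _document_from_sections(class_id: str, title: str, sections: Mapping[str, str]) -> Document:
    sentences: list[str] = []
    labels: list[str] = []
    for label, text in sections.items():
        for s in split_sentences(text):
            sentences.append(s)
            labels.append(label)
    if not sentences:
        raise ValueError(f"document {class_id!r} is empty")
    return Document(class_id=class_id, title=title, sentences=tuple(sentences),
                    section_labels=tuple(labels))


def load_corpus(path: str | Path, mask_token: str = "a bird") -> Corpus:
    """Load an expert corpus.

    Accepts either a JSON file — a list of
    ``{"class_id", "title", "sections": {label: text}}`` objects — or a
    directory of ``<class_id>.txt`` files, one article per class.
    """
    path = Path(path)
    docs: list[Document] = []
    if path.is_dir():
        files = sorted(path.glob("*.txt"))
        if not files:
            raise ValueError(f"{path}: no .txt documents found")
        for f in files:
            text = f.read_text(encoding="utf-8")
            if not normalize_text(text):
                raise ValueError(f"{f}: empty document")
            docs.append(Document(class_id=f.stem, title=f.stem,
                                 sentences=tuple(split_sentences(text))))
    else:
        with open(path, encoding="utf-8") as fh:
            records = json.load(fh)
        if not isinstance(records, list) or not records:
            raise ValueError(f"{path}: expected a non-empty JSON list of documents")
        for rec in records:
            docs.append(_document_from_sections(
                class_id=str(rec["class_id"]),
                title=str(rec.get("title", rec["class_id"])),
                sections=rec.get("sections", {"body": rec.get("text", "")}),
            ))
    return Corpus(documents=tuple(docs), mask_token=mask_token)


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as the JSON list format read by :func:`load_corpus`.

    Sentences are stored one per section entry keyed by their label (or
    ``body``), joined by spaces, so load ∘ save round-trips sentence lists.
    """
    records = []
    for d in corpus.documents:
        sections: dict[str, str] = {}
        labels = d.section_labels or tuple("body" for _ in d.sentences)
        for label, sentence in zip(labels, d.sentences):
            sections[label] = (sections[label] + " " + sentence) if label in sections else sentence
        records.append({"class_id": d.class_id, "title": d.title, "sections": sections})
    Path(path).write_text(json.dumps(records, indent=1), encoding="utf-8")
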