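"""Attribute-structured synthetic worlds for end-to-end testing.

Each synthetic species is a fixed assignment of colours to body parts (its
*signature*).  Layperson captions render a few parts of the signature in
plain templates, optionally corrupted by attribute dropout and a colour
confusion matrix (emulating that, say, blue and black often look alike).
Expert documents mix visual sentences — which may use an injective jargon
lexicon ("crimson" for red, "remex" for wing) — with non-visual filler
about habitat and behaviour that by construction shares no noun with any
caption.  The result is a world where the ground truth is known, the
separable configuration is provably identifiable, and every noise knob is
controlled.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .corpus_io import Caption, CaptionSet, Corpus, Document

__all__ = [
    "SynthConfig",
    "SpeciesSpec",
    "JARGON_PARTS",
    "JARGON_COLORS",
    "generate_species",
    "generate_captions",
    "generate_documents",
    "generate_benchmark",
    "save_benchmark",
]

#: injective plain-term → jargon-term tables (one jargon word per plain word)
JARGON_PARTS: dict[str, str] = {
    "wing": "remex", "belly": "venter", "head": "pileum",
    "beak": "culmen", "tail": "rectrix", "breast": "pectus",
    "crown": "vertex",
}
JARGON_COLORS: dict[str, str] = {
    "red": "crimson", "blue": "cerulean", "black": "ebony",
    "white": "alabaster", "yellow": "aureate", "green": "verdant",
    "brown": "umber", "grey": "cinereous",
}

_FILLER_TEMPLATES = (
    "They eat seeds and berries in winter.",
    "Nests are built near marshes and wetlands.",
    "The population is stable across its range.",
    "Migration occurs in spring and autumn.",
    "They gather in large flocks near the coast.",
    "The habitat includes woodlands and meadows.",
    "Its song carries far in the forest.",
    "The diet shifts toward insects in summer.",
)

_CAPTION_TEMPLATES = (
    "this bird has {attrs}.",
    "a small bird with {attrs}.",
    "it has {attrs}.",
    "you can see {attrs}.",
)

_GENUS_SYLLABLES = ("cor", "par", "tur", "lox", "seto", "pica", "vireo", "icter")
_EPITHET_SYLLABLES = ("alba", "rubra", "minor", "major", "virens", "pallida", "nigra", "flava")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    K: int = 20
    parts: tuple[str, ...] = ("wing", "belly", "head", "beak", "tail", "breast", "crown")
    colors: tuple[str, ...] = ("red", "blue", "black", "white", "yellow", "green", "brown", "grey")
    images_per_species: int = 5
    captions_per_image: int = 5
    parts_per_caption: int = 2
    attribute_dropout: float = 0.1
    color_confusion: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"blue": {"black": 0.1}, "black": {"blue": 0.1}}
    )
    jargon_rate: float = 0.25
    filler_fraction: float = 0.3
    doc_sentences: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K > len(self.colors) ** len(self.parts):
            raise ValueError(
                f"K={self.K} exceeds the number of distinct signatures "
                f"{len(self.colors)}^{len(self.parts)} = {len(self.colors) ** len(self.parts)}"
            )
        for p in (self.attribute_dropout, self.jargon_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.filler_fraction < 1.0:
            raise ValueError("filler_fraction must lie in [0, 1)")
        if not 1 <= self.parts_per_caption <= len(self.parts):
            raise ValueError("parts_per_caption out of range")

    def separable(self) -> "SynthConfig":
        """Noise-free copy: no dropout, no confusion, no jargon."""
        return dataclasses.replace(
            self, attribute_dropout=0.0, color_confusion={}, jargon_rate=0.0
        )


@dataclass(frozen=True)
class SpeciesSpec:
    class_id: str
    signature: Mapping[str, str]  # part → colour
    name: str                     # binomial-style, for masking tests


def _streams(config: SynthConfig) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)]


def generate_species(config: SynthConfig) -> list[SpeciesSpec]:
    """Sample K species with distinct part→colour signatures (no replacement)."""
    rng = _streams(config)[0]
    n_space = len(config.colors) ** len(config.parts)
    if n_space <= 4096:
        space = list(itertools.product(config.colors, repeat=len(config.parts)))
        idx = rng.choice(n_space, size=config.K, replace=False)
        sigs = [space[i] for i in idx]
    else:
        seen: set[tuple[str, ...]] = set()
        sigs = []
        while len(sigs) < config.K:
            sig = tuple(config.colors[i] for i in rng.integers(0, len(config.colors), len(config.parts)))
            if sig not in seen:
                seen.add(sig)
                sigs.append(sig)
    species = []
    used_names: set[str] = set()
    for k, sig in enumerate(sigs):
        while True:
            genus = str(rng.choice(_GENUS_SYLLABLES)).capitalize() + str(rng.choice(_EPITHET_SYLLABLES))[:3]
            epithet = str(rng.choice(_EPITHET_SYLLABLES))
            name = f"{genus} {epithet}"
            if name not in used_names:
                used_names.add(name)
                break
        species.append(SpeciesSpec(
            class_id=f"sp{k:03d}",
            signature=dict(zip(config.parts, sig)),
            name=name,
        ))
    return species


def _render_caption(sig: Mapping[str, str], config: SynthConfig, rng: np.random.Generator) -> str:
    part_idx = rng.choice(len(config.parts), size=config.parts_per_caption, replace=False)
    attrs = []
    for i in sorted(part_idx):
        part = config.parts[i]
        if config.attribute_dropout > 0 and rng.random() < config.attribute_dropout:
            continue
        color = sig[part]
        row = config.color_confusion.get(color, {})
        for wrong, p in row.items():
            if p > 0 and rng.random() < p:
                color = wrong
                break
        attrs.append(f"a {color} {part}")
    template = _CAPTION_TEMPLATES[int(rng.integers(0, len(_CAPTION_TEMPLATES)))]
    if not attrs:
        return "this is a small bird."
    if len(attrs) == 1:
        joined = attrs[0]
    else:
        joined = ", ".join(attrs[:-1]) + " and " + attrs[-1]
    return template.format(attrs=joined)


def generate_captions(species: list[SpeciesSpec], config: SynthConfig) -> list[CaptionSet]:
    """Per species, ``images_per_species`` images with noisy template captions."""
    rng = _streams(config)[1]
    caption_sets = []
    for sp in species:
        for img in range(config.images_per_species):
            image_id = f"{sp.class_id}-img{img}"
            caps = tuple(
                Caption.create(image_id, _render_caption(sp.signature, config, rng))
                for _ in range(config.captions_per_image)
            )
            caption_sets.append(CaptionSet(image_id=image_id, captions=caps,
                                           true_class_id=sp.class_id))
    return caption_sets


def _render_visual(sp: SpeciesSpec, part: str, config: SynthConfig,
                   rng: np.random.Generator) -> str:
    color = sp.signature[part]
    if config.jargon_rate > 0 and rng.random() < config.jargon_rate:
        jpart = JARGON_PARTS.get(part, part)
        jcolor = JARGON_COLORS.get(color, color)
        templates = (
            f"The {sp.name} displays a {jcolor} {jpart}.",
            f"In the {sp.name}, the {jpart} is {jcolor}.",
        )
    else:
        templates = (
            f"The {sp.name} has a {color} {part}.",
            f"Adults of the {sp.name} show a {color} {part}.",
        )
    return templates[int(rng.integers(0, len(templates)))]


def generate_documents(species: list[SpeciesSpec], config: SynthConfig) -> Corpus:
    """One expert article per species: visual sentences rendering the
    signature plus habitat/behaviour filler that carries no part or colour
    vocabulary.  Species names are left in place; mask with
    :meth:`fieldguide.corpus_io.Corpus.masked` before training or scoring."""
    rng = _streams(config)[2]
    docs = []
    for sp in species:
        n_filler = round(config.filler_fraction * config.doc_sentences)
        n_visual = config.doc_sentences - n_filler
        sentences: list[str] = []
        labels: list[str] = []
        for i in range(n_visual):
            part = config.parts[i % len(config.parts)]
            sentences.append(_render_visual(sp, part, config, rng))
            labels.append("identification")
        filler_order = rng.permutation(len(_FILLER_TEMPLATES))
        for i in range(n_filler):
            sentences.append(_FILLER_TEMPLATES[filler_order[i % len(_FILLER_TEMPLATES)]])
            labels.append("habitat")
        order = rng.permutation(len(sentences))
        docs.append(Document(
            class_id=sp.class_id,
            title=sp.name,
            sentences=tuple(sentences[i] for i in order),
            section_labels=tuple(labels[i] for i in order),
        ))
    return Corpus(documents=tuple(docs), mask_token="a bird")


def generate_benchmark(config: SynthConfig):
    """Build a self-consistent world: caption sets, masked corpus, truth.

    Returns ``(caption_sets, corpus, truth)`` where ``truth`` maps image id
    → class id and the corpus has all species names masked.
    """
    species = generate_species(config)
    caption_sets = generate_captions(species, config)
    corpus = generate_documents(species, config).masked([sp.name for sp in species])
    truth = {cs.image_id: cs.true_class_id for cs in caption_sets}
    return caption_sets, corpus, truth


def save_benchmark(config: SynthConfig, out_dir: str | Path) -> None:
    """Serialize a generated world: captions JSONL, corpus JSON, truth TSV,
    and a manifest recording the full config and seed."""
    from .corpus_io import save_corpus

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caption_sets, corpus, truth = generate_benchmark(config)
    with open(out / "captions.jsonl", "w", encoding="utf-8") as fh:
        for cs in caption_sets:
            for cap in cs.captions:
                fh.write(json.dumps({"image_id": cs.image_id, "text": cap.text,
                                     "class_id": cs.true_class_id}) + "\n")
    save_corpus(corpus, out / "corpus.json")
    with open(out / "truth.tsv", "w", encoding="utf-8") as fh:
        for image_id, class_id in truth.items():
            fh.write(f"{image_id}\t{class_id}\n")
    manifest = dataclasses.asdict(config)
    manifest["color_confusion"] = {k: dict(v) for k, v in config.color_confusion.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
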