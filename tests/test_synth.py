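import dataclasses
import json
import re

import numpy as np
import pytest

from fieldguide.corpus_io import extract_nouns
from fieldguide.synth import (
    JARGON_COLORS,
    JARGON_PARTS,
    SynthConfig,
    generate_benchmark,
    generate_captions,
    generate_documents,
    generate_species,
    save_benchmark,
)


def attribute_pairs(text: str, config: SynthConfig) -> set[tuple[str, str]]:
    """Brute-force (color, part) extractor: colour word immediately before a
    part noun, as the plain templates render them."""
    pairs = set()
    toks = re.findall(r"[a-z]+", text.lower())
    for a, b in zip(toks, toks[1:]):
        part = b[:-1] if b.endswith("s") else b
        if a in config.colors and part in config.parts:
            pairs.add((a, part))
    return pairs


class TestGenerateSpecies:
    def test_exhaustive_small_space(self):
        cfg = SynthConfig(K=4, parts=("wing", "tail"), colors=("red", "blue"),
                          parts_per_caption=1)
        species = generate_species(cfg)
        sigs = {tuple(sorted(sp.signature.items())) for sp in species}
        assert len(sigs) == 4  # all 2^2 signatures, each once

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            SynthConfig(K=5, parts=("wing", "tail"), colors=("red", "blue"),
                        parts_per_caption=1)

    def test_signatures_unique_and_reproducible(self):
        cfg = SynthConfig(K=20, seed=3)
        a, b = generate_species(cfg), generate_species(cfg)
        assert [sp.signature for sp in a] == [sp.signature for sp in b]
        assert len({tuple(sorted(sp.signature.items())) for sp in a}) == 20
        assert len({sp.name for sp in a}) == 20


class TestGenerateCaptions:
    def test_noise_free_captions_subset_of_signature(self):
        cfg = SynthConfig(K=8, seed=1).separable()
        species = generate_species(cfg)
        by_id = {sp.class_id: sp for sp in species}
        for cs in generate_captions(species, cfg):
            sig = by_id[cs.true_class_id].signature
            for cap in cs.captions:
                for color, part in attribute_pairs(cap.text, cfg):
                    assert sig[part] == color

    def test_total_confusion_removes_color(self):
        cfg = dataclasses.replace(
            SynthConfig(K=8, seed=1), attribute_dropout=0.0,
            color_confusion={"blue": {"black": 1.0}}, jargon_rate=0.0)
        species = generate_species(cfg)
        for cs in generate_captions(species, cfg):
            for cap in cs.captions:
                assert "blue" not in cap.text

    def test_confusion_rate_matches_probability(self):
        # species whose every part is blue; swap probability 0.3
        cfg = dataclasses.replace(
            SynthConfig(K=5, images_per_species=40, captions_per_image=5, seed=2),
            attribute_dropout=0.0, color_confusion={"blue": {"black": 0.3}},
            jargon_rate=0.0)
        species = generate_species(cfg)
        blue = dataclasses.replace(
            species[0], signature={p: "blue" for p in cfg.parts})
        sets = generate_captions([blue], cfg)
        n_blue = n_black = 0
        for cs in sets:
            for cap in cs.captions:
                n_blue += cap.text.count("blue")
                n_black += cap.text.count("black")
        n = n_blue + n_black
        rate = n_black / n
        # 3 sigma binomial tolerance
        assert abs(rate - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_shapes(self):
        cfg = SynthConfig(K=10, images_per_species=5, seed=0)
        sets = generate_captions(generate_species(cfg), cfg)
        assert len(sets) == 50
        assert all(len(cs.captions) == cfg.captions_per_image for cs in sets)


class TestGenerateDocuments:
    def test_filler_visual_split(self):
        cfg = dataclasses.replace(SynthConfig(K=4, seed=0),
                                  filler_fraction=0.5, doc_sentences=10)
        corpus = generate_documents(generate_species(cfg), cfg)
        for d in corpus.documents:
            assert len(d.sentences) == 10
            assert sum(l == "habitat" for l in d.section_labels) == 5
            assert sum(l == "identification" for l in d.section_labels) == 5

    def test_no_jargon_shares_surface_vocabulary(self):
        cfg = SynthConfig(K=4, seed=0).separable()
        species = generate_species(cfg)
        corpus = generate_documents(species, cfg)
        by_id = {sp.class_id: sp for sp in species}
        for d in corpus.documents:
            sig = by_id[d.class_id].signature
            vis = [s for s, l in zip(d.sentences, d.section_labels)
                   if l == "identification"]
            assert vis
            for s in vis:
                pairs = attribute_pairs(s, cfg)
                assert pairs and all(sig[p] == c for c, p in pairs)

    def test_masking_removes_species_names(self):
        cfg = SynthConfig(K=6, seed=4)
        species = generate_species(cfg)
        corpus = generate_documents(species, cfg).masked([sp.name for sp in species])
        for sp, d in zip(species, corpus.documents):
            for s in d.sentences:
                assert sp.name.lower() not in s.lower()

    def test_jargon_lexicon_injective(self):
        assert len(set(JARGON_PARTS.values())) == len(JARGON_PARTS)
        assert len(set(JARGON_COLORS.values())) == len(JARGON_COLORS)
        assert not set(JARGON_PARTS.values()) & set(JARGON_PARTS.keys())

    def test_filler_neutral_eligible_against_all_captions(self):
        cfg = SynthConfig(K=6, seed=5)
        caption_sets, corpus, _ = generate_benchmark(cfg)
        filler = [s for d in corpus.documents
                  for s, l in zip(d.sentences, d.section_labels) if l == "habitat"]
        assert filler
        for s in filler:
            sn = extract_nouns(s)
            for cs in caption_sets:
                for cap in cs.captions:
                    assert not (cap.nouns & sn), (cap.text, s)


class TestGenerateBenchmark:
    def test_world_shape_and_truth(self):
        cfg = SynthConfig(K=10, images_per_species=5, seed=0)
        caption_sets, corpus, truth = generate_benchmark(cfg)
        assert len(caption_sets) == 50
        assert corpus.n_classes == 10
        assert len(truth) == 50
        assert set(truth.values()) == set(corpus.class_ids)

    def test_separable_identifiability(self):
        """In the noise-free world the caption-set attribute multiset maps
        injectively onto species signatures."""
        cfg = SynthConfig(K=12, seed=6).separable()
        species = generate_species(cfg)
        sets = generate_captions(species, cfg)
        observed = {}
        for cs in sets:
            attrs = frozenset(p for cap in cs.captions
                              for p in attribute_pairs(cap.text, cfg))
            observed.setdefault(cs.true_class_id, set()).add(attrs)
        seen: dict[frozenset, str] = {}
        for cls, attr_sets in observed.items():
            for attrs in attr_sets:
                for other_cls, other in seen.items():
                    if other_cls != cls:
                        assert attrs != other
                seen.setdefault(cls, set())
        # and distinct species never produce identical full attribute sets
        full = {cls: frozenset().union(*sets_) for cls, sets_ in observed.items()}
        assert len(set(full.values())) == len(full)

    def test_separable_attribute_overlap_oracle_is_perfect(self):
        """A brute-force attribute matcher achieves 100% top-1 on the
        noise-free world (matching attributes, penalising contradictions)."""
        cfg = SynthConfig(K=12, seed=6).separable()
        caption_sets, corpus, truth = generate_benchmark(cfg)
        doc_attrs = {d.class_id: set().union(*(attribute_pairs(s, cfg)
                                               for s in d.sentences))
                     for d in corpus.documents}
        correct = 0
        for cs in caption_sets:
            cap_attrs = set().union(*(attribute_pairs(c.text, cfg)
                                      for c in cs.captions))
            def score(cls):
                match = len(cap_attrs & doc_attrs[cls])
                clash = sum(1 for c, p in cap_attrs
                            if (c, p) not in doc_attrs[cls]
                            and any(p2 == p for _, p2 in doc_attrs[cls]))
                return match - clash
            best = max(sorted(doc_attrs), key=score)
            correct += best == truth[cs.image_id]
        assert correct == len(caption_sets)

    def test_serialized_world_byte_identical_across_runs(self, tmp_path):
        cfg = SynthConfig(K=6, seed=9)
        save_benchmark(cfg, tmp_path / "w1")
        save_benchmark(cfg, tmp_path / "w2")
        for name in ("captions.jsonl", "corpus.json", "truth.tsv", "manifest.json"):
            assert (tmp_path / "w1" / name).read_bytes() == \
                   (tmp_path / "w2" / name).read_bytes()

    def test_manifest_records_config(self, tmp_path):
        cfg = SynthConfig(K=6, seed=9)
        save_benchmark(cfg, tmp_path / "w")
        manifest = json.loads((tmp_path / "w" / "manifest.json").read_text())
        assert manifest["K"] == 6 and manifest["seed"] == 9
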