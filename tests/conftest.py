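import numpy as np
import pytest

from fieldguide.corpus_io import Caption, CaptionSet, Corpus, Document
from fieldguide.encode import EncoderSpec
from fieldguide.synth import SynthConfig, generate_benchmark


@pytest.fixture(scope="session")
def spec():
    return EncoderSpec()


@pytest.fixture
def tiny_caption_sets():
    """Three images, hand-written captions with known noun structure."""
    def cs(image_id, texts, cls):
        return CaptionSet(image_id=image_id,
                          captions=tuple(Caption.create(image_id, t) for t in texts),
                          true_class_id=cls)
    return [
        cs("img1", ["this bird has blue wings and a red head",
                    "a bird with red head and blue wings",
                    "blue wings, red head"], "A"),
        cs("img2", ["this bird has a yellow belly",
                    "yellow belly and grey tail"], "B"),
        cs("img3", ["a green crown above a white throat"], "C"),
    ]


@pytest.fixture
def tiny_corpus():
    docs = (
        Document(class_id="A", title="Species A",
                 sentences=("The wings are blue.", "The head is red.",
                            "They eat seeds in winter."),
                 section_labels=("id", "id", "habitat")),
        Document(class_id="B", title="Species B",
                 sentences=("The belly is yellow.", "The tail is grey.",
                            "Migration occurs in spring."),
                 section_labels=("id", "id", "habitat")),
        Document(class_id="C", title="Species C",
                 sentences=("The crown is green.", "The throat is white."),
                 section_labels=("id", "id")),
    )
    return Corpus(documents=docs, mask_token="a bird")


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by the slower integration tests."""
    cfg = SynthConfig(K=10, images_per_species=3, captions_per_image=4, seed=7)
    caption_sets, corpus, truth = generate_benchmark(cfg)
    return cfg, caption_sets, corpus, truth
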