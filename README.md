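# fieldguide

Identify a fine-grained visual category — a bird or flower species —
from **free-text layperson descriptions**, by retrieving the matching
article from an expert corpus that contains exactly one document per
species.  No expert class labels are used at any point of training: the
supervision comes entirely from the fact that several people described
the same image.

The package is for researchers working on recognition-as-retrieval,
description-based identification, and text-side ablations of
caption-driven classifiers, and for anyone who needs a fully
reproducible, CPU-only testbed for such pipelines.

## The method

A trainable **fine-grained sentence matcher** scores whether two
sentences describe the same object.  With a frozen sentence encoder T
and a projection MLP φ, a pair (c, s) is scored by a linear head h over
the composite feature

    f(c, s) = h([φ(T(c)); φ(T(s)); |φ(T(c)) − φ(T(s))|]).

Training pairs are synthesised without labels: *positive* — two
descriptions of the same image; *negative* — descriptions of different
images; *neutral* — pairs sharing no noun (a caption and, e.g., a
habitat sentence), which lets the matcher absorb non-visual corpus
content.  The scalar pair score is `logit(positive) − logit(negative)`.

An image's score for document D_j is the mean over all caption ×
sentence pairs, `z_ij = mean f(c, s)`; a softmax over the corpus gives
the posterior `p(D_j | x_i)`, and the top-ranked document's class labels
the image.  A batch-level regularizer
`R(B) = Σ_x [−⟨p_x,p_x⟩ + Σ_{x'≠x} ⟨p_x,p_{x'}⟩]` can be added in the
second training stage to push posteriors toward confident, mutually
distinct assignments.  TF-IDF (word 2–3-grams, cosine), Okapi BM25 and
embedding-cosine ranking are included as baselines, and a synthetic
attribute world (species = colour-per-body-part signatures) makes the
whole pipeline testable offline.  See `docs/methods.md` for the full
model description, parameter choices, and two negative results measured
at small corpus scale.

## Worked example

```python
from fieldguide import SynthConfig, run_synthetic_experiment

world = SynthConfig(seed=0, parts_per_caption=3)   # 20 species, 5 images each,
result = run_synthetic_experiment(world, seed=0)   # 5 captions per image

for name in ("fgsm", "stage1", "stage2", "tfidf", "bm25", "cosine"):
    r = result.reports[name]
    print(f"{name:8s} top1={r.top1:5.1f}%  top5={r.top5:5.1f}%  MR={r.mean_rank:5.2f}")
```

prints

```
fgsm     top1= 56.0%  top5= 93.0%  MR= 2.18
stage1   top1= 58.0%  top5= 89.0%  MR= 2.38
stage2   top1= 57.0%  top5= 94.0%  MR= 2.52
tfidf    top1= 79.0%  top5= 99.0%  MR= 1.34
bm25     top1=  6.0%  top5= 23.0%  MR=10.77
cosine   top1= 50.0%  top5= 75.0%  MR= 4.00
```

Reading the numbers: with 20 species, random guessing gets 5% top-1 and
mean rank 10.5.  The matcher trained purely from caption co-occurrence
(`stage1`), its stage-2 retrain with the neutral class (`stage2`), and
their combined scorer (`fgsm`, the pipeline's final output) all recover
the species more than ten times better than chance from noisy,
three-attribute descriptions.  TF-IDF is the strongest lexical baseline
on this template world because attribute bigrams ("blue wing") are fully
discriminative there; BM25 collapses since its unigram scores are
swamped by shared vocabulary.

The same pipeline is scriptable from the shell:

```bash
fieldguide synth --out world/ --k 20 --seed 0
fieldguide train --captions world/captions.jsonl --corpus world/corpus.json \
                 --stage 1 --out model.npz
fieldguide rank  --captions world/captions.jsonl --corpus world/corpus.json \
                 --model model.npz --out rankings.tsv
fieldguide evaluate --rankings rankings.tsv --truth world/truth.tsv
```

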