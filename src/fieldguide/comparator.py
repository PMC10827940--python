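"""Fine-grained sentence matching (FGSM): the trainable comparator.

Two sentences are embedded by a frozen backend, projected by a small MLP
φ, composed as ``[φ1; φ2; |φ1 − φ2|]`` and classified by a linear head h
into match / mismatch (stage 1) or match / neutral / mismatch (stage 2).
The scalar retrieval score of a pair is ``logit(positive) −
logit(negative)``, which is invariant to shifting all logits and reduces
to the binary log-odds in the 2-class case.

Stage 1 trains φ and h on caption–caption pairs with softmax cross
entropy.  Stage 2 re-initialises φ and h (deeper projection, 3 classes)
and trains with cross entropy plus λ times a batch-level regularizer on
the per-image document posteriors, computed against the full corpus —
pulling each image's posterior toward one-hot and different images'
posteriors toward orthogonality.  Everything is plain numpy with Adam, so
runs are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .corpus_io import CaptionSet, Corpus
from .encode import EmbeddingCache, EncoderSpec, embed
from .pairs import PairDataset

__all__ = [
    "ComparatorConfig",
    "SentencePairClassifier",
    "RegContext",
    "project",
    "compose_features",
    "score_pair",
    "train_stage1",
    "train_stage2",
]

#: fixed class orders; the scalar score is logit(positive) − logit(negative)
LABELS_2 = ("negative", "positive")
LABELS_3 = ("negative", "neutral", "positive")


@dataclass(frozen=True)
class ComparatorConfig:
    """Hyper-parameters of one training stage.

    Defaults follow the reference setup: stage 1 projects through a
    two-layer MLP (256, 64) with a 2-class head; stage 2 re-trains from
    scratch with a three-layer MLP (256, 64, 32), a 3-class head and
    regularizer weight λ = 10.  The learning rate default (1e-5) suits
    large pretrained embeddings; small hash-feature worlds train with a
    larger rate passed explicitly.
    """

    stage: int = 1
    phi_dims: tuple[int, ...] | None = None
    head_classes: int | None = None
    lr: float = 1e-5
    lambda_reg: float = 0.0
    epochs: int = 20
    batch_size: int = 32
    images_per_batch: int = 8
    input_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")
        object.__setattr__(self, "phi_dims",
                           self.phi_dims or ((256, 64) if self.stage == 1 else (256, 64, 32)))
        object.__setattr__(self, "head_classes",
                           self.head_classes or (2 if self.stage == 1 else 3))
        if self.stage == 1 and self.head_classes != 2:
            raise ValueError("stage 1 uses a 2-class head")
        if self.stage == 2 and self.head_classes != 3:
            raise ValueError("stage 2 uses a 3-class head")


# ---------------------------------------------------------------------------
# numerics: MLP forward/backward, Adam
# ---------------------------------------------------------------------------

def _init_params(dims: Sequence[int], rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    # uniform fan-in scaling
    params = []
    for din, dout in zip(dims, dims[1:]):
        bound = 1.0 / np.sqrt(din)
        W = rng.uniform(-bound, bound, size=(din, dout))
        b = rng.uniform(-bound, bound, size=dout)
        params.append((W, b))
    return params


def _phi_forward(X: np.ndarray, params):
    """tanh on hidden layers, linear final layer; returns output + caches."""
    caches = []
    h = X
    for i, (W, b) in enumerate(params):
        z = h @ W + b
        if i < len(params) - 1:
            out = np.tanh(z)
        else:
            out = z
        caches.append((h, out, i < len(params) - 1))
        h = out
    return h, caches


def _phi_backward(dout, params, caches):
    grads = [None] * len(params)
    d = dout
    for i in reversed(range(len(params))):
        W, _ = params[i]
        h_in, out, is_tanh = caches[i]
        dz = d * (1.0 - out * out) if is_tanh else d
        grads[i] = (h_in.T @ dz, dz.sum(axis=0))
        d = dz @ W.T
    return d, grads


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params_flat, grads_flat):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params_flat, grads_flat)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------

def compose_features(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Pair feature ``[p1; p2; |p1 − p2|]`` (row-wise for 2-D inputs).

    The third block is symmetric under argument swap; the first two are
    not, so the full feature is order-sensitive by design.
    """
    p1, p2 = np.asarray(p1), np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError(f"projection shapes differ: {p1.shape} vs {p2.shape}")
    return np.concatenate([p1, p2, np.abs(p1 - p2)], axis=-1)


class RegContext:
    """Frozen-embedding context for the stage-2 regularizer.

    Holds the caption embeddings of the training images and every corpus
    sentence embedding, with the grouping needed to average pair scores
    into per-image, per-document scores against the *whole* corpus.
    """

    def __init__(self, caption_sets: Sequence[CaptionSet], corpus: Corpus,
                 caption_cache: EmbeddingCache, corpus_cache: EmbeddingCache):
        self.image_ids = [cs.image_id for cs in caption_sets]
        self.cap_embs = [caption_cache.vectors(cs.texts) for cs in caption_sets]
        self.S = np.vstack([corpus_cache.vectors(list(d.sentences)) for d in corpus.documents])
        sent_counts = [len(d.sentences) for d in corpus.documents]
        self.doc_slices = np.concatenate([[0], np.cumsum(sent_counts)])
        self.n_docs = corpus.n_classes

    @property
    def n_images(self) -> int:
        return len(self.cap_embs)


class SentencePairClassifier(BaseEstimator, ClassifierMixin):
    """Siamese sentence-pair classifier over precomputed embeddings.

    Parameters
    ----------
    phi_dims : output dimensions of the projection MLP φ (tanh hidden
        layers, linear final layer).
    n_classes : 2 (negative/positive) or 3 (negative/neutral/positive).
    lr : Adam learning rate for φ and h.
    lambda_reg : weight of the batch-level posterior regularizer; requires
        ``reg_context`` at fit time when positive.
    images_per_batch : images per regularizer batch B.
    """

    def __init__(self, phi_dims=(256, 64), n_classes=2, lr=1e-5, epochs=20,
                 batch_size=32, lambda_reg=0.0, images_per_batch=8,
                 input_dropout=0.0, average_last_epochs=0, seed=0):
        self.phi_dims = phi_dims
        self.n_classes = n_classes
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.lambda_reg = lambda_reg
        self.images_per_batch = images_per_batch
        self.input_dropout = input_dropout
        self.average_last_epochs = average_last_epochs
        self.seed = seed

    # -- parameter flattening ------------------------------------------------
    def _flat(self):
        flat = []
        for W, b in self.phi_params_:
            flat += [W, b]
        flat += [self.head_W_, self.head_b_]
        return flat

    def _unflat(self, flat):
        n = len(self.phi_params_)
        self.phi_params_ = [(flat[2 * i], flat[2 * i + 1]) for i in range(n)]
        self.head_W_, self.head_b_ = flat[2 * n], flat[2 * n + 1]

    # -- forward passes ------------------------------------------------------
    def _pair_logits(self, Xa, Xb, with_caches=False):
        Pa, ca = _phi_forward(Xa, self.phi_params_)
        Pb, cb = _phi_forward(Xb, self.phi_params_)
        F = compose_features(Pa, Pb)
        logits = F @ self.head_W_ + self.head_b_
        if with_caches:
            return logits, (Pa, Pb, F, ca, cb)
        return logits

    def _pair_backward(self, dlogits, fwd):
        """Gradients of a loss in the pair logits w.r.t. all parameters."""
        Pa, Pb, F, ca, cb = fwd
        dW_head = F.T @ dlogits
        db_head = dlogits.sum(axis=0)
        dF = dlogits @ self.head_W_.T
        d = Pa.shape[1]
        d1, d2, d3 = dF[:, :d], dF[:, d:2 * d], dF[:, 2 * d:]
        sign = np.sign(Pa - Pb)
        dPa = d1 + d3 * sign
        dPb = d2 - d3 * sign
        _, ga = _phi_backward(dPa, self.phi_params_, ca)
        _, gb = _phi_backward(dPb, self.phi_params_, cb)
        grads = []
        for (gWa, gba), (gWb, gbb) in zip(ga, gb):
            grads += [gWa + gWb, gba + gbb]
        grads += [dW_head, db_head]
        return grads

    # -- regularizer ---------------------------------------------------------
    def _reg_forward_backward(self, ctx: RegContext, image_idx: np.ndarray):
        """R(B) over the selected images against the full corpus, and its
        gradient w.r.t. all parameters (custom backward through the score
        averaging, the row softmax and the pairwise scoring head)."""
        A = np.vstack([ctx.cap_embs[i] for i in image_idx])
        cap_counts = np.array([ctx.cap_embs[i].shape[0] for i in image_idx])
        cap_slices = np.concatenate([[0], np.cumsum(cap_counts)])
        B, K = len(image_idx), ctx.n_docs

        Pa, ca = _phi_forward(A, self.phi_params_)
        Ps, cs = _phi_forward(ctx.S, self.phi_params_)
        d = Pa.shape[1]
        # scalar pair score s(c,s) = u·p1 + v·p2 + w·|p1−p2| + b0
        W, bvec = self.head_W_, self.head_b_
        ipos, ineg = self.n_classes - 1, 0
        u = W[:d, ipos] - W[:d, ineg]
        v = W[d:2 * d, ipos] - W[d:2 * d, ineg]
        w = W[2 * d:, ipos] - W[2 * d:, ineg]
        b0 = bvec[ipos] - bvec[ineg]

        diff = Pa[:, None, :] - Ps[None, :, :]
        absdiff = np.abs(diff)
        sc = Pa @ u + b0
        sc = sc[:, None] + Ps @ v + absdiff @ w  # (n_cap, n_sent)

        # average into z (B × K)
        z = np.empty((B, K))
        for bi in range(B):
            rows = sc[cap_slices[bi]:cap_slices[bi + 1]]
            for j in range(K):
                z[bi, j] = rows[:, ctx.doc_slices[j]:ctx.doc_slices[j + 1]].mean()
        P = _softmax(z)
        G = P @ P.T
        R = G.sum() - 2.0 * np.trace(G)

        # backward
        dP = 2.0 * P.sum(axis=0, keepdims=True) - 4.0 * P
        dz = P * (dP - (dP * P).sum(axis=1, keepdims=True))
        dsc = np.zeros_like(sc)
        for bi in range(B):
            nc = cap_counts[bi]
            for j in range(K):
                ns = ctx.doc_slices[j + 1] - ctx.doc_slices[j]
                dsc[cap_slices[bi]:cap_slices[bi + 1],
                    ctx.doc_slices[j]:ctx.doc_slices[j + 1]] = dz[bi, j] / (nc * ns)

        sgn = np.sign(diff)
        row_sum = dsc.sum(axis=1)
        col_sum = dsc.sum(axis=0)
        du = Pa.T @ row_sum
        dv = Ps.T @ col_sum
        dw = np.einsum("cs,csk->k", dsc, absdiff)
        db0 = dsc.sum()
        dPa = row_sum[:, None] * u + np.einsum("cs,csk->ck", dsc, sgn) * w
        dPs = col_sum[:, None] * v - np.einsum("cs,csk->sk", dsc, sgn) * w

        _, ga = _phi_backward(dPa, self.phi_params_, ca)
        _, gs = _phi_backward(dPs, self.phi_params_, cs)
        grads = []
        for (gWa, gba), (gWs, gbs) in zip(ga, gs):
            grads += [gWa + gWs, gba + gbs]
        dW_head = np.zeros_like(W)
        db_head = np.zeros_like(bvec)
        dW_head[:d, ipos] += du;   dW_head[:d, ineg] -= du
        dW_head[d:2 * d, ipos] += dv; dW_head[d:2 * d, ineg] -= dv
        dW_head[2 * d:, ipos] += dw;  dW_head[2 * d:, ineg] -= dw
        db_head[ipos] += db0; db_head[ineg] -= db0
        grads += [dW_head, db_head]
        return R, grads

    def objective(self, Xa, Xb, y_idx, ctx=None, image_idx=None):
        """Cross entropy (mean over pairs) + λ·R — used by gradient checks."""
        logits = self._pair_logits(Xa, Xb)
        P = _softmax(logits)
        ce = -np.mean(np.log(P[np.arange(len(y_idx)), y_idx] + 1e-300))
        if self.lambda_reg > 0 and ctx is not None:
            R, _ = self._reg_forward_backward(ctx, np.asarray(image_idx))
            return ce + self.lambda_reg * R
        return ce

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y, reg_context: RegContext | None = None):
        """Train φ and h from fresh initialisation.

        X : array (n_pairs, 2, dim) of embedded pairs; y : labels (strings
        from the fixed class order, or integer indices into it).
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != 2:
            raise ValueError(f"X must have shape (n, 2, dim), got {X.shape}")
        labels = LABELS_2 if self.n_classes == 2 else LABELS_3
        y_arr = np.asarray(y)
        if y_arr.dtype.kind in "iu":
            y_idx = y_arr.astype(int)
        else:
            unknown = set(map(str, y_arr)) - set(labels)
            if unknown:
                raise ValueError(f"labels {sorted(unknown)} invalid for a "
                                 f"{self.n_classes}-class comparator {labels}")
            lut = {l: i for i, l in enumerate(labels)}
            y_idx = np.array([lut[str(l)] for l in y_arr])
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")
        if self.lambda_reg > 0 and reg_context is None:
            raise ValueError("lambda_reg > 0 requires a reg_context "
                             "(precomputed caption and corpus embedding caches)")

        dim = X.shape[2]
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.array(labels)
        self.n_features_in_ = dim
        self.phi_params_ = _init_params([dim, *self.phi_dims], rng)
        head_rng_bound = 1.0 / np.sqrt(3 * self.phi_dims[-1])
        self.head_W_ = rng.uniform(-head_rng_bound, head_rng_bound,
                                   size=(3 * self.phi_dims[-1], self.n_classes))
        self.head_b_ = rng.uniform(-head_rng_bound, head_rng_bound, size=self.n_classes)

        opt = _Adam([p.shape for p in self._flat()], lr=self.lr)
        Xa_all, Xb_all = X[:, 0, :], X[:, 1, :]
        n = len(y_idx)
        self.loss_curve_ = []
        self.accuracy_curve_ = []
        swa_sum = None
        swa_count = 0
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            if reg_context is not None and self.lambda_reg > 0:
                img_order = rng.permutation(reg_context.n_images)
                img_pos = 0
            epoch_obj, epoch_correct = 0.0, 0
            n_steps = 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                Xa, Xb, yb = Xa_all[idx], Xb_all[idx], y_idx[idx]
                if self.input_dropout > 0:
                    # inverted dropout on the frozen embeddings (train only)
                    keep = 1.0 - self.input_dropout
                    Xa = Xa * rng.binomial(1, keep, size=Xa.shape) / keep
                    Xb = Xb * rng.binomial(1, keep, size=Xb.shape) / keep
                logits, fwd = self._pair_logits(Xa, Xb, with_caches=True)
                P = _softmax(logits)
                ce = -np.mean(np.log(P[np.arange(len(yb)), yb] + 1e-300))
                epoch_correct += int((logits.argmax(axis=1) == yb).sum())
                dlogits = P.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads = self._pair_backward(dlogits, fwd)
                obj = ce
                if reg_context is not None and self.lambda_reg > 0:
                    if img_pos >= reg_context.n_images:
                        img_order = rng.permutation(reg_context.n_images)
                        img_pos = 0
                    take = img_order[img_pos:img_pos + self.images_per_batch]
                    img_pos += self.images_per_batch
                    R, rgrads = self._reg_forward_backward(reg_context, take)
                    obj = ce + self.lambda_reg * R
                    grads = [g + self.lambda_reg * rg for g, rg in zip(grads, rgrads)]
                self._unflat(opt.step(self._flat(), grads))
                epoch_obj += obj
                n_steps += 1
            self.loss_curve_.append(epoch_obj / max(n_steps, 1))
            self.accuracy_curve_.append(epoch_correct / n)
            if (self.average_last_epochs > 0
                    and _epoch >= self.epochs - self.average_last_epochs):
                flat = self._flat()
                if swa_sum is None:
                    swa_sum = [p.copy() for p in flat]
                else:
                    for acc, p in zip(swa_sum, flat):
                        acc += p
                swa_count += 1
        if swa_count > 0:
            # tail weight averaging: flattens run-to-run optimisation noise
            self._unflat([p / swa_count for p in swa_sum])
        self.final_objective_ = self.loss_curve_[-1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Scalar pair score logit(positive) − logit(negative)."""
        X = np.asarray(X, dtype=np.float64)
        logits = self._pair_logits(X[:, 0, :], X[:, 1, :])
        return logits[:, self.n_classes - 1] - logits[:, 0]

    def predict_logits(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return self._pair_logits(X[:, 0, :], X[:, 1, :])

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.predict_logits(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_logits(X).argmax(axis=1)]

    def score_pairs(self, Pa_embs: np.ndarray, Pb_embs: np.ndarray) -> np.ndarray:
        """Pairwise score matrix (n_a × n_b) for all cross pairs; the first
        argument plays the caption role."""
        Pa, _ = _phi_forward(np.asarray(Pa_embs, dtype=np.float64), self.phi_params_)
        Ps, _ = _phi_forward(np.asarray(Pb_embs, dtype=np.float64), self.phi_params_)
        d = Pa.shape[1]
        W, b = self.head_W_, self.head_b_
        ipos, ineg = self.n_classes - 1, 0
        u = W[:d, ipos] - W[:d, ineg]
        v = W[d:2 * d, ipos] - W[d:2 * d, ineg]
        w = W[2 * d:, ipos] - W[2 * d:, ineg]
        b0 = b[ipos] - b[ineg]
        out = (Pa @ u + b0)[:, None] + (Ps @ v)[None, :]
        # chunk the |p1−p2| term to bound the (n_a, n_b, d) intermediate
        step = max(1, int(2_000_000 // max(Ps.shape[0] * d, 1)))
        for s in range(0, Pa.shape[0], step):
            out[s:s + step] += np.abs(Pa[s:s + step, None, :] - Ps[None, :, :]) @ w
        return out


def project(e: np.ndarray, model: SentencePairClassifier) -> np.ndarray:
    """φ(e): the comparator's projection of an embedding (vector or rows)."""
    e = np.asarray(e, dtype=np.float64)
    single = e.ndim == 1
    out, _ = _phi_forward(np.atleast_2d(e), model.phi_params_)
    return out[0] if single else out


def score_pair(text_a: str, text_b: str, model: SentencePairClassifier,
               cache: EmbeddingCache | None = None,
               spec: EncoderSpec | None = None) -> float:
    """Scalar compatibility of two sentences (caption first)."""
    if cache is not None:
        va, vb = cache.vector(text_a), cache.vector(text_b)
    elif spec is not None:
        va, vb = embed([text_a, text_b], spec)
    else:
        raise ValueError("provide an embedding cache or an encoder spec")
    X = np.stack([np.stack([va, vb])])
    return float(model.decision_function(X)[0])


def save_model(model: SentencePairClassifier, path) -> None:
    """Single-file checkpoint: weights + config + class order (.npz)."""
    import json as _json
    arrays = {}
    for i, (W, b) in enumerate(model.phi_params_):
        arrays[f"phi_W{i}"], arrays[f"phi_b{i}"] = W, b
    arrays["head_W"], arrays["head_b"] = model.head_W_, model.head_b_
    arrays["config"] = np.frombuffer(
        _json.dumps(model.get_params()).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> SentencePairClassifier:
    import json as _json
    with np.load(path) as data:
        params = _json.loads(bytes(data["config"]).decode("utf-8"))
        params["phi_dims"] = tuple(params["phi_dims"])
        model = SentencePairClassifier(**params)
        model.phi_params_ = []
        i = 0
        while f"phi_W{i}" in data:
            model.phi_params_.append((data[f"phi_W{i}"], data[f"phi_b{i}"]))
            i += 1
        model.head_W_, model.head_b_ = data["head_W"], data["head_b"]
    model.classes_ = np.array(LABELS_2 if model.n_classes == 2 else LABELS_3)
    model.n_features_in_ = model.phi_params_[0][0].shape[0]
    return model


# ---------------------------------------------------------------------------
# stage wrappers
# ---------------------------------------------------------------------------

def _pairs_to_arrays(dataset: PairDataset, cache: EmbeddingCache):
    Xa = cache.vectors([p.text_a for p in dataset.pairs])
    Xb = cache.vectors([p.text_b for p in dataset.pairs])
    y = np.array([p.label for p in dataset.pairs])
    return np.stack([Xa, Xb], axis=1), y


def _cache_for_pairs(dataset: PairDataset, spec: EncoderSpec) -> EmbeddingCache:
    texts = [p.text_a for p in dataset.pairs] + [p.text_b for p in dataset.pairs]
    return EmbeddingCache.build(texts, spec)


def train_stage1(dataset: PairDataset, spec: EncoderSpec,
                 config: ComparatorConfig | None = None) -> SentencePairClassifier:
    """Train the 2-class comparator on positive/negative caption pairs."""
    config = config or ComparatorConfig(stage=1)
    if config.stage != 1:
        raise ValueError("train_stage1 requires a stage-1 config")
    if any(p.label == "neutral" for p in dataset.pairs):
        raise ValueError("stage 1 is binary; dataset contains neutral pairs")
    cache = _cache_for_pairs(dataset, spec)
    X, y = _pairs_to_arrays(dataset, cache)
    model = SentencePairClassifier(
        phi_dims=config.phi_dims, n_classes=2, lr=config.lr, epochs=config.epochs,
        batch_size=config.batch_size, input_dropout=config.input_dropout,
        seed=config.seed)
    return model.fit(X, y)


def train_stage2(dataset: PairDataset, caption_sets: Sequence[CaptionSet],
                 corpus: Corpus, spec: EncoderSpec,
                 config: ComparatorConfig | None = None,
                 caption_cache: EmbeddingCache | None = None,
                 corpus_cache: EmbeddingCache | None = None) -> SentencePairClassifier:
    """Train the 3-class comparator from scratch with the λ·R(B) objective.

    Requires prebuilt embedding caches for the training captions and the
    full corpus (the encoder is frozen in this stage).
    """
    config = config or ComparatorConfig(stage=2, lambda_reg=10.0)
    if config.stage != 2:
        raise ValueError("train_stage2 requires a stage-2 config")
    if caption_cache is None or corpus_cache is None:
        raise ValueError("stage 2 requires prebuilt caption and corpus embedding caches")
    ctx = RegContext(caption_sets, corpus, caption_cache, corpus_cache)
    pair_cache = _cache_for_pairs(dataset, spec)
    X, y = _pairs_to_arrays(dataset, pair_cache)
    model = SentencePairClassifier(
        phi_dims=config.phi_dims, n_classes=3, lr=config.lr, epochs=config.epochs,
        batch_size=config.batch_size, lambda_reg=config.lambda_reg,
        images_per_batch=config.images_per_batch,
        input_dropout=config.input_dropout, seed=config.seed)
    return model.fit(X, y, reg_context=ctx)
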