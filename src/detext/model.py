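"""Convolutional per-read classifier with a signature prior.

The network scores a single candidate-supporting read as *true variant* vs
*false positive*.  Token indices from the difference encoding pass through a
small embedding (vocabulary 20, dimension 5), giving an input matrix
``A in R^(5 x 100)`` whose columns are positions along the read.  Three banks
of filters with region sizes (2, 3, 4) and full width 100 slide over the five
embedding rows; each filter output goes through ReLU and 1-max pooling,
yielding one feature per filter.  The pooled features, together with the
scaled mutational-signature prior of the candidate's trinucleotide class, form
the penultimate layer, which is regularized by dropout and an l2 max-norm
constraint on the softmax weights and mapped to two class probabilities.

Everything runs on CPU in numpy; gradients are hand-derived (the model has
~65k parameters) and optimized with Adam under cross-entropy loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import PAD_TOKEN, VOCAB_SIZE

__all__ = [
    "ModelConfig",
    "ModelParams",
    "TrainingExample",
    "TrainingHistory",
    "embed",
    "convolve",
    "feature_map",
    "max_pool",
    "forward",
    "constrain_norms",
    "init_params",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier and its training loop.

    The architecture defaults (region sizes 2/3/4, 100 feature maps per
    size, dropout 0.5, max-norm 3) are the baseline configuration; the
    optimizer settings (Adam, lr 1e-3, batch 64, patience 50) are this
    implementation's defaults and are freely configurable.
    """

    region_sizes: tuple[int, ...] = (2, 3, 4)
    feature_maps: int = 100
    embed_vocab: int = VOCAB_SIZE
    embed_dim: int = 5
    seq_len: int = 100
    dropout_rate: float = 0.5
    norm_constraint: float = 3.0
    ms_coefficient: float = 7.0
    max_iters: int = 2500
    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 50
    val_fraction: float = 0.1
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if any(h > self.embed_dim for h in self.region_sizes):
            raise ValueError(
                f"region sizes {self.region_sizes} must not exceed "
                f"embed_dim={self.embed_dim} (conv output would be empty)"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.norm_constraint <= 0:
            raise ValueError("norm_constraint must be > 0")
        if self.ms_coefficient < 0:
            raise ValueError("ms_coefficient must be >= 0")

    @property
    def n_pooled(self) -> int:
        return self.feature_maps * len(self.region_sizes)


@dataclass
class ModelParams:
    """Learned weights; shapes fixed by :class:`ModelConfig`."""

    embedding: np.ndarray  # (vocab, embed_dim)
    filters: dict[int, np.ndarray]  # h -> (feature_maps, h, seq_len)
    filter_biases: dict[int, np.ndarray]  # h -> (feature_maps,)
    out_weight: np.ndarray  # (2, n_pooled + 1)
    out_bias: np.ndarray  # (2,)

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.embedding.copy(),
            {h: w.copy() for h, w in self.filters.items()},
            {h: b.copy() for h, b in self.filter_biases.items()},
            self.out_weight.copy(),
            self.out_bias.copy(),
        )


@dataclass(frozen=True)
class TrainingExample:
    """One labeled candidate read: tokens, raw class prior, binary label."""

    tokens: tuple[int, ...]
    prior: float  # raw max signature probability (unscaled)
    label: int  # 1 = true variant, 0 = false positive


@dataclass
class TrainingHistory:
    """Per-iteration curves recorded during training."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    converged_at: int = 0


def init_params(config: ModelConfig, rng: np.random.Generator) -> ModelParams:
    """Gaussian-initialized parameters; the pad token's embedding starts at 0."""
    emb = rng.normal(0.0, 0.1, size=(config.embed_vocab, config.embed_dim))
    emb[PAD_TOKEN] = 0.0
    filters, biases = {}, {}
    for h in config.region_sizes:
        fan_in = h * config.seq_len
        filters[h] = rng.normal(
            0.0, 1.0 / np.sqrt(fan_in), size=(config.feature_maps, h, config.seq_len)
        )
        biases[h] = np.zeros(config.feature_maps)
    d = config.n_pooled + 1
    out_w = rng.normal(0.0, 1.0 / np.sqrt(d), size=(2, d))
    return ModelParams(emb, filters, biases, out_w, np.zeros(2))


# ---------------------------------------------------------------------------
# Primitive forward operations (also used directly by oracle tests)


def embed(tokens: Sequence[int], params: ModelParams) -> np.ndarray:
    """Input matrix A (embed_dim x seq_len); column j embeds token j."""
    idx = np.asarray(tokens, dtype=np.int64)
    if idx.min() < 0 or idx.max() >= params.embedding.shape[0]:
        raise ValueError(
            f"token index out of range [0, {params.embedding.shape[0]}): "
            f"{idx.min()}..{idx.max()}"
        )
    return params.embedding[idx].T


def convolve(A: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Slide a full-width filter over the embedding rows of A.

    ``A`` is (d x L), ``w`` is (h x L) with h <= d; output o has length
    d - h + 1 with ``o[i] = sum(w * A[i:i+h])`` (a plain dot product of the
    filter with each h-row submatrix).
    """
    d, L = A.shape
    h, Lw = w.shape
    if Lw != L:
        raise ValueError(f"filter width {Lw} != input width {L}")
    if h > d:
        raise ValueError(f"region size {h} exceeds input height {d}")
    return np.array([float(np.sum(w * A[i : i + h])) for i in range(d - h + 1)])


def feature_map(o: np.ndarray, b: float) -> np.ndarray:
    """ReLU feature map c_i = max(0, o_i + b)."""
    return np.maximum(0.0, np.asarray(o, dtype=float) + b)


def max_pool(c: np.ndarray) -> float:
    """1-max (max-over-time) pooling: the single largest activation."""
    c = np.asarray(c)
    if c.size == 0:
        raise ValueError("cannot max-pool an empty feature map")
    return float(c.max())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _conv_bank(A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Batched convolution: A (B,d,L), W (F,h,L) -> o (B,F,d-h+1)."""
    B, d, L = A.shape
    F, h, _ = W.shape
    n_out = d - h + 1
    Wf = W.reshape(F, h * L)
    o = np.empty((B, F, n_out))
    for i in range(n_out):
        o[:, :, i] = A[:, i : i + h, :].reshape(B, h * L) @ Wf.T
    return o


def _pooled_features(
    tokens: np.ndarray, params: ModelParams, config: ModelConfig
) -> tuple[np.ndarray, dict]:
    """Pooled conv features for a token batch, plus a cache for backprop."""
    A = params.embedding[tokens].transpose(0, 2, 1)  # (B, d, L)
    cache = {"A": A, "per_h": {}}
    pooled = []
    for h in config.region_sizes:
        o = _conv_bank(A, params.filters[h])
        c = np.maximum(0.0, o + params.filter_biases[h][None, :, None])
        arg = c.argmax(axis=2)
        pooled.append(np.take_along_axis(c, arg[:, :, None], axis=2)[:, :, 0])
        cache["per_h"][h] = {"o": o, "argmax": arg}
    return np.concatenate(pooled, axis=1), cache


def _penultimate(
    tokens: np.ndarray, priors: np.ndarray, params: ModelParams, config: ModelConfig
) -> tuple[np.ndarray, dict]:
    feats, cache = _pooled_features(tokens, params, config)
    prior_col = (config.ms_coefficient * priors)[:, None]
    return np.concatenate([feats, prior_col], axis=1), cache


def _forward_batch(
    tokens: np.ndarray,
    priors: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    train_mode: bool,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, dict]:
    z, cache = _penultimate(tokens, priors, params, config)
    keep = 1.0 - config.dropout_rate
    if train_mode and config.dropout_rate > 0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        mask = (rng.random(z.shape) < keep).astype(float)
        z_used = z * mask
        cache["dropout_mask"] = mask
        logits = z_used @ params.out_weight.T + params.out_bias
    else:
        # inference: dropout replaced by scaling the learned weights by the
        # retain probability, so expected pre-activations match training
        w_hat = params.out_weight * (keep if config.dropout_rate > 0 else 1.0)
        z_used = z
        logits = z @ w_hat.T + params.out_bias
    cache["z"] = z
    cache["z_used"] = z_used
    return _softmax(logits), cache


def forward(
    example: TrainingExample,
    params: ModelParams,
    config: ModelConfig,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class probabilities (p_false, p_true) for a single example."""
    tokens = np.asarray(example.tokens, dtype=np.int64)[None, :]
    priors = np.asarray([example.prior], dtype=float)
    probs, _ = _forward_batch(tokens, priors, params, config, train_mode, rng)
    return probs[0]


def constrain_norms(params: ModelParams, s: float) -> ModelParams:
    """Rescale each softmax weight row to l2 norm s whenever it exceeds s.

    Rows already within the ball are untouched; the operation is idempotent.
    Applied in place after every optimizer step.
    """
    if s <= 0:
        raise ValueError("norm constraint must be > 0")
    w = params.out_weight
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    scale = np.where(norms > s, s / np.maximum(norms, 1e-12), 1.0)
    params.out_weight = w * scale
    return params


# ---------------------------------------------------------------------------
# Training


def as_arrays(
    dataset,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize a dataset to (tokens, priors, labels) arrays.

    Accepts anything exposing ``tokens``/``priors``/``labels`` attributes
    (e.g. :class:`detext.simulate.LabeledDataset`) or an iterable of
    :class:`TrainingExample`.
    """
    if hasattr(dataset, "tokens") and hasattr(dataset, "labels"):
        return (
            np.asarray(dataset.tokens, dtype=np.int64),
            np.asarray(dataset.priors, dtype=float),
            np.asarray(dataset.labels, dtype=np.int64),
        )
    examples = list(dataset)
    return (
        np.array([e.tokens for e in examples], dtype=np.int64),
        np.array([e.prior for e in examples], dtype=float),
        np.array([e.label for e in examples], dtype=np.int64),
    )


def _backward(
    probs: np.ndarray,
    labels: np.ndarray,
    tokens: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    cache: dict,
) -> dict:
    B = len(labels)
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B

    grads = {
        "out_weight": dlogits.T @ cache["z_used"],
        "out_bias": dlogits.sum(axis=0),
    }
    dz = dlogits @ params.out_weight
    if "dropout_mask" in cache:
        dz = dz * cache["dropout_mask"]

    A = cache["A"]
    dA = np.zeros_like(A)
    offset = 0
    F = config.feature_maps
    B_, d, L = A.shape
    grads["filters"], grads["filter_biases"] = {}, {}
    for h in config.region_sizes:
        dpool = dz[:, offset : offset + F]  # (B, F)
        offset += F
        per = cache["per_h"][h]
        o, arg = per["o"], per["argmax"]
        n_out = o.shape[2]
        do = np.zeros_like(o)
        np.put_along_axis(do, arg[:, :, None], dpool[:, :, None], axis=2)
        active = (o + params.filter_biases[h][None, :, None]) > 0
        do *= active
        dW = np.zeros_like(params.filters[h])
        Wf = params.filters[h].reshape(F, h * L)
        for i in range(n_out):
            Ai = A[:, i : i + h, :].reshape(B_, h * L)  # (B, h*L)
            dW += (do[:, :, i].T @ Ai).reshape(F, h, L)
            dA[:, i : i + h, :] += (do[:, :, i] @ Wf).reshape(B_, h, L)
        grads["filters"][h] = dW
        grads["filter_biases"][h] = do.sum(axis=(0, 2))

    demb = np.zeros_like(params.embedding)
    np.add.at(demb, tokens, dA.transpose(0, 2, 1))
    demb[PAD_TOKEN] = 0.0  # pad stays a true zero vector
    grads["embedding"] = demb
    return grads


class _Adam:
    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            m = self.m.setdefault(k, np.zeros_like(g))
            v = self.v.setdefault(k, np.zeros_like(g))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            arrays[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _flat_arrays(params: ModelParams) -> dict[str, np.ndarray]:
    out = {"embedding": params.embedding, "out_weight": params.out_weight,
           "out_bias": params.out_bias}
    for h, w in params.filters.items():
        out[f"filters/{h}"] = w
        out[f"filter_biases/{h}"] = params.filter_biases[h]
    return out


def _flat_grads(grads: dict) -> dict[str, np.ndarray]:
    out = {"embedding": grads["embedding"], "out_weight": grads["out_weight"],
           "out_bias": grads["out_bias"]}
    for h, g in grads["filters"].items():
        out[f"filters/{h}"] = g
        out[f"filter_biases/{h}"] = grads["filter_biases"][h]
    return out


def _xent(probs: np.ndarray, labels: np.ndarray) -> float:
    p = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(p, 1e-12, None))))


def _stratified_holdout(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        k = max(1, int(round(fraction * len(idx))))
        val_idx.append(idx[:k])
        train_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train(
    dataset,
    config: ModelConfig,
) -> tuple[ModelParams, TrainingHistory]:
    """Fit the classifier by mini-batch Adam under cross-entropy.

    Dropout is applied to the penultimate layer on every step and the
    max-norm constraint is re-imposed on the softmax weight rows after every
    update.  A stratified holdout (``config.val_fraction``) drives early
    stopping: training stops when the holdout loss has not improved for
    ``config.patience`` iterations, or at ``config.max_iters``; the
    best-holdout parameters are returned.  Fully reproducible from
    ``config.seed``.
    """
    tokens, priors, labels = as_arrays(dataset)
    if len(tokens) == 0:
        raise ValueError("empty training set")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError(
            f"training set contains only class {classes.tolist()}; both the "
            "true-variant and false-positive class are required"
        )

    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)
    opt = _Adam(config.learning_rate)
    history = TrainingHistory()

    tr_idx, val_idx = _stratified_holdout(labels, config.val_fraction, rng)
    best_val, best_params, since_best = np.inf, params.copy(), 0

    for it in range(config.max_iters):
        batch = rng.choice(tr_idx, size=min(config.batch_size, len(tr_idx)),
                           replace=False)
        probs, cache = _forward_batch(
            tokens[batch], priors[batch], params, config, True, rng
        )
        grads = _backward(probs, labels[batch], tokens[batch], params, config, cache)
        opt.step(_flat_arrays(params), _flat_grads(grads))
        constrain_norms(params, config.norm_constraint)

        history.train_loss.append(_xent(probs, labels[batch]))
        history.train_acc.append(
            float(np.mean(probs.argmax(axis=1) == labels[batch]))
        )
        vprobs, _ = _forward_batch(
            tokens[val_idx], priors[val_idx], params, config, False, None
        )
        vloss = _xent(vprobs, labels[val_idx])
        history.val_loss.append(vloss)
        history.val_acc.append(
            float(np.mean(vprobs.argmax(axis=1) == labels[val_idx]))
        )
        if vloss < best_val - 1e-6:
            best_val, best_params, since_best = vloss, params.copy(), 0
        else:
            since_best += 1
            if config.patience and since_best >= config.patience:
                break
    history.converged_at = len(history.train_loss)
    return best_params, history


def predict(
    params: ModelParams,
    dataset,
    config: ModelConfig,
) -> np.ndarray:
    """Probability of *true variant* per example; deterministic (no dropout)."""
    tokens, priors, _labels = (
        as_arrays(dataset)
        if not isinstance(dataset, tuple)
        else (dataset[0], dataset[1], None)
    )
    out = np.empty(len(tokens))
    step = 1024
    for lo in range(0, len(tokens), step):
        probs, _ = _forward_batch(
            tokens[lo : lo + step], priors[lo : lo + step], params, config, False, None
        )
        out[lo : lo + step] = probs[:, 1]
    return out


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(
    path: str | Path, params: ModelParams, config: ModelConfig
) -> None:
    """Single-file archive of config + parameter arrays (versioned)."""
    arrays = {k.replace("/", "__"): v for k, v in _flat_arrays(params).items()}
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION, "config": asdict(config)}
    with open(path, "wb") as f:  # explicit handle: keep the exact filename
        np.savez(
            f,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('format_version')}"
            )
        cfg_dict = meta["config"]
        cfg_dict["region_sizes"] = tuple(cfg_dict["region_sizes"])
        config = ModelConfig(**cfg_dict)
        filters = {h: data[f"filters__{h}"] for h in config.region_sizes}
        fbias = {h: data[f"filter_biases__{h}"] for h in config.region_sizes}
        params = ModelParams(
            data["embedding"], filters, fbias, data["out_weight"], data["out_bias"]
        )
    return params, config
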