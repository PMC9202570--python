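"""TextCNN and multitask MT-CNN text classifiers, implemented in numpy.

The architecture is the standard convolutional text classifier: a learned
word-embedding table, parallel 1-D convolutions of several widths over
the embedded token sequence, global max-pooling of each filter's
activations, dropout, and a fully connected softmax decision layer. The
multitask variant (MT-CNN) shares the embedding and convolutional trunk
across tasks and attaches one softmax head per task, training on the sum
of per-task cross-entropies; with a single task it reduces exactly to
TextCNN.

Everything — initialization, batch shuffling, dropout — is driven by a
single seeded generator, so training and prediction are bit-reproducible
for identical (data, config, seed). The implementation is desk-scale: it
trains corpora of a few thousand short documents on one CPU core in
seconds, which is all the synthetic study requires.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Vocabulary",
    "TokenSequence",
    "CNNConfig",
    "TaskSpec",
    "TrainedClassifier",
    "build_vocabulary",
    "encode",
    "encode_batch",
    "train",
    "predict_proba",
    "predict_label",
]

PAD_INDEX = 0
UNK_INDEX = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


def _tokenize(text: str) -> list[str]:
    return text.lower().split()


@dataclass(frozen=True)
class Vocabulary:
    """Token-to-index map with reserved padding (0) and unknown (1) slots."""

    token_to_index: dict[str, int]
    min_frequency: int = 1

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length encoded document: indices padded beyond true_length."""

    indices: np.ndarray
    true_length: int


def build_vocabulary(
    texts: Iterable[str], min_frequency: int = 1
) -> Vocabulary:
    """Index every token with corpus frequency >= min_frequency.

    Ordering is frequency-descending with lexicographic tie-break, after
    the two reserved slots, so the map is deterministic.
    """
    counts: dict[str, int] = {}
    n_texts = 0
    for text in texts:
        n_texts += 1
        for tok in _tokenize(text):
            counts[tok] = counts.get(tok, 0) + 1
    if n_texts == 0:
        raise ValueError("empty corpus")
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_frequency),
        key=lambda t: (-counts[t], t),
    )
    mapping = {PAD_TOKEN: PAD_INDEX, UNK_TOKEN: UNK_INDEX}
    for i, tok in enumerate(kept, start=2):
        mapping[tok] = i
    return Vocabulary(mapping, min_frequency)


def encode(text: str, vocab: Vocabulary, max_len: int) -> TokenSequence:
    """Lowercase, split on whitespace, map to indices, pad/truncate."""
    toks = _tokenize(text)[:max_len]
    idx = np.full(max_len, PAD_INDEX, dtype=np.int32)
    for i, tok in enumerate(toks):
        idx[i] = vocab.index(tok)
    return TokenSequence(idx, len(toks))


def encode_batch(
    texts: Sequence[str], vocab: Vocabulary, max_len: int
) -> np.ndarray:
    """Encode many texts into an (n, max_len) int32 matrix."""
    out = np.full((len(texts), max_len), PAD_INDEX, dtype=np.int32)
    for r, text in enumerate(texts):
        toks = _tokenize(text)[:max_len]
        for i, tok in enumerate(toks):
            out[r, i] = vocab.index(tok)
    return out


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of the convolutional classifier."""

    embedding_dim: int = 64
    filter_widths: tuple[int, ...] = (3, 4, 5)
    filters_per_width: int = 64
    dropout: float = 0.5
    max_len: int = 256
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    min_frequency: int = 1

    def __post_init__(self) -> None:
        if self.embedding_dim <= 0 or self.filters_per_width <= 0:
            raise ValueError("embedding_dim and filters_per_width must be > 0")
        if not self.filter_widths or any(w <= 0 for w in self.filter_widths):
            raise ValueError("filter widths must be positive")
        if any(w >= self.max_len for w in self.filter_widths):
            raise ValueError("filter widths must be smaller than max_len")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be > 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        object.__setattr__(self, "filter_widths", tuple(self.filter_widths))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter_widths"] = list(self.filter_widths)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CNNConfig":
        d = dict(d)
        if "filter_widths" in d:
            d["filter_widths"] = tuple(d["filter_widths"])
        return cls(**d)


@dataclass(frozen=True)
class TaskSpec:
    """One classification task: a name and its ordered label space."""

    task_name: str
    label_space: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.label_space)
        if len(labels) < 2:
            raise ValueError(
                f"task {self.task_name!r} needs >= 2 classes, "
                f"got {len(labels)}"
            )
        if len(set(labels)) != len(labels):
            raise ValueError(f"task {self.task_name!r} has duplicate labels")
        object.__setattr__(self, "label_space", labels)

    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.label_space)}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            params[k] -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _init_params(
    vocab_size: int, config: CNNConfig, tasks: Sequence[TaskSpec],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    D = config.embedding_dim
    F = config.filters_per_width
    params: dict[str, np.ndarray] = {
        "E": rng.normal(0.0, 0.1, size=(vocab_size, D))
    }
    params["E"][PAD_INDEX] = 0.0
    for w in config.filter_widths:
        fan_in, fan_out = w * D, F
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        params[f"W{w}"] = rng.uniform(-bound, bound, size=(w * D, F))
        params[f"b{w}"] = np.zeros(F)
    H = F * len(config.filter_widths)
    for t, task in enumerate(tasks):
        C = len(task.label_space)
        bound = np.sqrt(6.0 / (H + C))
        params[f"U{t}"] = rng.uniform(-bound, bound, size=(H, C))
        params[f"c{t}"] = np.zeros(C)
    return params


def _forward_features(
    params: Mapping[str, np.ndarray], X: np.ndarray, config: CNNConfig
) -> tuple[np.ndarray, dict]:
    """Embed, convolve, relu, global-max-pool. Returns (features, cache)."""
    emb = params["E"][X]  # (B, L, D)
    B, L, D = emb.shape
    feats = []
    cache: dict = {"emb": emb, "X": X, "widths": {}}
    for w in config.filter_widths:
        P = L - w + 1
        # width-w convolution as a sum of per-offset matmuls
        W = params[f"W{w}"].reshape(w, D, -1)
        Z = np.broadcast_to(params[f"b{w}"], (B, P, W.shape[2])).copy()
        for j in range(w):
            Z += emb[:, j:j + P, :] @ W[j]
        A = np.maximum(Z, 0.0)
        pooled = A.max(axis=1)  # (B, F)
        argmax = A.argmax(axis=1)  # (B, F)
        feats.append(pooled)
        cache["widths"][w] = (Z, argmax)
    return np.concatenate(feats, axis=1), cache


def _backward(
    params: Mapping[str, np.ndarray],
    cache: dict,
    dH: np.ndarray,
    config: CNNConfig,
) -> dict[str, np.ndarray]:
    """Backpropagate a gradient on the pooled feature vector."""
    grads: dict[str, np.ndarray] = {}
    X = cache["X"]
    emb = cache["emb"]
    B, L = X.shape
    D = config.embedding_dim
    F = config.filters_per_width
    dEmb = np.zeros((B, L, D))
    for wi, w in enumerate(config.filter_widths):
        Z, argmax = cache["widths"][w]
        P = Z.shape[1]
        dPool = dH[:, wi * F:(wi + 1) * F]  # (B, F)
        dZ = np.zeros_like(Z)
        np.put_along_axis(
            dZ, argmax[:, None, :], (dPool * (np.take_along_axis(
                Z, argmax[:, None, :], axis=1
            ).squeeze(1) > 0))[:, None, :], axis=1,
        )
        W = params[f"W{w}"].reshape(w, D, F)
        dW = np.empty_like(W)
        dZ_flat = dZ.reshape(B * P, F)
        for j in range(w):
            dW[j] = emb[:, j:j + P, :].reshape(B * P, D).T @ dZ_flat
            dEmb[:, j:j + P, :] += dZ @ W[j].T
        grads[f"W{w}"] = dW.reshape(w * D, F)
        grads[f"b{w}"] = dZ.sum(axis=(0, 1))
    dE = np.zeros_like(params["E"])
    np.add.at(dE, X.ravel(), dEmb.reshape(-1, D))
    dE[PAD_INDEX] = 0.0
    grads["E"] = dE
    return grads


@dataclass
class TrainedClassifier:
    """A trained (MT-)CNN: parameters, vocabulary, config, task specs."""

    params: dict[str, np.ndarray]
    vocab: Vocabulary
    config: CNNConfig
    tasks: tuple[TaskSpec, ...]

    CHECKPOINT_VERSION = 1

    @property
    def is_multitask(self) -> bool:
        return len(self.tasks) > 1

    def predict_proba_batch(self, texts: Sequence[str]) -> list[np.ndarray]:
        """Per-task (n, n_classes) softmax probability matrices."""
        X = encode_batch(texts, self.vocab, self.config.max_len)
        outs = [
            np.empty((len(texts), len(task.label_space)))
            for task in self.tasks
        ]
        for start in range(0, len(texts), 512):
            sl = slice(start, start + 512)
            H, _ = _forward_features(self.params, X[sl], self.config)
            for t in range(len(self.tasks)):
                logits = H @ self.params[f"U{t}"] + self.params[f"c{t}"]
                outs[t][sl] = _softmax(logits)
        return outs

    def predict_label_batch(self, texts: Sequence[str]) -> list[list[str]]:
        out = []
        for task, probs in zip(self.tasks, self.predict_proba_batch(texts)):
            idx = probs.argmax(axis=1)  # ties -> lowest class index
            out.append([task.label_space[i] for i in idx])
        return out

    def save(self, path: str | Path) -> None:
        meta = {
            "version": self.CHECKPOINT_VERSION,
            "vocab": self.vocab.token_to_index,
            "min_frequency": self.vocab.min_frequency,
            "config": self.config.to_dict(),
            "tasks": [
                {"task_name": t.task_name, "label_space": list(t.label_space)}
                for t in self.tasks
            ],
        }
        arrays = {k: v for k, v in self.params.items()}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("version") != cls.CHECKPOINT_VERSION:
                raise ValueError("unsupported checkpoint version")
            params = {
                k: data[k] for k in data.files if k != "__meta__"
            }
        return cls(
            params=params,
            vocab=Vocabulary(meta["vocab"], meta["min_frequency"]),
            config=CNNConfig.from_dict(meta["config"]),
            tasks=tuple(
                TaskSpec(t["task_name"], tuple(t["label_space"]))
                for t in meta["tasks"]
            ),
        )


def _resolve_tasks(
    frame: pd.DataFrame, label_columns: Sequence[str]
) -> list[TaskSpec]:
    tasks = []
    for col in label_columns:
        labels = tuple(sorted(set(str(v) for v in frame[col])))
        tasks.append(TaskSpec(col, labels))  # raises if < 2 classes
    return tasks


def train(
    frame: pd.DataFrame,
    label_columns: str | Sequence[str],
    config: CNNConfig | None = None,
) -> TrainedClassifier:
    """Train a TextCNN (one label column) or MT-CNN (several).

    ``frame`` must have a ``text`` column plus the label column(s); every
    row needs a label for every task. The loss is the sum of per-task
    cross-entropies. Deterministic for identical (data, config, seed).
    """
    config = config if config is not None else CNNConfig()
    if isinstance(label_columns, str):
        label_columns = [label_columns]
    if len(frame) == 0:
        raise ValueError("empty training set")
    tasks = _resolve_tasks(frame, label_columns)
    texts = frame["text"].tolist()
    vocab = build_vocabulary(texts, config.min_frequency)
    X = encode_batch(texts, vocab, config.max_len)
    Y = [
        np.array([task.label_index()[str(v)] for v in frame[task.task_name]])
        for task in tasks
    ]
    rng = np.random.default_rng(config.seed)
    params = _init_params(len(vocab), config, tasks, rng)
    opt = _Adam(params, config.learning_rate)
    n = len(frame)
    keep = 1.0 - config.dropout
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            B = len(batch)
            H, cache = _forward_features(params, X[batch], config)
            if config.dropout > 0:
                mask = (rng.random(H.shape) < keep) / keep
                Hd = H * mask
            else:
                mask = None
                Hd = H
            grads: dict[str, np.ndarray] = {}
            dHd = np.zeros_like(H)
            for t, task in enumerate(tasks):
                logits = Hd @ params[f"U{t}"] + params[f"c{t}"]
                probs = _softmax(logits)
                probs[np.arange(B), Y[t][batch]] -= 1.0
                dlogits = probs / B
                grads[f"U{t}"] = Hd.T @ dlogits
                grads[f"c{t}"] = dlogits.sum(axis=0)
                dHd += dlogits @ params[f"U{t}"].T
            dH = dHd * mask if mask is not None else dHd
            grads.update(_backward(params, cache, dH, config))
            opt.step(params, grads)
            params["E"][PAD_INDEX] = 0.0
    return TrainedClassifier(params, vocab, config, tuple(tasks))


def predict_proba(
    clf: TrainedClassifier, text: str
) -> list[np.ndarray]:
    """Softmax probability vector for one document, one per task."""
    return [p[0] for p in clf.predict_proba_batch([text])]


def predict_label(clf: TrainedClassifier, text: str) -> list[str]:
    """Argmax class code per task; ties break to the lowest class index."""
    return [labels[0] for labels in clf.predict_label_batch([text])]
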