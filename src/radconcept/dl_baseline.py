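"""Bidirectional-LSTM report classifiers, implemented in NumPy.

Two architectures are provided, mirroring a Keras layer-count convention:

* ``simple`` — 5 layers: embedding, two stacked bidirectional LSTM layers,
  one dense layer, sigmoid output.  No dropout.
* ``dropout`` — 13 layers: the same recurrent trunk interleaved with six
  dropout layers and three intermediate dense layers before the output.

No deep-learning framework is assumed: forward and backward passes
(truncated-nowhere BPTT over the padded sequence) are written against NumPy
and trained with Adam on the binary cross-entropy.  Analytic gradients are
verified against finite differences in the test suite.

Padding uses index 0; out-of-vocabulary tokens map to index 1.  As with the
Keras default (``mask_zero=False``) the recurrence runs over padding steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ModelStateError, ParameterError
from .evaluation import MetricSet, confusion, metrics

PAD_INDEX = 0
OOV_INDEX = 1


# --------------------------------------------------------------------------
# corpus encoding
# --------------------------------------------------------------------------

@dataclass
class SequenceBatch:
    """Padded integer sequences plus binary targets and the vocabulary used."""

    sequences: np.ndarray  # [N, T] int
    targets: np.ndarray  # [N] in {0,1}
    vocab: dict[str, int]
    max_len: int

    def __post_init__(self) -> None:
        if self.sequences.size and self.sequences.max() >= len(self.vocab) + 2:
            raise ValueError("token index exceeds vocabulary size")


def build_vocab(texts: Sequence[str], vocab_size: int) -> dict[str, int]:
    """Most frequent ``vocab_size`` tokens -> indices starting at 2."""
    from collections import Counter

    counts = Counter(tok for text in texts for tok in text.split())
    most = [tok for tok, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return {tok: i + 2 for i, tok in enumerate(most[:vocab_size])}


def encode_with_vocab(texts: Sequence[str], vocab: dict[str, int], max_len: int) -> np.ndarray:
    if max_len < 1:
        raise ParameterError("max_len must be >= 1")
    out = np.full((len(texts), max_len), PAD_INDEX, dtype=np.int64)
    for i, text in enumerate(texts):
        toks = text.split()[:max_len]
        for j, tok in enumerate(toks):
            out[i, j] = vocab.get(tok, OOV_INDEX)
    return out


def encode_corpus(
    texts: Sequence[str],
    targets: Sequence[int] | None = None,
    max_len: int = 100,
    vocab_size: int = 5000,
) -> SequenceBatch:
    """Build the vocabulary from ``texts`` and encode them (training-side op)."""
    vocab = build_vocab(texts, vocab_size)
    seqs = encode_with_vocab(texts, vocab, max_len)
    y = np.zeros(len(texts), dtype=np.int64) if targets is None else np.asarray(targets, dtype=np.int64)
    return SequenceBatch(sequences=seqs, targets=y, vocab=vocab, max_len=max_len)


def decode_sequence(seq: np.ndarray, vocab: dict[str, int]) -> list[str]:
    """Inverse of encoding for in-vocabulary tokens (pad dropped, OOV marked)."""
    inv = {i: tok for tok, i in vocab.items()}
    out = []
    for idx in seq:
        if idx == PAD_INDEX:
            continue
        out.append(inv.get(int(idx), "<oov>"))
    return out


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
                    np.exp(np.clip(x, -500, 500)) / (1.0 + np.exp(np.clip(x, -500, 500))))


class Embedding:
    name = "embedding"

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.E = rng.normal(0, 0.1, size=(vocab_size, dim))
        self.dE = np.zeros_like(self.E)

    def forward(self, idx: np.ndarray, train: bool) -> np.ndarray:
        self._idx = idx
        return self.E[idx]

    def backward(self, dout: np.ndarray) -> None:
        self.dE[...] = 0.0
        np.add.at(self.dE, self._idx, dout)
        return None  # nothing upstream

    def params(self):
        return {"E": (self.E, self.dE)}


class Dropout:
    name = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return {}


class _LstmDirection:
    """One LSTM direction; gate order [i, f, o, g]."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(in_dim + hidden)
        self.Wx = rng.normal(0, scale, size=(in_dim, 4 * hidden))
        self.Wh = rng.normal(0, scale, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.hidden = hidden
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        out = np.empty((B, T, H))
        self._X = X
        for t in range(T):
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            o = _sigmoid(z[:, 2 * H : 3 * H])
            g = np.tanh(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            self._cache.append((h, c, i, f, o, g, c_new))
            h, c = h_new, c_new
            out[:, t] = h
        return out

    def backward(self, dH_seq: np.ndarray) -> np.ndarray:
        X = self._X
        B, T, _ = X.shape
        H = self.hidden
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, o, g, c_new = self._cache[t]
            dh = dH_seq[:, t] + dh_next
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g**2),
                ],
                axis=1,
            )
            self.dWx += X[:, t].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dX[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dX


class BiLstm:
    """Bidirectional LSTM; returns the full sequence or a pooled final vector.

    Pooling concatenates the forward direction's last hidden state with the
    backward direction's state at the first time step (its own "last").
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, pool_final: bool):
        self.fwd = _LstmDirection(in_dim, hidden, rng)
        self.bwd = _LstmDirection(in_dim, hidden, rng)
        self.hidden = hidden
        self.pool_final = pool_final
        self.name = "bilstm"

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        Hf = self.fwd.forward(X)
        Hb = self.bwd.forward(X[:, ::-1])[:, ::-1]  # back to original order
        self._T = X.shape[1]
        if self.pool_final:
            return np.concatenate([Hf[:, -1], Hb[:, 0]], axis=1)
        return np.concatenate([Hf, Hb], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.hidden
        if self.pool_final:
            B = dout.shape[0]
            dHf = np.zeros((B, self._T, H))
            dHb = np.zeros((B, self._T, H))
            dHf[:, -1] = dout[:, :H]
            dHb[:, 0] = dout[:, H:]
        else:
            dHf = dout[:, :, :H]
            dHb = dout[:, :, H:]
        dXf = self.fwd.backward(dHf)
        dXb = self.bwd.backward(dHb[:, ::-1])[:, ::-1]
        return dXf + dXb

    def params(self):
        out = {}
        for tag, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            out[f"{tag}_Wx"] = (d.Wx, d.dWx)
            out[f"{tag}_Wh"] = (d.Wh, d.dWh)
            out[f"{tag}_b"] = (d.b, d.db)
        return out


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, relu: bool, name: str = "dense"):
        self.W = rng.normal(0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.relu = relu
        self.name = name
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return {"W": (self.W, self.dW), "b": (self.b, self.db)}


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass
class BilstmSpec:
    """Architecture + training hyperparameters."""

    architecture: str = "simple"  # "simple" (5 layers) or "dropout" (13 layers)
    embedding_dim: int = 32
    hidden_size: int = 16
    seq_len: int = 100
    vocab_size: int = 5000
    epochs: int = 20
    learning_rate: float = 0.01
    batch_size: int = 16
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("simple", "dropout"):
            raise ParameterError(f"unknown architecture {self.architecture!r}")
        if self.seq_len < 1:
            raise ParameterError("seq_len must be >= 1")

    @property
    def n_layers(self) -> int:
        return 5 if self.architecture == "simple" else 13


class BilstmClassifier:
    """Binary sequence classifier assembled from the layers above."""

    def __init__(self, spec: BilstmSpec, vocab_size: int):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        D, H = spec.embedding_dim, spec.hidden_size
        V = vocab_size + 2  # + pad, oov
        r = self.rng
        if spec.architecture == "simple":
            self.layers = [
                Embedding(V, D, r),
                BiLstm(D, H, r, pool_final=False),
                BiLstm(2 * H, H, r, pool_final=True),
                Dense(2 * H, H, r, relu=True, name="dense"),
                Dense(H, 1, r, relu=False, name="output"),
            ]
        else:
            p = spec.dropout_rate
            self.layers = [
                Embedding(V, D, r),
                Dropout(p, r),
                BiLstm(D, H, r, pool_final=False),
                Dropout(p, r),
                BiLstm(2 * H, H, r, pool_final=True),
                Dropout(p, r),
                Dense(2 * H, H, r, relu=True, name="dense_1"),
                Dropout(p, r),
                Dense(H, H, r, relu=True, name="dense_2"),
                Dropout(p, r),
                Dense(H, H, r, relu=True, name="dense_3"),
                Dropout(p, r),
                Dense(H, 1, r, relu=False, name="output"),
            ]
        self._adam: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self._adam_t = 0
        self.trained = False
        self.history: list[dict] = []

    # -- introspection ----------------------------------------------------
    def summary(self) -> list[str]:
        return [layer.name for layer in self.layers]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    # -- forward / backward ----------------------------------------------
    def _forward(self, idx: np.ndarray, train: bool) -> np.ndarray:
        x = idx
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]  # logits

    def _backward(self, dlogit: np.ndarray) -> None:
        grad = dlogit[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def _adam_step(self, lr: float) -> None:
        self._adam_t += 1
        t = self._adam_t
        b1, b2, eps = 0.9, 0.999, 1e-8
        for li, layer in enumerate(self.layers):
            for name, (param, grad) in layer.params().items():
                key = (li, name)
                if key not in self._adam:
                    self._adam[key] = (np.zeros_like(param), np.zeros_like(param))
                m, v = self._adam[key]
                m[...] = b1 * m + (1 - b1) * grad
                v[...] = b2 * v + (1 - b2) * grad**2
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training ---------------------------------------------------------
    def fit(self, sequences: np.ndarray, y: np.ndarray) -> "BilstmClassifier":
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("training split must contain both classes")
        n = len(y)
        order_rng = np.random.default_rng(self.spec.seed + 1)
        for epoch in range(self.spec.epochs):
            order = order_rng.permutation(n)
            losses = []
            correct = 0
            for start in range(0, n, self.spec.batch_size):
                sel = order[start : start + self.spec.batch_size]
                logits = self._forward(sequences[sel], train=True)
                p = _sigmoid(logits)
                eps = 1e-12
                losses.append(
                    float(-np.mean(y[sel] * np.log(p + eps) + (1 - y[sel]) * np.log(1 - p + eps)))
                )
                correct += int(np.sum((p >= 0.5) == (y[sel] == 1)))
                self._backward((p - y[sel]) / len(sel))
                self._adam_step(self.spec.learning_rate)
            self.history.append(
                {"epoch": epoch, "loss": float(np.mean(losses)), "train_accuracy": correct / n}
            )
        self.trained = True
        return self

    def predict_proba(self, sequences: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise ModelStateError("classifier has not been fit")
        out = []
        for start in range(0, len(sequences), 256):
            out.append(_sigmoid(self._forward(sequences[start : start + 256], train=False)))
        return np.concatenate(out) if out else np.empty(0)

    def predict(self, sequences: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(sequences) >= threshold).astype(int)


# --------------------------------------------------------------------------
# training drivers
# --------------------------------------------------------------------------

def stratified_split(
    y: Sequence[int], test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified index split (train, test)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


@dataclass
class TrainResult:
    model: BilstmClassifier
    vocab: dict[str, int]
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_scores: np.ndarray
    test_metrics: MetricSet
    log: dict = field(default_factory=dict)


def train_bilstm(
    texts: Sequence[str], labels: Sequence[int], spec: BilstmSpec, test_fraction: float = 0.3
) -> TrainResult:
    """Stratified 70:30 split, vocabulary from the training side only."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    train_idx, test_idx = stratified_split(y, test_fraction, spec.seed)
    train_texts = [texts[i] for i in train_idx]
    vocab = build_vocab(train_texts, spec.vocab_size)
    Xtr = encode_with_vocab(train_texts, vocab, spec.seq_len)
    Xte = encode_with_vocab([texts[i] for i in test_idx], vocab, spec.seq_len)
    model = BilstmClassifier(spec, vocab_size=len(vocab)).fit(Xtr, y[train_idx])
    scores = model.predict_proba(Xte)
    pred = (scores >= 0.5).astype(int)
    return TrainResult(
        model=model,
        vocab=vocab,
        train_idx=train_idx,
        test_idx=test_idx,
        test_scores=scores,
        test_metrics=metrics(confusion(y[test_idx], pred)),
        log={"seed": spec.seed, "note": "deterministic NumPy backend"},
    )


@dataclass
class CrossvalResult:
    fold_metrics: list[MetricSet]
    fold_predictions: list[np.ndarray]
    fold_truths: list[np.ndarray]
    fold_test_indices: list[np.ndarray]
    mean: dict[str, float | None]
    sd: dict[str, float | None]


def crossval_bilstm(
    texts: Sequence[str], labels: Sequence[int], spec: BilstmSpec, k: int = 5
) -> CrossvalResult:
    """Stratified k-fold cross-validation; metrics via the evaluation module."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    fold_metrics, fold_preds, fold_truths, fold_tests = [], [], [], []
    for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_texts = [texts[i] for i in tr]
        vocab = build_vocab(train_texts, spec.vocab_size)
        Xtr = encode_with_vocab(train_texts, vocab, spec.seq_len)
        Xte = encode_with_vocab([texts[i] for i in te], vocab, spec.seq_len)
        fold_spec = BilstmSpec(**{**spec.__dict__, "seed": spec.seed + fold_i})
        model = BilstmClassifier(fold_spec, vocab_size=len(vocab)).fit(Xtr, y[tr])
        pred = model.predict(Xte)
        fold_metrics.append(metrics(confusion(y[te], pred)))
        fold_preds.append(pred)
        fold_truths.append(y[te])
        fold_tests.append(te)
    mean, sd = {}, {}
    for name in ("sensitivity", "ppv", "npv", "f1", "accuracy"):
        vals = [getattr(m, name) for m in fold_metrics if getattr(m, name) is not None]
        mean[name] = float(np.mean(vals)) if vals else None
        sd[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return CrossvalResult(
        fold_metrics=fold_metrics,
        fold_predictions=fold_preds,
        fold_truths=fold_truths,
        fold_test_indices=fold_tests,
        mean=mean,
        sd=sd,
    )
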