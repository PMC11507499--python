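"""Client model zoo under a uniform functional contract.

Two model families cover the experiments: multinomial (softmax) logistic
regression for the tabular synthetic benchmarks, and a single-layer LSTM text
classifier (embedding -> LSTM -> last-unmasked hidden state -> dense softmax)
for sentence-level symptom classification.  Both expose the same four
operations — ``init_params``, ``loss_and_grad``, ``predict``, ``accuracy`` —
so the federated loop never branches on architecture.

The loss is always the mean cross-entropy (negative log-probability of the
true label) over the batch.  Gradients are exact: closed form for the
logistic model, hand-written backpropagation-through-time for the LSTM; both
are validated against central finite differences in the test suite.

Token index 0 is reserved for padding.  Padded positions are masked out of
the recurrence (hidden and cell states carry through unchanged), so appending
padding beyond the true sequence length never changes the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .params import ModelParams

__all__ = [
    "ModelSpec",
    "Batch",
    "init_params",
    "loss_and_grad",
    "predict",
    "accuracy",
    "load_word2vec_text",
    "build_embedding_matrix",
]

PAD_INDEX = 0


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; hashable so the model object can be cached."""

    kind: str  # "logreg" | "lstm"
    n_classes: int = 2
    init_seed: int = 0
    # logreg
    n_features: int | None = None
    # lstm
    vocab_size: int | None = None
    embed_dim: int = 100
    hidden_dim: int = 128
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.kind not in ("logreg", "lstm"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.kind == "logreg" and not self.n_features:
            raise ValueError("logreg requires n_features")
        if self.kind == "lstm":
            if not self.vocab_size:
                raise ValueError("lstm requires vocab_size")
            if self.max_len < 1:
                raise ValueError("lstm requires max_len >= 1")


@dataclass
class Batch:
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("batch x/y row counts disagree")
        if len(self.y) == 0:
            raise ValueError("empty batch")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _ce_loss_and_dlogits(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    p = _softmax(logits)
    eps = 1e-300  # guards log of exact zero for pathological inputs
    loss = float(-np.log(p[np.arange(n), y] + eps).mean())
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class _LogReg:
    """Multinomial logistic regression; zero init (convex problem)."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    def init_params(self) -> ModelParams:
        d, c = self.spec.n_features, self.spec.n_classes
        return ModelParams([("W", np.zeros((d, c))), ("b", np.zeros(c))])

    def scores(self, theta: ModelParams, x: np.ndarray) -> np.ndarray:
        return x @ theta.arrays[0] + theta.arrays[1]

    def loss_and_grad(self, theta: ModelParams, batch: Batch):
        x = np.asarray(batch.x, dtype=np.float64)
        loss, dlogits = _ce_loss_and_dlogits(self.scores(theta, x), batch.y)
        grad = ModelParams([("W", x.T @ dlogits), ("b", dlogits.sum(axis=0))])
        return loss, grad


class _LSTM:
    """Embedding -> single LSTM layer -> last unmasked state -> dense softmax.

    Gate layout inside the fused (4H) axis is [input, forget, cell, output].
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    def init_params(self) -> ModelParams:
        s = self.spec
        rng = np.random.default_rng((s.init_seed, 77_003))
        u = lambda *shape: rng.uniform(-0.08, 0.08, size=shape)
        return ModelParams(
            [
                ("embedding", u(s.vocab_size, s.embed_dim)),
                ("W_x", u(s.embed_dim, 4 * s.hidden_dim)),
                ("W_h", u(s.hidden_dim, 4 * s.hidden_dim)),
                ("b_lstm", np.zeros(4 * s.hidden_dim)),
                ("W_out", u(s.hidden_dim, s.n_classes)),
                ("b_out", np.zeros(s.n_classes)),
            ]
        )

    def _forward(self, theta: ModelParams, tokens: np.ndarray, keep_cache: bool):
        emb, W_x, W_h, b, W_out, b_out = theta.arrays
        tokens = np.asarray(tokens, dtype=np.int64)
        n, T = tokens.shape
        H = self.spec.hidden_dim
        mask = (tokens != PAD_INDEX).astype(np.float64)
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        cache = []
        for t in range(T):
            x_t = emb[tokens[:, t]]
            a = x_t @ W_x + h @ W_h + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_cand = f * c + i * g
            tc = np.tanh(c_cand)
            h_cand = o * tc
            m = mask[:, t : t + 1]
            h_new = m * h_cand + (1.0 - m) * h
            c_new = m * c_cand + (1.0 - m) * c
            if keep_cache:
                cache.append((x_t, h, c, i, f, g, o, tc, m))
            h, c = h_new, c_new
        logits = h @ W_out + b_out
        return logits, h, mask, cache

    def scores(self, theta: ModelParams, x: np.ndarray) -> np.ndarray:
        logits, _, _, _ = self._forward(theta, x, keep_cache=False)
        return logits

    def loss_and_grad(self, theta: ModelParams, batch: Batch):
        emb, W_x, W_h, b, W_out, b_out = theta.arrays
        tokens = np.asarray(batch.x, dtype=np.int64)
        n, T = tokens.shape
        H = self.spec.hidden_dim
        logits, h_final, mask, cache = self._forward(theta, tokens, keep_cache=True)
        loss, dlogits = _ce_loss_and_dlogits(logits, batch.y)

        dW_out = h_final.T @ dlogits
        db_out = dlogits.sum(axis=0)
        dh = dlogits @ W_out.T
        dc = np.zeros_like(dh)
        d_emb = np.zeros_like(emb)
        dW_x = np.zeros_like(W_x)
        dW_h = np.zeros_like(W_h)
        db = np.zeros_like(b)
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc, m = cache[t]
            dh_cand = dh * m
            dh_skip = dh * (1.0 - m)
            dc_cand = dc * m + dh_cand * o * (1.0 - tc * tc)
            do = dh_cand * tc
            di = dc_cand * g
            df = dc_cand * c_prev
            dg = dc_cand * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW_x += x_t.T @ da
            dW_h += h_prev.T @ da
            db += da.sum(axis=0)
            np.add.at(d_emb, tokens[:, t], da @ W_x.T)
            dh = dh_skip + da @ W_h.T
            dc = dc * (1.0 - m) + dc_cand * f
        grad = ModelParams(
            [
                ("embedding", d_emb),
                ("W_x", dW_x),
                ("W_h", dW_h),
                ("b_lstm", db),
                ("W_out", dW_out),
                ("b_out", db_out),
            ]
        )
        return loss, grad


@lru_cache(maxsize=64)
def _model_for(spec: ModelSpec):
    return _LogReg(spec) if spec.kind == "logreg" else _LSTM(spec)


def init_params(spec: ModelSpec) -> ModelParams:
    """Deterministic initial parameters for the given architecture/seed."""
    return _model_for(spec).init_params()


def loss_and_grad(spec: ModelSpec, theta: ModelParams, batch: Batch):
    """Mean cross-entropy over the batch and its exact gradient."""
    return _model_for(spec).loss_and_grad(theta, batch)


def predict(spec: ModelSpec, theta: ModelParams, x: np.ndarray) -> np.ndarray:
    """Argmax class labels; ties break toward the lowest class index."""
    return np.argmax(_model_for(spec).scores(theta, x), axis=1)


def accuracy(spec: ModelSpec, theta: ModelParams, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(predict(spec, theta, x) == np.asarray(y)))


def batch_loss(spec: ModelSpec, theta: ModelParams, x: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy without the gradient (evaluation path)."""
    logits = _model_for(spec).scores(theta, np.asarray(x))
    loss, _ = _ce_loss_and_dlogits(logits, np.asarray(y))
    return loss


# -- word-embedding support ----------------------------------------------------------


def load_word2vec_text(path) -> tuple[dict[str, np.ndarray], int]:
    """Read word2vec text format: header "count dim", then "token v1 ... vd"."""
    vectors: dict[str, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("word2vec text format requires a 'count dim' header")
        _, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"bad vector line for token {parts[0]!r}")
            vectors[parts[0]] = np.asarray(parts[1:], dtype=np.float64)
    return vectors, dim


def build_embedding_matrix(
    vocab: dict[str, int],
    dim: int,
    pretrained: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Embedding matrix for a token->index vocab.

    Tokens found in ``pretrained`` use their vectors; out-of-vocabulary tokens
    get a seeded random vector.  Row 0 (padding) is all zeros.
    """
    n_rows = max(vocab.values()) + 1 if vocab else 1
    rng = np.random.default_rng((seed, 88_007))
    mat = rng.uniform(-0.08, 0.08, size=(n_rows, dim))
    mat[PAD_INDEX] = 0.0
    if pretrained:
        for tok, idx in vocab.items():
            vec = pretrained.get(tok)
            if vec is not None:
                if len(vec) != dim:
                    raise ValueError(f"dimension mismatch for token {tok!r}")
                mat[idx] = vec
    return mat
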