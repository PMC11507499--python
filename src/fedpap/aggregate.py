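"""Server-side model aggregation.

Two aggregation families:

* sample-size weighted averaging — the classic convex combination
  ``theta = sum_k (n_k / sum_j n_j) theta_k``;
* attention-weighted aggregation — the server measures the L2 distance
  between its current model and each client model, softmax-normalizes those
  distances into attention weights ``alpha_k``, and takes the gradient-like
  step ``theta <- theta - stepsize * sum_k alpha_k (theta - theta_k)``.

Note the printed convention this package reproduces deliberately: the softmax
is taken over the raw distances, so *more distant* clients receive *larger*
weights.  The prose around the formula speaks of "similarity", which would
suggest the opposite sign; ``negate_scores=True`` exposes that variant, but
the default follows the formula as published.

``scope`` selects whether one softmax covers the whole parameter vector or
one softmax is taken per layer (the attentive-aggregation lineage uses
per-layer weights; that is the default in the experiment presets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ModelParams

__all__ = [
    "AttentionReport",
    "weighted_average",
    "attention_weights",
    "attention_aggregate",
]


@dataclass
class AttentionReport:
    """Distances and softmax weights from one aggregation step.

    ``distances`` and ``weights`` have shape (n_clients,) for whole-model
    scope and (n_clients, n_layers) for per-layer scope; each softmax group
    (overall, or one per layer) sums to 1.
    """

    scope: str
    layer_names: tuple[str, ...]
    distances: np.ndarray
    weights: np.ndarray

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "layer_names": list(self.layer_names),
            "distances": self.distances.tolist(),
            "weights": self.weights.tolist(),
        }


def weighted_average(
    clients: Sequence[tuple[ModelParams, int]]
) -> ModelParams:
    """Sample-size weighted convex combination of client models."""
    if len(clients) == 0:
        raise ValueError("no clients to aggregate")
    for _, n_k in clients:
        if n_k <= 0:
            raise ValueError("client sample sizes must be positive")
    ref = clients[0][0]
    total = float(sum(n for _, n in clients))
    acc = [np.zeros_like(a) for a in ref.arrays]
    for theta, n_k in clients:
        ref.require_conformable(theta)
        w = n_k / total
        for s, a in zip(acc, theta.arrays):
            s += w * a
    return ModelParams(zip(ref.names, acc))


def _stable_softmax(scores: np.ndarray, axis: int = 0) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_weights(
    theta_global: ModelParams,
    clients: Sequence[ModelParams],
    scope: str = "per_layer",
    negate_scores: bool = False,
) -> AttentionReport:
    """Softmax attention weights from server-client parameter distances."""
    if len(clients) == 0:
        raise ValueError("no clients")
    if scope not in ("whole_model", "per_layer"):
        raise ValueError(f"unknown scope {scope!r}")
    rows = []
    for theta_k in clients:
        theta_global.require_conformable(theta_k)
        sq = [
            float(((a - b) ** 2).sum())
            for a, b in zip(theta_global.arrays, theta_k.arrays)
        ]
        if scope == "whole_model":
            rows.append([np.sqrt(sum(sq))])
        else:
            rows.append(list(np.sqrt(sq)))
    distances = np.asarray(rows)  # (n_clients, n_groups)
    scores = -distances if negate_scores else distances
    weights = _stable_softmax(scores, axis=0)
    if scope == "whole_model":
        distances = distances[:, 0]
        weights = weights[:, 0]
    return AttentionReport(scope, theta_global.names, distances, weights)


def attention_aggregate(
    theta_global: ModelParams,
    clients: Sequence[ModelParams],
    stepsize: float,
    scope: str = "per_layer",
    negate_scores: bool = False,
) -> tuple[ModelParams, AttentionReport]:
    """Attention step: theta - stepsize * sum_k alpha_k (theta - theta_k)."""
    if stepsize <= 0:
        raise ValueError("stepsize must be positive")
    report = attention_weights(theta_global, clients, scope, negate_scores)
    w = report.weights if report.weights.ndim == 2 else report.weights[:, None]
    n_layers = len(theta_global)
    new_layers = []
    for li, (name, g_layer) in enumerate(theta_global):
        col = 0 if report.scope == "whole_model" else li
        pull = np.zeros_like(g_layer)
        for k, theta_k in enumerate(clients):
            pull += w[k, col] * (g_layer - theta_k.arrays[li])
        new_layers.append((name, g_layer - stepsize * pull))
    return ModelParams(new_layers), report
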