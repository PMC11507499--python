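"""Client-side optimizers and the local update loop.

Four optimizers share one stepping interface:

* ``sgd``   — plain minibatch gradient descent.
* ``pgd``   — perturbed (proximal) gradient descent: SGD on the augmented
  objective ``H(theta, anchor) = F_k(theta) + (mu/2)||theta - anchor||^2``,
  whose gradient is ``grad F_k + mu (theta - anchor)``.  The anchor is the
  round-start global model and is frozen for the whole round.
* ``adam``  — bias-corrected first/second-moment adaptive steps.
* ``padam`` — Adam applied to the perturbed gradient.

By construction ``pgd(mu=0) == sgd`` and ``padam(mu=0) == adam`` bit-exactly.

Optimizer state (moments, step counter, anchor) is created fresh at the start
of every ``client_update``: the server overwrites local parameters each
communication round, which invalidates stale moment estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .models import Batch, ModelSpec, loss_and_grad
from .params import ModelParams
from .synthetic import ClientDataset

__all__ = [
    "OptimizerConfig",
    "OptimizerState",
    "perturbed_grad",
    "step",
    "client_update",
]

_KINDS = ("sgd", "pgd", "adam", "padam")
_PROXIMAL = ("pgd", "padam")


@dataclass(frozen=True)
class OptimizerConfig:
    kind: str
    learning_rate: float
    mu: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown optimizer kind {self.kind!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kind in _PROXIMAL and self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1/beta2 must lie in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class OptimizerState:
    """Per-round optimizer memory; fresh (zero moments, t=0) at creation."""

    m: ModelParams
    v: ModelParams
    t: int
    anchor: ModelParams | None

    @staticmethod
    def fresh(template: ModelParams, anchor: ModelParams | None = None) -> "OptimizerState":
        return OptimizerState(template.zeros_like(), template.zeros_like(), 0, anchor)


def perturbed_grad(
    grad: ModelParams, theta_local: ModelParams, anchor: ModelParams, mu: float
) -> ModelParams:
    """Gradient of the proximally augmented objective: g + mu*(theta - anchor)."""
    grad.require_conformable(theta_local)
    theta_local.require_conformable(anchor)
    if mu == 0.0:
        return grad
    return ModelParams(
        (n, g + mu * (tl - a))
        for (n, g), tl, a in zip(grad, theta_local.arrays, anchor.arrays)
    )


def step(
    config: OptimizerConfig,
    state: OptimizerState,
    theta: ModelParams,
    grad: ModelParams,
) -> tuple[ModelParams, OptimizerState]:
    """One optimizer step; returns updated parameters and state.

    For the proximal kinds the perturbation is applied here, so callers pass
    the raw data gradient regardless of optimizer kind.
    """
    theta.require_conformable(grad)
    if config.kind in _PROXIMAL:
        if state.anchor is None:
            raise ValueError(f"{config.kind} requires an anchor in the state")
        g = perturbed_grad(grad, theta, state.anchor, config.mu)
    else:
        g = grad

    if config.kind in ("sgd", "pgd"):
        eta = config.learning_rate
        new_theta = ModelParams(
            (n, th - eta * ga) for (n, th), ga in zip(theta, g.arrays)
        )
        return new_theta, replace(state, t=state.t + 1)

    # adam / padam
    b1, b2, eps, eta = config.beta1, config.beta2, config.epsilon, config.learning_rate
    t = state.t + 1
    bc1 = 1.0 - b1**t
    bc2 = 1.0 - b2**t
    new_m, new_v, new_th = [], [], []
    for (name, th), ga, m, v in zip(theta, g.arrays, state.m.arrays, state.v.arrays):
        m_new = b1 * m + (1.0 - b1) * ga
        v_new = b2 * v + (1.0 - b2) * ga * ga
        m_hat = m_new / bc1
        v_hat = v_new / bc2
        new_m.append((name, m_new))
        new_v.append((name, v_new))
        new_th.append((name, th - eta * m_hat / (np.sqrt(v_hat) + eps)))
    return ModelParams(new_th), OptimizerState(
        ModelParams(new_m), ModelParams(new_v), t, state.anchor
    )


def _batch_plan(
    n: int, batch_size: int, num_epochs: int, num_iters: int, iter_mode: str,
    rng: np.random.Generator,
):
    """Yield index arrays: shuffled cycling over the training set.

    ``product`` mode runs num_epochs * num_iters minibatch steps (the two
    local-loop knobs multiply); ``epoch_pass`` runs num_epochs full passes.
    Each epoch reshuffles; batches cycle through the permutation, wrapping
    around when num_iters exceeds one pass.
    """
    if batch_size > n:
        warnings.warn(
            f"batch_size {batch_size} exceeds client training size {n}; "
            "using full-batch steps",
            stacklevel=3,
        )
    b = min(batch_size, n)
    steps_per_epoch = num_iters if iter_mode == "product" else -(-n // b)
    for _ in range(num_epochs):
        perm = rng.permutation(n)
        pos = 0
        for _ in range(steps_per_epoch):
            if pos + b > n:
                perm = rng.permutation(n)
                pos = 0
            yield perm[pos : pos + b]
            pos += b


def client_update(
    spec: ModelSpec,
    theta_global: ModelParams,
    data: ClientDataset,
    config: OptimizerConfig,
    num_epochs: int,
    num_iters: int,
    batch_size: int,
    rng_seed,
    iter_mode: str = "product",
) -> ModelParams:
    """Run one client's local training round and return its updated model.

    Starts from the broadcast global parameters with a fresh optimizer state
    anchored at them, then performs seeded minibatch steps.  Deterministic
    given ``rng_seed``; no state survives between calls.
    """
    if data.n_train < 1:
        raise ValueError("client has no training data")
    if min(num_epochs, num_iters, batch_size) < 1:
        raise ValueError("num_epochs, num_iters and batch_size must be >= 1")
    if iter_mode not in ("product", "epoch_pass"):
        raise ValueError(f"unknown iter_mode {iter_mode!r}")
    rng = np.random.default_rng(rng_seed)
    theta = theta_global
    state = OptimizerState.fresh(theta_global, anchor=theta_global)
    x, y = data.train_x, data.train_y
    for idx in _batch_plan(
        data.n_train, batch_size, num_epochs, num_iters, iter_mode, rng
    ):
        _, grad = loss_and_grad(spec, theta, Batch(x[idx], y[idx]))
        theta, state = step(config, state, theta, grad)
    return theta
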