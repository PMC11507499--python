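"""Federated orchestration: the communication-round protocol and algorithm presets.

One communication round is: the server samples a subset of clients, broadcasts
the global parameters, each sampled client runs its local update, the server
aggregates the returned models, and (every ``eval_every`` rounds) the global
model is evaluated on **all** clients' test sets, weighted by test-set size.

The nine named algorithms are (aggregator, local optimizer) bindings:

==========  =====================  ================
algorithm   aggregation            local optimizer
==========  =====================  ================
fedavg      weighted average       sgd
fedprox     weighted average       pgd
fedatt      attention              sgd
fedpa       attention              pgd
fedavgs     weighted average       adam
fedavgt     weighted average       adam (alias of fedavgs; the distinction
                                   in the source experiments was a library-vs-
                                   custom Adam validation, same mathematics)
fedproxp    weighted average       padam
fedatts     attention              adam
fedpap      attention              padam
==========  =====================  ================

Setting ``mu=0`` collapses each proximal algorithm onto its plain counterpart
bit-exactly (fedprox->fedavg, fedpa->fedatt, fedproxp->fedavgs,
fedpap->fedatts), because all training randomness derives from ``config.seed``
via named substreams that do not depend on the algorithm label.

The user-facing surface is statsmodels-shaped: build a
:class:`FederatedExperiment` from a dataset, a model spec and a config, call
``fit()``, and read the returned :class:`FederatedResults` (round metrics,
max-Acc / min-loss summary, plotting).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as _models
from .aggregate import AttentionReport, attention_aggregate, weighted_average
from .models import ModelSpec
from .optim import OptimizerConfig, client_update
from .params import ModelParams
from .synthetic import FederatedDataset, SyntheticSpec, generate_synthetic

__all__ = [
    "ALGORITHMS",
    "FederatedConfig",
    "RoundMetrics",
    "FederatedExperiment",
    "FederatedResults",
    "sample_clients",
    "run_federated",
    "evaluate_global",
    "summarize_runs",
]

# algorithm -> (aggregator, optimizer kind)
ALGORITHMS: dict[str, tuple[str, str]] = {
    "fedavg": ("average", "sgd"),
    "fedprox": ("average", "pgd"),
    "fedatt": ("attention", "sgd"),
    "fedpa": ("attention", "pgd"),
    "fedavgs": ("average", "adam"),
    "fedavgt": ("average", "adam"),
    "fedproxp": ("average", "padam"),
    "fedatts": ("attention", "adam"),
    "fedpap": ("attention", "padam"),
}

# named RNG substreams of config.seed
_STREAM_SAMPLING = 101
_STREAM_CLIENT = 202


@dataclass(frozen=True)
class FederatedConfig:
    """Hyperparameters of one federated run (defaults = the benchmark set)."""

    algorithm: str = "fedavg"
    learning_rate: float = 0.01
    num_rounds: int = 100
    clients_per_round: int = 10
    num_epochs: int = 10
    num_iters: int = 20
    eval_every: int = 1
    batch_size: int = 10
    seed: int = 0
    mu: float = 1.0
    stepsize: float = 1.2
    scope: str = "per_layer"
    negate_scores: bool = False
    iter_mode: str = "product"
    loss_on: str = "test"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {sorted(ALGORITHMS)}"
            )
        for name in ("num_rounds", "clients_per_round", "num_epochs", "num_iters",
                     "eval_every", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.stepsize <= 0:
            raise ValueError("stepsize must be positive")
        if self.loss_on not in ("test", "train"):
            raise ValueError("loss_on must be 'test' or 'train'")

    @property
    def aggregator(self) -> str:
        return ALGORITHMS[self.algorithm][0]

    @property
    def optimizer_kind(self) -> str:
        return ALGORITHMS[self.algorithm][1]

    def optimizer_config(self) -> OptimizerConfig:
        kind = self.optimizer_kind
        return OptimizerConfig(
            kind=kind,
            learning_rate=self.learning_rate,
            mu=self.mu if kind in ("pgd", "padam") else 0.0,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "FederatedConfig":
        return FederatedConfig(**d)


@dataclass
class RoundMetrics:
    round: int
    acc: float
    loss: float
    attention: AttentionReport | None = None
    elapsed_ms: float = 0.0

    def to_dict(self) -> dict:
        d = {
            "round": self.round,
            "acc": self.acc,
            "loss": self.loss,
            "elapsed_ms": self.elapsed_ms,
        }
        if self.attention is not None:
            d["attention"] = self.attention.to_dict()
        return d


def sample_clients(
    n_clients: int, clients_per_round: int, round_index: int, seed: int
) -> np.ndarray:
    """Uniform sample without replacement; deterministic in (seed, round)."""
    if clients_per_round > n_clients:
        raise ValueError(
            f"clients_per_round {clients_per_round} exceeds population {n_clients}"
        )
    rng = np.random.default_rng((seed, _STREAM_SAMPLING, round_index))
    return np.sort(rng.choice(n_clients, size=clients_per_round, replace=False))


def evaluate_global(
    model_spec: ModelSpec,
    theta: ModelParams,
    dataset: FederatedDataset,
    loss_on: str = "test",
) -> tuple[float, float]:
    """Test-sample-weighted accuracy and cross-entropy of the global model.

    The accuracy weighting by client test-set size is algebraically the
    pooled correct-over-total rate across all clients.
    """
    correct = 0
    total = 0
    loss_num = 0.0
    loss_den = 0
    for cl in dataset.clients:
        pred = _models.predict(model_spec, theta, cl.test_x)
        correct += int((pred == cl.test_y).sum())
        total += cl.n_test
        lx, ly = (cl.train_x, cl.train_y) if loss_on == "train" else (cl.test_x, cl.test_y)
        loss_num += _models.batch_loss(model_spec, theta, lx, ly) * len(ly)
        loss_den += len(ly)
    return correct / total, loss_num / loss_den


def _validate(config: FederatedConfig, dataset: FederatedDataset, spec: ModelSpec):
    if dataset.n_clients < config.clients_per_round:
        raise ValueError("dataset has fewer clients than clients_per_round")
    sample = dataset.clients[0].train_x
    if spec.kind == "logreg":
        if sample.shape[1] != spec.n_features:
            raise ValueError(
                f"dataset feature dim {sample.shape[1]} != model n_features {spec.n_features}"
            )
    else:
        top = max(int(np.max(c.train_x, initial=0)) for c in dataset.clients)
        if top >= spec.vocab_size:
            raise ValueError(
                f"token index {top} out of range for vocab_size {spec.vocab_size}"
            )
    top_y = max(int(np.max(c.train_y, initial=0)) for c in dataset.clients)
    if top_y >= spec.n_classes:
        raise ValueError(f"label {top_y} out of range for n_classes {spec.n_classes}")


def run_federated(
    config: FederatedConfig,
    dataset: FederatedDataset,
    model_spec: ModelSpec,
    progress: bool = False,
) -> tuple[list[RoundMetrics], ModelParams]:
    """Run the full federated protocol; fully deterministic given config.seed."""
    _validate(config, dataset, model_spec)
    theta = _models.init_params(model_spec)
    opt_config = config.optimizer_config()
    attention = config.aggregator == "attention"
    metrics: list[RoundMetrics] = []
    for r in range(1, config.num_rounds + 1):
        t0 = time.perf_counter()
        selected = sample_clients(
            dataset.n_clients, config.clients_per_round, r, config.seed
        )
        client_thetas = []
        client_sizes = []
        for k in selected:
            cl = dataset.clients[k]
            theta_k = client_update(
                model_spec,
                theta,
                cl,
                opt_config,
                num_epochs=config.num_epochs,
                num_iters=config.num_iters,
                batch_size=config.batch_size,
                rng_seed=(config.seed, _STREAM_CLIENT, r, int(k)),
                iter_mode=config.iter_mode,
            )
            client_thetas.append(theta_k)
            client_sizes.append(cl.n_train)
        report = None
        if attention:
            theta, report = attention_aggregate(
                theta,
                client_thetas,
                stepsize=config.stepsize,
                scope=config.scope,
                negate_scores=config.negate_scores,
            )
        else:
            theta = weighted_average(list(zip(client_thetas, client_sizes)))
        if (r - 1) % config.eval_every == 0:
            acc, loss = evaluate_global(model_spec, theta, dataset, config.loss_on)
            metrics.append(
                RoundMetrics(r, acc, loss, report, (time.perf_counter() - t0) * 1e3)
            )
            if progress:
                print(f"round {r:4d}  acc {acc:.4f}  loss {loss:.4f}")
    return metrics, theta


class FederatedResults:
    """Fit results: per-round metrics, summary statistics, plotting."""

    def __init__(
        self,
        metrics: list[RoundMetrics],
        final_params: ModelParams,
        config: FederatedConfig,
    ):
        self.metrics = metrics
        self.final_params = final_params
        self.config = config

    @property
    def max_acc(self) -> float:
        """Best weighted test accuracy over all evaluated rounds."""
        return max(m.acc for m in self.metrics)

    @property
    def min_loss(self) -> float:
        """Best (smallest) weighted cross-entropy over all evaluated rounds."""
        return min(m.loss for m in self.metrics)

    @property
    def final_acc(self) -> float:
        return self.metrics[-1].acc

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": [m.round for m in self.metrics],
                "acc": [m.acc for m in self.metrics],
                "loss": [m.loss for m in self.metrics],
                "elapsed_ms": [m.elapsed_ms for m in self.metrics],
            }
        )

    def summary(self) -> str:
        df = self.to_dataframe()
        lines = [
            "Federated training results",
            "=" * 42,
            f"algorithm:        {self.config.algorithm}",
            f"rounds evaluated: {len(df)}",
            f"max Acc:          {self.max_acc:.4f} (round {int(df.loc[df.acc.idxmax(), 'round'])})",
            f"min loss:         {self.min_loss:.4f} (round {int(df.loc[df.loss.idxmin(), 'round'])})",
            f"final Acc:        {self.final_acc:.4f}",
            f"mean round time:  {df.elapsed_ms.mean():.1f} ms",
        ]
        return "\n".join(lines)

    def save_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for m in self.metrics:
                fh.write(json.dumps(m.to_dict()) + "\n")

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, ax_acc=None, ax_loss=None, label: str | None = None):
        """Plot Acc and loss against communication round."""
        import matplotlib.pyplot as plt

        if ax_acc is None or ax_loss is None:
            _, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(10, 4))
        df = self.to_dataframe()
        name = label or self.config.algorithm
        ax_acc.plot(df["round"], df["acc"], label=name)
        ax_loss.plot(df["round"], df["loss"], label=name)
        ax_acc.set_xlabel("communication round"); ax_acc.set_ylabel("Acc")
        ax_loss.set_xlabel("communication round"); ax_loss.set_ylabel("loss")
        return ax_acc, ax_loss


class FederatedExperiment:
    """A federated training run bound to a dataset, model and config.

    Examples
    --------
    >>> from fedpap import FederatedConfig, FederatedExperiment, SyntheticSpec
    >>> exp = FederatedExperiment.from_synthetic(
    ...     SyntheticSpec(alpha=0.5, beta=0.5),
    ...     FederatedConfig(algorithm="fedpap", learning_rate=0.001,
    ...                     mu=0.03, stepsize=4, num_rounds=10),
    ... )
    >>> res = exp.fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: FederatedDataset,
        model_spec: ModelSpec,
        config: FederatedConfig,
    ):
        self.dataset = dataset
        self.model_spec = model_spec
        self.config = config
        _validate(config, dataset, model_spec)

    @classmethod
    def from_synthetic(
        cls,
        data_spec: SyntheticSpec,
        config: FederatedConfig,
        model_kind: str = "logreg",
    ) -> "FederatedExperiment":
        """Generate a synthetic dataset and bind a matching logistic model."""
        dataset = generate_synthetic(data_spec)
        if model_kind != "logreg":
            raise ValueError("synthetic tabular data pairs with the logreg model")
        model_spec = ModelSpec(
            kind="logreg",
            n_features=data_spec.n_features,
            n_classes=data_spec.n_classes,
            init_seed=config.seed,
        )
        return cls(dataset, model_spec, config)

    def fit(self, progress: bool = False) -> FederatedResults:
        metrics, theta = run_federated(
            self.config, self.dataset, self.model_spec, progress=progress
        )
        return FederatedResults(metrics, theta, self.config)


def summarize_runs(runs: dict[str, "FederatedResults | pd.DataFrame"]) -> pd.DataFrame:
    """Max-Acc / min-loss comparison table across named runs."""
    rows = []
    for name, res in runs.items():
        df = res.to_dataframe() if isinstance(res, FederatedResults) else res
        rows.append(
            {
                "run": name,
                "max_acc": float(df["acc"].max()),
                "min_loss": float(df["loss"].min()),
                "final_acc": float(df["acc"].iloc[-1]),
                "rounds": len(df),
            }
        )
    return pd.DataFrame(rows)
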