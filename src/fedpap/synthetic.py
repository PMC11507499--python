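"""Synthetic heterogeneous federated classification data.

The ``synthetic(alpha, beta)`` generator builds one classification dataset per
client from client-specific latent draws, so that statistical heterogeneity is
controlled by two knobs:

* ``alpha`` — label-distribution skew.  Each client k draws a latent mean
  ``u_k ~ N(0, alpha)`` and its own softmax model ``W_k, b_k ~ N(u_k, 1)``;
  larger ``alpha`` pushes client models apart and therefore skews per-client
  label distributions.
* ``beta`` — feature-distribution skew.  Each client draws ``B_k ~ N(0, beta)``
  and a feature-mean vector ``v_k`` with entries ``N(B_k, 1)``; larger ``beta``
  shifts client feature clouds apart.

Features are drawn ``x ~ N(v_k, Sigma)`` with the fixed diagonal covariance
``Sigma_jj = j**-1.2`` (decaying per-feature variance), and labels are the
argmax of ``softmax(x W_k + b_k)``.  Client sample sizes follow the power-law
convention of the published lineage this generator follows:
``n_k = 50 + floor(LogNormal(4, 2))``, i.e. a few large clients and many small
ones.  The IID variant shares a single ``(W, b)`` and a single feature mean
across all clients.

Every client's draw comes from its own child stream of the root seed, so
changing ``n_clients`` never reshuffles earlier clients' data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "ClientDataset",
    "FederatedDataset",
    "PartitionStats",
    "generate_synthetic",
    "partition_stats",
    "save_dataset",
    "load_dataset",
    "dataset_to_csv",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic(alpha, beta) generator.

    ``size_offset``, ``size_log_mean``, ``size_log_sd`` define the client
    sample-size law ``n_k = size_offset + floor(LogNormal(mean, sd))``;
    ``cov_exponent`` is the per-feature variance decay ``Sigma_jj = j**-e``.
    """

    alpha: float = 0.0
    beta: float = 0.0
    n_clients: int = 30
    n_features: int = 60
    n_classes: int = 10
    iid: bool = False
    seed: int = 0
    train_fraction: float = 0.9
    size_offset: int = 50
    size_log_mean: float = 4.0
    size_log_sd: float = 2.0
    cov_exponent: float = 1.2

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if min(self.n_clients, self.n_features) < 1:
            raise ValueError("n_clients and n_features must be positive")


@dataclass
class ClientDataset:
    """One client's train/test arrays; ``x`` rows pair with ``y`` entries."""

    client_id: int
    train_x: np.ndarray
    train_y: np.ndarray
    test_x: np.ndarray
    test_y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.train_x) != len(self.train_y):
            raise ValueError("train x/y row counts disagree")
        if len(self.test_x) != len(self.test_y):
            raise ValueError("test x/y row counts disagree")

    @property
    def n_train(self) -> int:
        return len(self.train_y)

    @property
    def n_test(self) -> int:
        return len(self.test_y)


@dataclass
class FederatedDataset:
    clients: list[ClientDataset]
    provenance: dict = field(default_factory=dict)

    @property
    def n_clients(self) -> int:
        return len(self.clients)

    @property
    def n_train(self) -> int:
        return sum(c.n_train for c in self.clients)

    @property
    def n_test(self) -> int:
        return sum(c.n_test for c in self.clients)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _split(
    x: np.ndarray, y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = len(y)
    n_train = int(np.floor(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)  # both splits nonempty
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    return x[tr], y[tr], x[te], y[te]


def generate_synthetic(spec: SyntheticSpec) -> FederatedDataset:
    """Generate a synthetic(alpha, beta) federated dataset.

    Deterministic given ``spec`` (including ``spec.seed``).  Client ``k`` is a
    pure function of ``(seed, k)``: its sample size, latent model, feature
    means and samples all come from the stream ``default_rng((seed, k))``.
    """
    d, c = spec.n_features, spec.n_classes
    cov_diag = np.power(np.arange(1, d + 1, dtype=np.float64), -spec.cov_exponent)
    cov_sd = np.sqrt(cov_diag)

    if spec.iid:
        shared = np.random.default_rng((spec.seed, 1_000_003))
        W_shared = shared.normal(0.0, 1.0, size=(d, c))
        b_shared = shared.normal(0.0, 1.0, size=c)
        B_shared = shared.normal(0.0, spec.beta) if spec.beta > 0 else 0.0
        v_shared = np.full(d, B_shared)

    clients: list[ClientDataset] = []
    for k in range(spec.n_clients):
        rng = np.random.default_rng((spec.seed, k))
        n_k = spec.size_offset + int(
            np.floor(rng.lognormal(spec.size_log_mean, spec.size_log_sd))
        )
        if spec.iid:
            W, b, v = W_shared, b_shared, v_shared
        else:
            u_k = rng.normal(0.0, spec.alpha) if spec.alpha > 0 else 0.0
            W = rng.normal(u_k, 1.0, size=(d, c))
            b = rng.normal(u_k, 1.0, size=c)
            B_k = rng.normal(0.0, spec.beta) if spec.beta > 0 else 0.0
            v = rng.normal(B_k, 1.0, size=d)
        x = v + rng.standard_normal(size=(n_k, d)) * cov_sd
        y = np.argmax(_softmax(x @ W + b), axis=1).astype(np.int64)
        tr_x, tr_y, te_x, te_y = _split(x, y, spec.train_fraction, rng)
        clients.append(ClientDataset(k, tr_x, tr_y, te_x, te_y))

    return FederatedDataset(clients, provenance=asdict(spec))


@dataclass
class PartitionStats:
    """Per-client sample-size and class-distribution report."""

    table: pd.DataFrame  # one row per client: sizes + per-class train counts
    n_classes: int

    @property
    def total_train(self) -> int:
        return int(self.table["n_train"].sum())

    @property
    def total_test(self) -> int:
        return int(self.table["n_test"].sum())

    @property
    def max_train_size(self) -> int:
        return int(self.table["n_train"].max())

    @property
    def min_train_size(self) -> int:
        return int(self.table["n_train"].min())

    def class_count(self, client_id: int, klass: int) -> int:
        row = self.table.loc[self.table["client_id"] == client_id]
        if row.empty:
            raise KeyError(f"no client {client_id}")
        return int(row[f"class_{klass}"].iloc[0])

    def label_distributions(self) -> np.ndarray:
        """(n_clients, n_classes) row-normalized training label frequencies."""
        counts = self.table[[f"class_{j}" for j in range(self.n_classes)]].to_numpy(
            dtype=np.float64
        )
        return counts / counts.sum(axis=1, keepdims=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def partition_stats(ds: FederatedDataset) -> PartitionStats:
    """Tabulate per-client sizes and per-class training counts."""
    n_classes = int(
        max(
            max((c.train_y.max(initial=0) for c in ds.clients), default=0),
            max((c.test_y.max(initial=0) for c in ds.clients), default=0),
        )
        + 1
    )
    if "n_classes" in ds.provenance:
        n_classes = max(n_classes, int(ds.provenance["n_classes"]))
    rows = []
    for cl in ds.clients:
        counts = np.bincount(cl.train_y, minlength=n_classes)
        row = {"client_id": cl.client_id, "n_train": cl.n_train, "n_test": cl.n_test}
        row.update({f"class_{j}": int(counts[j]) for j in range(n_classes)})
        rows.append(row)
    return PartitionStats(pd.DataFrame(rows), n_classes)


# -- on-disk dataset format ---------------------------------------------------------


def save_dataset(ds: FederatedDataset, out_dir) -> None:
    """One directory per dataset: JSON manifest + per-client array archives."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_clients": ds.n_clients,
        "provenance": ds.provenance,
        "clients": [c.client_id for c in ds.clients],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for cl in ds.clients:
        np.savez(
            out / f"client_{cl.client_id}.npz",
            train_x=cl.train_x,
            train_y=cl.train_y,
            test_x=cl.test_x,
            test_y=cl.test_y,
        )


def load_dataset(in_dir) -> FederatedDataset:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    clients = []
    for cid in manifest["clients"]:
        with np.load(src / f"client_{cid}.npz") as z:
            clients.append(
                ClientDataset(cid, z["train_x"], z["train_y"], z["test_x"], z["test_y"])
            )
    return FederatedDataset(clients, provenance=manifest.get("provenance", {}))


def dataset_to_csv(ds: FederatedDataset, path) -> None:
    """Flat CSV export: client_id, split, feature columns, label."""
    frames = []
    for cl in ds.clients:
        for split, x, y in (("train", cl.train_x, cl.train_y), ("test", cl.test_x, cl.test_y)):
            df = pd.DataFrame(np.asarray(x))
            df.columns = [f"f{j}" for j in range(df.shape[1])]
            df.insert(0, "split", split)
            df.insert(0, "client_id", cl.client_id)
            df["label"] = np.asarray(y)
            frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
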