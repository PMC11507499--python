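"""Parameter-space algebra over models.

Every aggregation rule and local optimizer in this package is written as
arithmetic on whole model parameter vectors (the ``theta`` of the federated
objective).  :class:`ModelParams` is the container for one such vector: an
ordered collection of named layer tensors.  Layer order is part of the
identity — attention aggregation may assign one weight per layer, so two
parameter sets are interchangeable only if their layers agree in name, order
and shape ("conformability").

All operations are pure: they return new values and never mutate operands,
because aggregation formulas reference the round-start global model and the
freshly updated client models simultaneously.
"""

from __future__ import annotations

import json
import zipfile
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "ConformabilityError",
    "param_axpy",
    "param_l2_distance",
    "flatten",
    "unflatten",
]


class ConformabilityError(ValueError):
    """Two parameter sets do not share layer names, order and shapes."""


class ModelParams:
    """Ordered, named collection of real-valued layer tensors.

    Parameters
    ----------
    layers
        Iterable of ``(name, array)`` pairs in model construction order.
        Arrays are converted to float64 and copied, and must be non-empty.
    """

    __slots__ = ("_names", "_arrays")

    def __init__(self, layers: Iterable[tuple[str, np.ndarray]]):
        names: list[str] = []
        arrays: list[np.ndarray] = []
        for name, arr in layers:
            a = np.array(arr, dtype=np.float64)
            if a.size == 0:
                raise ValueError(f"layer {name!r} is empty")
            names.append(str(name))
            arrays.append(a)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        self._names = tuple(names)
        self._arrays = arrays

    # -- basic container protocol -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    @property
    def arrays(self) -> list[np.ndarray]:
        """The layer tensors, in order.  Treat as read-only."""
        return self._arrays

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(zip(self._names, self._arrays))

    def __len__(self) -> int:
        return len(self._names)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._arrays[self._names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    @property
    def n_parameters(self) -> int:
        return sum(a.size for a in self._arrays)

    def copy(self) -> "ModelParams":
        return ModelParams(zip(self._names, self._arrays))

    def conformable(self, other: "ModelParams") -> bool:
        return self._names == other._names and all(
            a.shape == b.shape for a, b in zip(self._arrays, other._arrays)
        )

    def require_conformable(self, other: "ModelParams") -> None:
        if self._names != other._names:
            raise ConformabilityError(
                f"layer names differ: {self._names} vs {other._names}"
            )
        for name, a, b in zip(self._names, self._arrays, other._arrays):
            if a.shape != b.shape:
                raise ConformabilityError(
                    f"layer {name!r} shapes differ: {a.shape} vs {b.shape}"
                )

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}{a.shape}" for n, a in self)
        return f"ModelParams({inner})"

    def allclose(self, other: "ModelParams", rtol: float = 1e-12, atol: float = 0.0) -> bool:
        return self.conformable(other) and all(
            np.allclose(a, b, rtol=rtol, atol=atol)
            for a, b in zip(self._arrays, other._arrays)
        )

    def equals(self, other: "ModelParams") -> bool:
        """Bit-exact equality (used by the reduction-identity contracts)."""
        return self.conformable(other) and all(
            np.array_equal(a, b) for a, b in zip(self._arrays, other._arrays)
        )

    # -- elementwise construction helpers ------------------------------------------
    def map(self, fn) -> "ModelParams":
        return ModelParams((n, fn(a)) for n, a in self)

    def zeros_like(self) -> "ModelParams":
        return self.map(np.zeros_like)

    @staticmethod
    def binary_map(fn, x: "ModelParams", y: "ModelParams") -> "ModelParams":
        x.require_conformable(y)
        return ModelParams(
            (n, fn(a, b)) for (n, a), b in zip(x, y.arrays)
        )

    # -- serialization --------------------------------------------------------------
    def save(self, path) -> None:
        """Write a single-file archive (npz) plus an embedded JSON manifest."""
        manifest = {
            "layers": [{"name": n, "shape": list(a.shape)} for n, a in self]
        }
        arrays = {f"layer_{i}": a for i, a in enumerate(self._arrays)}
        np.savez(path, **arrays)
        # np.savez cannot carry strings portably alongside; append manifest entry
        with zipfile.ZipFile(path, "a") as zf:
            zf.writestr("manifest.json", json.dumps(manifest))

    @staticmethod
    def load(path) -> "ModelParams":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
        with np.load(path) as data:
            layers = [
                (entry["name"], data[f"layer_{i}"])
                for i, entry in enumerate(manifest["layers"])
            ]
        return ModelParams(layers)


def param_axpy(a: float, x: ModelParams, y: ModelParams) -> ModelParams:
    """Layer-wise ``a * x + y``; the workhorse of every update formula."""
    x.require_conformable(y)
    return ModelParams(
        (n, a * ax + ay) for (n, ax), ay in zip(x, y.arrays)
    )


def param_l2_distance(
    a: ModelParams, b: ModelParams, scope: str = "whole_model"
):
    """Euclidean distance between two parameter sets.

    ``scope="whole_model"`` returns a single scalar over all entries;
    ``scope="per_layer"`` returns one distance per layer in layer order.
    """
    a.require_conformable(b)
    sq = [float(((x - y) ** 2).sum()) for x, y in zip(a.arrays, b.arrays)]
    if scope == "whole_model":
        return float(np.sqrt(sum(sq)))
    if scope == "per_layer":
        return [float(np.sqrt(s)) for s in sq]
    raise ValueError(f"unknown scope {scope!r}")


def flatten(p: ModelParams) -> np.ndarray:
    """Concatenate all layers into one vector, in layer order."""
    return np.concatenate([a.ravel() for a in p.arrays])


def unflatten(v: np.ndarray, template: ModelParams) -> ModelParams:
    """Inverse of :func:`flatten` relative to ``template``'s shapes."""
    v = np.asarray(v, dtype=np.float64).ravel()
    if v.size != template.n_parameters:
        raise ValueError(
            f"vector length {v.size} != parameter count {template.n_parameters}"
        )
    out = []
    pos = 0
    for name, a in template:
        out.append((name, v[pos : pos + a.size].reshape(a.shape)))
        pos += a.size
    return ModelParams(out)
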