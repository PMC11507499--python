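import numpy as np
import pytest

from fedpap.params import ModelParams
from fedpap.synthetic import ClientDataset, FederatedDataset


def make_params(rng: np.random.Generator, shapes=None) -> ModelParams:
    """Random small ModelParams with a fixed two-layer layout."""
    shapes = shapes or [("W", (3, 4)), ("b", (4,))]
    return ModelParams((n, rng.standard_normal(s)) for n, s in shapes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_client(rng, n=40, d=5, c=3, client_id=0, separation=3.0):
    """Linearly separable client: class means spread apart along axes."""
    means = np.zeros((c, d))
    for j in range(c):
        means[j, j % d] = separation
    y = rng.integers(0, c, size=n)
    x = means[y] + rng.standard_normal((n, d)) * 0.5
    n_tr = int(0.8 * n)
    return ClientDataset(client_id, x[:n_tr], y[:n_tr], x[n_tr:], y[n_tr:])


@pytest.fixture
def toy_dataset(rng):
    """5-client linearly separable dataset for orchestration tests."""
    clients = [toy_client(rng, n=30 + 5 * k, client_id=k) for k in range(5)]
    return FederatedDataset(clients, provenance={"n_classes": 3})
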