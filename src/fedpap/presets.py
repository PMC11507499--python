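"""Ready-made experiment presets: algorithm x dataset with tuned hyperparameters.

The synthetic presets use the hyperparameters found optimal in the source
experiments: SGD learning rate 0.01 vs Adam learning rate 0.001; attention
stepsize 4 on the synthetic benchmarks (9 on the dialogue corpus, whose
default here is the text fixture); proximal mu 0.03 for the attention+proximal
algorithms and 1 for plain fedprox.  Every preset round-trips through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml

from .federated import ALGORITHMS, FederatedConfig
from .medtext import CorpusFixtureSpec
from .synthetic import SyntheticSpec

__all__ = ["ExperimentPreset", "get_preset", "preset_names", "DATASETS"]

DATASETS: dict[str, dict] = {
    "synthetic00": {"kind": "synthetic", "alpha": 0.0, "beta": 0.0},
    "synthetic0505": {"kind": "synthetic", "alpha": 0.5, "beta": 0.5},
    "synthetic11": {"kind": "synthetic", "alpha": 1.0, "beta": 1.0},
    "synthetic_iid": {"kind": "synthetic", "alpha": 0.0, "beta": 0.0, "iid": True},
    "fixture_text": {"kind": "fixture_text"},
}

_ADAM_ALGOS = {"fedavgs", "fedavgt", "fedproxp", "fedatts", "fedpap"}
_PROXIMAL_ALGOS = {"fedprox", "fedpa", "fedproxp", "fedpap"}
_ATTENTION_ALGOS = {"fedatt", "fedpa", "fedatts", "fedpap"}


@dataclass
class ExperimentPreset:
    name: str
    config: FederatedConfig
    dataset: dict
    model: dict

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "dataset": self.dataset,
            "model": self.model,
            **self.config.to_dict(),
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "ExperimentPreset":
        doc = yaml.safe_load(text)
        name = doc.pop("name", "experiment")
        dataset = doc.pop("dataset")
        model = doc.pop("model", {"kind": "logreg"})
        return ExperimentPreset(name, FederatedConfig(**doc), dataset, model)


def _tuned_config(algorithm: str, text: bool, **overrides) -> FederatedConfig:
    lr = 0.001 if algorithm in _ADAM_ALGOS else 0.01
    mu = 1.0
    if algorithm in {"fedpa", "fedpap"} or (text and algorithm in _PROXIMAL_ALGOS):
        mu = 0.03
    stepsize = 1.2
    if algorithm in _ATTENTION_ALGOS:
        stepsize = 9.0 if text else 4.0
    base = dict(
        algorithm=algorithm,
        learning_rate=lr,
        mu=mu,
        stepsize=stepsize,
    )
    if text:
        # desk-scale text run: the fixture is small and high-signal, so a
        # short local loop over half the clients per round suffices
        base.update(num_rounds=20, clients_per_round=5, num_epochs=2, num_iters=10)
    base.update(overrides)
    return FederatedConfig(**base)


def get_preset(algorithm: str, dataset: str, **overrides) -> ExperimentPreset:
    """Build the preset for one algorithm on one named dataset."""
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}"
        )
    if dataset not in DATASETS:
        raise ValueError(f"unknown dataset {dataset!r}; choose from {sorted(DATASETS)}")
    text = dataset == "fixture_text"
    config = _tuned_config(algorithm, text, **overrides)
    ds = dict(DATASETS[dataset])
    if text:
        fx = CorpusFixtureSpec()
        ds.update(asdict(fx))
        # desk-scale text run: small LSTM dims, short sequences
        model = {
            "kind": "lstm",
            "vocab_size": fx.vocab_size + 2,  # + pad/unk rows
            "embed_dim": 16,
            "hidden_dim": 32,
            "max_len": 20,
            "n_classes": fx.n_classes,
        }
        ds.setdefault("n_clients", 10)
    else:
        spec = SyntheticSpec(alpha=ds.get("alpha", 0.0), beta=ds.get("beta", 0.0),
                             iid=ds.get("iid", False))
        ds = {"kind": "synthetic", **asdict(spec)}
        model = {
            "kind": "logreg",
            "n_features": spec.n_features,
            "n_classes": spec.n_classes,
        }
    return ExperimentPreset(f"{algorithm}_{dataset}", config, ds, model)


def preset_names() -> list[str]:
    return [f"{a}_{d}" for a in ALGORITHMS for d in DATASETS]


def materialize(preset: ExperimentPreset, data_seed: int | None = None):
    """Build the (dataset, model_spec) pair a preset describes.

    ``data_seed`` overrides the dataset seed (the data seed is separate from
    the training seed in ``preset.config.seed``).
    """
    from .federated import FederatedExperiment
    from .models import ModelSpec

    ds = dict(preset.dataset)
    kind = ds.pop("kind")
    if kind == "synthetic":
        if data_seed is not None:
            ds["seed"] = data_seed
        from .synthetic import generate_synthetic

        dataset = generate_synthetic(SyntheticSpec(**ds))
    elif kind == "fixture_text":
        from .medtext import build_federated_text, fixture_vocab, generate_fixture, read_imcs

        n_clients = ds.pop("n_clients", 10)
        max_len = preset.model.get("max_len", 20)
        fx = CorpusFixtureSpec(
            **{k: v for k, v in ds.items() if k in CorpusFixtureSpec.__dataclass_fields__}
        )
        if data_seed is not None:
            fx = CorpusFixtureSpec(**{**asdict(fx), "seed": data_seed})
        records = read_imcs(generate_fixture(fx))
        dataset = build_federated_text(
            records, n_clients, fixture_vocab(fx), max_len=max_len, seed=fx.seed
        )
    elif kind == "dir":
        from .synthetic import load_dataset

        dataset = load_dataset(ds["path"])
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")

    model = dict(preset.model)
    model.setdefault("init_seed", preset.config.seed)
    model_spec = ModelSpec(**model)
    return dataset, model_spec
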