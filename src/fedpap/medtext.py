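"""Doctor-patient dialogue data path for federated sentence classification.

Reads dialogue corpora in the IMCS-V2 JSON layout (one record per dialogue:
``example_id``, patient ``self_report``, ``diagnosis``, and a ``dialogue``
list of sentences each carrying a ``speaker``, the ``sentence`` text and a
per-sentence ``symptom_type`` class label), partitions whole dialogues onto
simulated clients, and tokenizes sentences into padded index sequences for
the LSTM client.

Because the real corpus is an external download, the module also generates
synthetic fixtures in the same JSON layout: dialogues with class-conditional
token distributions over a synthetic vocabulary and a controllable per-
dialogue label skew.  The fixtures are statistically learnable (token
distributions differ by class) so the federated text experiments have
signal, and they round-trip exactly through the reader.

The default tokenizer is a dependency-free greedy longest-match segmenter
over a lexicon with single-character fallback — the language-neutral analogue
of dictionary-based Chinese word segmentation.  An external segmenter can be
plugged in as any ``text -> list[str]`` callable.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np

from .models import PAD_INDEX
from .synthetic import ClientDataset, FederatedDataset, _split

__all__ = [
    "DialogueRecord",
    "CorpusFixtureSpec",
    "SchemaError",
    "read_imcs",
    "generate_fixture",
    "build_vocab",
    "tokenize",
    "tokenize_and_index",
    "build_federated_text",
    "save_vocab",
    "load_vocab",
]

logger = logging.getLogger(__name__)

UNK_INDEX = 1
_FIRST_TOKEN_INDEX = 2


class SchemaError(ValueError):
    """A dialogue record does not follow the expected field layout."""


@dataclass
class DialogueRecord:
    example_id: str
    diagnosis: str
    self_report: str
    # (sentence_id, speaker, text, symptom_type)
    sentences: list[tuple[str, str, str, int]]

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.sentences]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate sentence_id in {self.example_id}")


def read_imcs(source) -> list[DialogueRecord]:
    """Parse IMCS-V2-format JSON into dialogue records.

    ``source`` may be a path, an open text stream, a JSON string, or an
    already-parsed object.  The document is either a mapping
    ``example_id -> record`` or a list of records.  Dialogue sentences
    lacking a ``symptom_type`` label are dropped (counted and logged).
    """
    doc = _load_json(source)
    if isinstance(doc, dict):
        items = [dict(rec, example_id=rec.get("example_id", eid)) for eid, rec in doc.items()]
    elif isinstance(doc, list):
        items = doc
    else:
        raise SchemaError("document must be a JSON object or array of dialogues")

    records = []
    dropped = 0
    for rec in items:
        if "example_id" not in rec:
            raise SchemaError("record missing example_id")
        eid = str(rec["example_id"])
        if "dialogue" not in rec:
            raise SchemaError(f"record {eid} missing dialogue")
        sentences = []
        for sent in rec["dialogue"]:
            missing = {"sentence_id", "speaker", "sentence"} - set(sent)
            if missing:
                raise SchemaError(f"record {eid} sentence missing fields {sorted(missing)}")
            label = sent.get("symptom_type")
            if label is None or label == "":
                dropped += 1
                continue
            sentences.append(
                (str(sent["sentence_id"]), str(sent["speaker"]),
                 str(sent["sentence"]), int(label))
            )
        records.append(
            DialogueRecord(
                example_id=eid,
                diagnosis=str(rec.get("diagnosis", "")),
                self_report=str(rec.get("self_report", "")),
                sentences=sentences,
            )
        )
    if dropped:
        logger.warning("dropped %d sentences lacking a symptom_type label", dropped)
    return records


def _load_json(source):
    if isinstance(source, (dict, list)):
        return source
    if hasattr(source, "read"):
        return json.load(source)
    text = str(source)
    if text.lstrip().startswith(("{", "[")):
        return json.loads(text)
    with open(text, "r", encoding="utf-8") as fh:
        return json.load(fh)


# -- tokenization -------------------------------------------------------------------


def tokenize(text: str, lexicon) -> list[str]:
    """Greedy longest-match segmentation with single-character fallback."""
    if not text:
        return []
    terms = set(lexicon)
    max_len = max((len(t) for t in terms), default=1)
    out = []
    i = 0
    n = len(text)
    while i < n:
        for width in range(min(max_len, n - i), 0, -1):
            piece = text[i : i + width]
            if piece in terms:
                out.append(piece)
                i += width
                break
        else:
            out.append(text[i])
            i += 1
    return out


def tokenize_and_index(
    text: str,
    lexicon=None,
    vocab: dict[str, int] | None = None,
    tokenizer=None,
) -> list[int]:
    """Segment text and map tokens to vocab indices (unknown -> UNK)."""
    if vocab is None:
        raise ValueError("a vocab (token -> index) is required")
    if tokenizer is None:
        tokens = tokenize(text, lexicon if lexicon is not None else vocab.keys())
    else:
        tokens = tokenizer(text)
    return [vocab.get(t, UNK_INDEX) for t in tokens]


def build_vocab(
    records: list[DialogueRecord],
    max_size: int | None = None,
    lexicon=None,
    tokenizer=None,
) -> dict[str, int]:
    """Frequency-ranked token -> index map; indices 0/1 reserved (pad/unk)."""
    counts: dict[str, int] = {}
    for rec in records:
        for _, _, text, _ in rec.sentences:
            toks = tokenizer(text) if tokenizer else tokenize(
                text, lexicon if lexicon is not None else []
            )
            for t in toks:
                counts[t] = counts.get(t, 0) + 1
    ranked = sorted(counts, key=lambda t: (-counts[t], t))
    if max_size is not None:
        ranked = ranked[: max(max_size - _FIRST_TOKEN_INDEX, 0)]
    return {t: i + _FIRST_TOKEN_INDEX for i, t in enumerate(ranked)}


def save_vocab(vocab: dict[str, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tok, idx in sorted(vocab.items(), key=lambda kv: kv[1]):
            fh.write(f"{tok}\t{idx}\n")


def load_vocab(path) -> dict[str, int]:
    vocab = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            tok, idx = line.rstrip("\n").split("\t")
            vocab[tok] = int(idx)
    return vocab


# -- client construction -------------------------------------------------------------


def build_federated_text(
    records: list[DialogueRecord],
    n_clients: int,
    vocab: dict[str, int],
    max_len: int = 50,
    seed: int = 0,
    train_fraction: float = 0.9,
    tokenizer=None,
    lexicon=None,
) -> FederatedDataset:
    """Partition whole dialogues onto clients and build padded index arrays.

    Dialogues are shuffled (seeded) and dealt round-robin, so every client
    holds complete conversations — the unit of heterogeneity in this corpus.
    Each labeled sentence becomes one (token sequence, symptom_type) sample.
    """
    if n_clients < 1:
        raise ValueError("n_clients must be positive")
    if n_clients > len(records):
        raise ValueError(
            f"n_clients {n_clients} exceeds number of dialogues {len(records)}"
        )
    rng = np.random.default_rng((seed, 303))
    order = rng.permutation(len(records))
    groups: list[list[DialogueRecord]] = [[] for _ in range(n_clients)]
    for slot, rec_idx in enumerate(order):
        groups[slot % n_clients].append(records[rec_idx])

    lex = lexicon if lexicon is not None else list(vocab.keys())
    clients = []
    for cid, group in enumerate(groups):
        seqs, labels = [], []
        for rec in group:
            for _, _, text, label in rec.sentences:
                idxs = tokenize_and_index(text, lex, vocab, tokenizer)[:max_len]
                row = np.full(max_len, PAD_INDEX, dtype=np.int64)
                row[: len(idxs)] = idxs
                seqs.append(row)
                labels.append(label)
        if len(labels) < 2:
            raise ValueError(
                f"client {cid} received {len(labels)} labeled sentences; "
                "cannot form train and test splits"
            )
        x = np.stack(seqs)
        y = np.asarray(labels, dtype=np.int64)
        tr_x, tr_y, te_x, te_y = _split(
            x, y, train_fraction, np.random.default_rng((seed, 304, cid))
        )
        clients.append(ClientDataset(cid, tr_x, tr_y, te_x, te_y))
    return FederatedDataset(
        clients,
        provenance={"kind": "dialogue_corpus", "n_dialogues": len(records),
                    "n_clients": n_clients, "seed": seed, "max_len": max_len},
    )


# -- synthetic fixture ---------------------------------------------------------------


@dataclass(frozen=True)
class CorpusFixtureSpec:
    """Parameters of the synthetic dialogue-corpus generator.

    ``label_skew`` controls how dialogue-specific the class priors are:
    0 means every dialogue shares the global uniform prior; larger values
    concentrate each dialogue on its own label mix (a Dirichlet with
    concentration ``1/label_skew`` per class).
    """

    n_dialogues: int = 60
    sentences_per_dialogue_mean: float = 12.0
    tokens_per_sentence_mean: float = 8.0
    vocab_size: int = 500
    n_classes: int = 2
    label_skew: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_dialogues, self.vocab_size, self.n_classes) < 1:
            raise ValueError("counts must be positive")
        if self.sentences_per_dialogue_mean <= 0 or self.tokens_per_sentence_mean <= 0:
            raise ValueError("per-dialogue/sentence means must be positive")
        if self.label_skew < 0:
            raise ValueError("label_skew must be nonnegative")


def _fixture_tokens(n: int) -> list[str]:
    """Distinct fixed-width tokens: unambiguous under greedy matching."""
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    toks = []
    for combo in itertools.product(alphabet, repeat=3):
        toks.append("".join(combo))
        if len(toks) == n:
            return toks
    raise ValueError("vocab_size too large for the fixture token space")


def generate_fixture(spec: CorpusFixtureSpec) -> dict:
    """Generate an IMCS-V2-format JSON document (mapping example_id -> record).

    Sentence token streams are drawn from class-conditional categorical
    distributions, so the symptom label is statistically recoverable from the
    text.  Deterministic given ``spec.seed``; passes ``read_imcs`` round-trip.
    """
    rng = np.random.default_rng((spec.seed, 404))
    tokens = _fixture_tokens(spec.vocab_size)
    # class-conditional token log-weights; distinct classes -> learnable text
    class_token_p = []
    for _ in range(spec.n_classes):
        z = rng.normal(0.0, 1.5, size=spec.vocab_size)
        p = np.exp(z - z.max())
        class_token_p.append(p / p.sum())

    base_prior = np.full(spec.n_classes, 1.0 / spec.n_classes)
    doc = {}
    for d in range(spec.n_dialogues):
        if spec.label_skew == 0:
            prior = base_prior
        else:
            prior = rng.dirichlet(base_prior / spec.label_skew)
        n_sent = max(1, int(rng.poisson(spec.sentences_per_dialogue_mean)))
        dialogue = []
        for s in range(n_sent):
            label = int(rng.choice(spec.n_classes, p=prior))
            n_tok = max(1, int(rng.poisson(spec.tokens_per_sentence_mean)))
            idx = rng.choice(spec.vocab_size, size=n_tok, p=class_token_p[label])
            dialogue.append(
                {
                    "sentence_id": f"s{s:03d}",
                    "speaker": "patient" if s % 2 == 0 else "doctor",
                    "sentence": "".join(tokens[i] for i in idx),
                    "symptom_type": label,
                }
            )
        eid = f"fixture_{d:05d}"
        doc[eid] = {
            "example_id": eid,
            "diagnosis": "synthetic",
            "self_report": "",
            "dialogue": dialogue,
        }
    return doc


def fixture_vocab(spec: CorpusFixtureSpec) -> dict[str, int]:
    """The exact token -> index vocab underlying a fixture."""
    return {
        t: i + _FIRST_TOKEN_INDEX for i, t in enumerate(_fixture_tokens(spec.vocab_size))
    }
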