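"""Dialogue-corpus path: reader, tokenizer, partitioning, fixture generator."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from fedpap.medtext import (
    CorpusFixtureSpec,
    SchemaError,
    build_federated_text,
    build_vocab,
    fixture_vocab,
    generate_fixture,
    load_vocab,
    read_imcs,
    save_vocab,
    tokenize,
    tokenize_and_index,
)

MINIMAL_DOC = {
    "d1": {
        "example_id": "d1",
        "diagnosis": "indigestion",
        "self_report": "baby has diarrhea",
        "dialogue": [
            {"sentence_id": "s1", "speaker": "patient",
             "sentence": "has diarrhea", "symptom_type": 1},
            {"sentence_id": "s2", "speaker": "doctor",
             "sentence": "any fever", "symptom_type": 0},
        ],
    }
}


class TestReader:
    def test_minimal_round_trip(self):
        recs = read_imcs(MINIMAL_DOC)
        assert len(recs) == 1
        assert recs[0].example_id == "d1"
        assert len(recs[0].sentences) == 2
        assert recs[0].sentences[0][3] == 1

    def test_json_string_and_list_forms(self):
        recs = read_imcs(json.dumps(list(MINIMAL_DOC.values())))
        assert len(recs) == 1

    def test_unlabeled_sentences_dropped_with_warning(self, caplog):
        doc = {"d1": {"example_id": "d1", "dialogue": [
            {"sentence_id": "s1", "speaker": "doctor", "sentence": "hello"},
        ]}}
        with caplog.at_level("WARNING"):
            recs = read_imcs(doc)
        assert len(recs) == 1 and len(recs[0].sentences) == 0
        assert "dropped 1" in caplog.text

    def test_missing_fields_raise_schema_error(self):
        with pytest.raises(SchemaError, match="example_id"):
            read_imcs([{"dialogue": []}])
        with pytest.raises(SchemaError, match="d9"):
            read_imcs([{"example_id": "d9"}])


class TestTokenizer:
    LEX = {"AB", "A", "B", "ABC"}

    def test_single_term(self):
        assert tokenize("ABC", self.LEX) == ["ABC"]

    def test_longest_match_wins(self):
        assert tokenize("AB", self.LEX) == ["AB"]
        assert tokenize("ABA", self.LEX) == ["AB", "A"]

    def test_single_char_fallback(self):
        assert tokenize("AXB", self.LEX) == ["A", "X", "B"]

    def test_empty_string(self):
        assert tokenize("", self.LEX) == []

    def test_index_mapping_with_unk(self):
        vocab = {"AB": 2, "C": 3}
        assert tokenize_and_index("ABZC", vocab=vocab) == [2, 1, 3]

    def test_pluggable_tokenizer(self):
        vocab = {"x": 2, "y": 3}
        out = tokenize_and_index("x y", vocab=vocab, tokenizer=str.split)
        assert out == [2, 3]


class TestFixture:
    SPEC = CorpusFixtureSpec(n_dialogues=20, vocab_size=50, n_classes=2,
                             label_skew=1.0, seed=0)

    def test_byte_identical_given_seed(self):
        a = json.dumps(generate_fixture(self.SPEC), sort_keys=True)
        b = json.dumps(generate_fixture(self.SPEC), sort_keys=True)
        assert a == b

    def test_reader_round_trip_counts(self):
        doc = generate_fixture(self.SPEC)
        recs = read_imcs(doc)
        assert len(recs) == self.SPEC.n_dialogues
        assert {r.example_id for r in recs} == set(doc.keys())
        for rec in recs:
            assert len(rec.sentences) == len(doc[rec.example_id]["dialogue"])

    def test_sentence_count_near_mean(self):
        spec = CorpusFixtureSpec(n_dialogues=10, sentences_per_dialogue_mean=40,
                                 vocab_size=50, seed=1)
        total = sum(len(r.sentences) for r in read_imcs(generate_fixture(spec)))
        assert 300 <= total <= 500  # +-25% of 400

    def test_zero_skew_label_frequencies_homogeneous(self):
        """With label_skew=0 all dialogues share one class prior."""
        spec = CorpusFixtureSpec(n_dialogues=40, sentences_per_dialogue_mean=30,
                                 vocab_size=50, n_classes=3, label_skew=0.0, seed=2)
        recs = read_imcs(generate_fixture(spec))
        table = np.array([
            np.bincount([s[3] for s in r.sentences], minlength=3) for r in recs
        ])
        table = table[table.sum(axis=1) > 0]
        _, p, _, _ = sps.chi2_contingency(table)
        assert p > 0.01

    def test_positive_skew_differentiates_dialogues(self):
        spec = CorpusFixtureSpec(n_dialogues=40, sentences_per_dialogue_mean=30,
                                 vocab_size=50, n_classes=3, label_skew=5.0, seed=2)
        recs = read_imcs(generate_fixture(spec))
        table = np.array([
            np.bincount([s[3] for s in r.sentences], minlength=3) for r in recs
        ])
        table = table[table.sum(axis=1) > 0]
        _, p, _, _ = sps.chi2_contingency(table)
        assert p < 0.01

    def test_tokens_in_fixture_vocab(self):
        doc = generate_fixture(self.SPEC)
        vocab = fixture_vocab(self.SPEC)
        for rec in read_imcs(doc):
            for _, _, text, _ in rec.sentences:
                idx = tokenize_and_index(text, vocab=vocab)
                assert all(i >= 2 for i in idx)  # no UNK: exact round trip


class TestPartitioning:
    SPEC = CorpusFixtureSpec(n_dialogues=12, vocab_size=50, seed=0)

    def _dataset(self, n_clients=4, seed=0):
        recs = read_imcs(generate_fixture(self.SPEC))
        return recs, build_federated_text(
            recs, n_clients, fixture_vocab(self.SPEC), max_len=12, seed=seed
        )

    def test_sample_conservation(self):
        recs, ds = self._dataset()
        total = sum(len(r.sentences) for r in recs)
        assert ds.n_train + ds.n_test == total

    def test_one_dialogue_per_client(self):
        recs = read_imcs(generate_fixture(self.SPEC))
        ds = build_federated_text(
            recs, len(recs), fixture_vocab(self.SPEC), max_len=12, seed=0,
            train_fraction=0.5,
        )
        counts = sorted(c.n_train + c.n_test for c in ds.clients)
        assert counts == sorted(len(r.sentences) for r in recs)

    def test_deterministic_partition(self):
        _, a = self._dataset(seed=5)
        _, b = self._dataset(seed=5)
        for ca, cb in zip(a.clients, b.clients):
            np.testing.assert_array_equal(ca.train_x, cb.train_x)
            np.testing.assert_array_equal(ca.train_y, cb.train_y)

    def test_too_many_clients_rejected(self):
        recs = read_imcs(generate_fixture(self.SPEC))
        with pytest.raises(ValueError, match="exceeds"):
            build_federated_text(recs, 100, fixture_vocab(self.SPEC))

    def test_padding_and_shape(self):
        _, ds = self._dataset()
        for cl in ds.clients:
            assert cl.train_x.shape[1] == 12
            assert cl.train_x.dtype == np.int64


class TestVocab:
    def test_build_save_load(self, tmp_path):
        recs = read_imcs(MINIMAL_DOC)
        vocab = build_vocab(recs, tokenizer=str.split)
        assert set(vocab) == {"has", "diarrhea", "any", "fever"}
        assert min(vocab.values()) == 2
        save_vocab(vocab, tmp_path / "v.tsv")
        assert load_vocab(tmp_path / "v.tsv") == vocab

    def test_max_size_caps_by_frequency(self):
        recs = read_imcs(MINIMAL_DOC)
        vocab = build_vocab(recs, max_size=3, tokenizer=str.split)
        assert len(vocab) == 1  # indices 0/1 reserved


class TestLearnability:
    def test_bag_of_tokens_beats_majority_class(self):
        """Class-conditional token draws leave recoverable signal."""
        from fedpap.models import Batch, ModelSpec, accuracy, init_params
        from fedpap.optim import OptimizerConfig, client_update
        from fedpap.synthetic import ClientDataset

        spec = CorpusFixtureSpec(n_dialogues=60, vocab_size=60, n_classes=2,
                                 label_skew=1.0, seed=3)
        recs = read_imcs(generate_fixture(spec))
        vocab = fixture_vocab(spec)
        xs, ys = [], []
        for rec in recs:
            for _, _, text, label in rec.sentences:
                idx = tokenize_and_index(text, vocab=vocab)
                row = np.bincount(idx, minlength=62)
                xs.append(row)
                ys.append(label)
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys)
        n = len(y)
        cut = int(0.8 * n)
        mspec = ModelSpec(kind="logreg", n_features=x.shape[1], n_classes=2)
        data = ClientDataset(0, x[:cut], y[:cut], x[cut:], y[cut:])
        theta = client_update(
            mspec, init_params(mspec), data,
            OptimizerConfig("adam", 0.05), 5, 20, 32, rng_seed=0,
        )
        majority = max(np.bincount(y[cut:])) / (n - cut)
        assert accuracy(mspec, theta, x[cut:], y[cut:]) > majority + 0.05
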