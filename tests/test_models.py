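"""Model-zoo contracts: losses, exact gradients, prediction, embeddings."""

import numpy as np
import pytest

from fedpap.models import (
    Batch,
    ModelSpec,
    accuracy,
    build_embedding_matrix,
    init_params,
    load_word2vec_text,
    loss_and_grad,
    predict,
)
from fedpap.params import ModelParams, flatten, unflatten

LOGREG = ModelSpec(kind="logreg", n_features=6, n_classes=4, init_seed=0)
LSTM = ModelSpec(
    kind="lstm", vocab_size=15, embed_dim=4, hidden_dim=5, max_len=7,
    n_classes=3, init_seed=3,
)


def random_batch(spec, rng, n=5):
    if spec.kind == "logreg":
        x = rng.standard_normal((n, spec.n_features))
    else:
        x = rng.integers(0, spec.vocab_size, size=(n, spec.max_len))
        x[:, -2:] = 0  # trailing padding
    y = rng.integers(0, spec.n_classes, size=n)
    return Batch(x, y)


def finite_difference_grad(spec, theta, batch, h=1e-5):
    """Central finite differences on the flattened parameter vector."""
    v = flatten(theta)
    g = np.zeros_like(v)
    for i in range(len(v)):
        vp, vm = v.copy(), v.copy()
        vp[i] += h
        vm[i] -= h
        lp, _ = loss_and_grad(spec, unflatten(vp, theta), batch)
        lm, _ = loss_and_grad(spec, unflatten(vm, theta), batch)
        g[i] = (lp - lm) / (2 * h)
    return g


class TestInit:
    def test_seeded_determinism(self):
        assert init_params(LSTM).equals(init_params(LSTM))

    def test_logreg_layer_shapes(self):
        theta = init_params(ModelSpec(kind="logreg", n_features=60, n_classes=10))
        assert theta.names == ("W", "b")
        assert theta["W"].shape == (60, 10) and theta["b"].shape == (10,)

    def test_different_seeds_differ(self):
        a = init_params(LSTM)
        b = init_params(ModelSpec(**{**LSTM.__dict__, "init_seed": 4}))
        assert not a.equals(b)


class TestLossAndGrad:
    def test_zero_params_uniform_loss(self, rng):
        spec = ModelSpec(kind="logreg", n_features=8, n_classes=10)
        theta = init_params(spec)  # zeros
        batch = random_batch(spec, rng, n=7)
        loss, _ = loss_and_grad(spec, theta, batch)
        assert loss == pytest.approx(np.log(10), rel=1e-12)

    @pytest.mark.parametrize("spec", [LOGREG, LSTM], ids=["logreg", "lstm"])
    def test_gradient_matches_finite_differences(self, spec, rng):
        theta = init_params(spec)
        if spec.kind == "logreg":  # move off the zero init
            theta = theta.map(lambda a: a + rng.standard_normal(a.shape) * 0.3)
        batch = random_batch(spec, rng)
        _, grad = loss_and_grad(spec, theta, batch)
        fd = finite_difference_grad(spec, theta, batch)
        an = flatten(grad)
        denom = np.maximum(np.abs(fd), 1e-3)
        assert np.max(np.abs(an - fd) / denom) < 1e-4

    def test_perfect_prediction_zero_loss_zero_output_grad(self):
        spec = ModelSpec(kind="logreg", n_features=2, n_classes=2)
        # huge margin toward class 1 for x=[0,1]
        theta = ModelParams([("W", np.array([[0.0, 0.0], [0.0, 60.0]])),
                             ("b", np.zeros(2))])
        loss, grad = loss_and_grad(spec, theta, Batch(np.array([[0.0, 1.0]]),
                                                      np.array([1])))
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(grad["W"], 0, atol=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Batch(np.zeros((0, 3)), np.zeros(0, dtype=int))

    def test_logreg_convexity_on_chords(self, rng):
        spec = LOGREG
        batch = random_batch(spec, rng, n=8)
        for _ in range(10):
            va = rng.standard_normal(spec.n_features * spec.n_classes + spec.n_classes)
            vb = rng.standard_normal(len(va))
            t = rng.uniform()
            template = init_params(spec)
            la, _ = loss_and_grad(spec, unflatten(va, template), batch)
            lb, _ = loss_and_grad(spec, unflatten(vb, template), batch)
            lm, _ = loss_and_grad(spec, unflatten(t * va + (1 - t) * vb, template), batch)
            assert lm <= t * la + (1 - t) * lb + 1e-9


class TestPredict:
    def test_perfect_margin_accuracy_one(self, rng):
        spec = ModelSpec(kind="logreg", n_features=3, n_classes=3)
        theta = ModelParams([("W", 50 * np.eye(3)), ("b", np.zeros(3))])
        x = np.eye(3)
        assert accuracy(spec, theta, x, np.array([0, 1, 2])) == 1.0

    def test_constant_predictor_on_balanced_labels(self):
        spec = ModelSpec(kind="logreg", n_features=2, n_classes=2)
        theta = ModelParams([("W", np.zeros((2, 2))), ("b", np.array([5.0, 0.0]))])
        x = np.random.default_rng(0).standard_normal((10, 2))
        y = np.array([0, 1] * 5)
        assert accuracy(spec, theta, x, y) == 0.5

    def test_three_of_four_correct(self):
        spec = ModelSpec(kind="logreg", n_features=2, n_classes=2)
        theta = ModelParams([("W", np.array([[10.0, 0.0], [0.0, 10.0]])),
                             ("b", np.zeros(2))])
        x = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        y = np.array([0, 0, 1, 0])  # last one wrong on purpose
        assert accuracy(spec, theta, x, y) == 0.75

    def test_ties_break_to_lowest_index(self):
        spec = ModelSpec(kind="logreg", n_features=2, n_classes=3)
        theta = ModelParams([("W", np.zeros((2, 3))), ("b", np.zeros(3))])
        pred = predict(spec, theta, np.ones((4, 2)))
        assert np.all(pred == 0)


class TestLSTMContracts:
    def test_forward_deterministic(self, rng):
        theta = init_params(LSTM)
        batch = random_batch(LSTM, rng)
        l1, g1 = loss_and_grad(LSTM, theta, batch)
        l2, g2 = loss_and_grad(LSTM, theta, batch)
        assert l1 == l2 and g1.equals(g2)

    def test_padding_beyond_sequence_is_inert(self, rng):
        """Appending pad tokens after the true length must not change scores."""
        short = ModelSpec(**{**LSTM.__dict__, "max_len": 4})
        long = ModelSpec(**{**LSTM.__dict__, "max_len": 9})
        theta = init_params(short)
        x_short = rng.integers(1, short.vocab_size, size=(6, 4))
        x_long = np.zeros((6, 9), dtype=np.int64)
        x_long[:, :4] = x_short
        p_short = predict(short, theta, x_short)
        p_long = predict(long, theta, x_long)
        np.testing.assert_array_equal(p_short, p_long)

    def test_internal_padding_masks_recurrence(self, rng):
        """Pad positions inside a sequence carry state through unchanged."""
        theta = init_params(LSTM)
        a = np.array([[3, 5, 0, 0, 7, 0, 0]])
        b = np.array([[3, 5, 7, 0, 0, 0, 0]])
        la, _ = loss_and_grad(LSTM, theta, Batch(a, np.array([1])))
        lb, _ = loss_and_grad(LSTM, theta, Batch(b, np.array([1])))
        assert la == pytest.approx(lb, rel=1e-12)


class TestEmbeddings:
    def test_word2vec_text_round_trip(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("2 3\nfever 1.0 2.0 3.0\ncough 0.5 0.25 0.125\n")
        vectors, dim = load_word2vec_text(path)
        assert dim == 3
        np.testing.assert_array_equal(vectors["fever"], [1.0, 2.0, 3.0])

    def test_embedding_matrix_pretrained_and_oov(self, tmp_path):
        vocab = {"fever": 2, "rash": 3}
        pretrained = {"fever": np.array([1.0, 2.0])}
        mat = build_embedding_matrix(vocab, 2, pretrained, seed=1)
        np.testing.assert_array_equal(mat[2], [1.0, 2.0])
        assert np.all(mat[0] == 0)  # padding row
        mat2 = build_embedding_matrix(vocab, 2, pretrained, seed=1)
        np.testing.assert_array_equal(mat[3], mat2[3])  # seeded OOV
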